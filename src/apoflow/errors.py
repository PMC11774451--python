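"""Exception hierarchy.

``InputError`` marks bad user-supplied data (files, SMILES, sequences);
``ContractError`` marks violated internal preconditions (shape or state
mismatches between objects that the caller is responsible for keeping
consistent); ``DegeneracyError`` marks numerically ill-posed geometry.
"""


class ApoflowError(Exception):
    """Base class for all package errors."""


class InputError(ApoflowError, ValueError):
    """Invalid user input (unparsable SMILES, empty structure, bad path)."""


class ContractError(ApoflowError, ValueError):
    """An API precondition was violated by the caller."""


class DegeneracyError(ApoflowError, ValueError):
    """Geometric problem is numerically degenerate (e.g. collinear points)."""
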