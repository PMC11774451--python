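"""Prior distributions over initial (t = 0) complex states.

The ligand prior is a *harmonic* Gaussian whose precision matrix is the
bond-graph Laplacian ``L = D - A``: density proportional to
``exp(-x.T L x / 2)`` independently per spatial dimension, so bonded atoms
fluctuate around each other with unit-scale bond lengths while the overall
shape stays compact. ``L`` is singular (one zero eigenvalue per connected
fragment, the translation mode), so sampling is performed in the strictly
positive eigenspace and each fragment is afterwards translated so that its
centroid sits at a requested center.

The protein prior is the user-supplied unbound (apo) structure plus
isotropic Gaussian noise of scale ``sigma`` (default 1e-4 Angstrom), which
during training regularizes the map away from an exact apo-to-holo point
mapping. The same noise is applied to holo *targets* at training time;
inference uses the apo structure as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import ComplexState, LigandGraph, ProteinStructure
from .errors import ContractError, InputError

EIG_TOL = 1e-9


@dataclass(frozen=True)
class NoiseConfig:
    """Coordinate noise settings: ``sigma`` in Angstrom, plus the RNG seed."""

    sigma: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InputError("sigma must be non-negative")


@dataclass(frozen=True)
class PriorSample:
    """A drawn t = 0 state plus the sampling context (centers, seed)."""

    state: ComplexState
    log_context: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.state.time != 0.0:
            raise ContractError("prior samples live at t = 0")


def sample_harmonic_ligand(
    graph: LigandGraph, centers: np.ndarray, seed: int, size: int | None = None
) -> np.ndarray:
    """Draw ligand coordinates from the harmonic bond-graph prior.

    Per fragment the coordinates follow the zero-mean Gaussian with the
    fragment's Laplacian as precision, restricted to the non-null eigenspace:
    eigencoefficients ``c_k ~ N(0, 1/lambda_k)`` independently per spatial
    dimension, null (translation) components fixed by translating the
    fragment centroid to its requested center.

    Parameters
    ----------
    graph : LigandGraph
    centers : array (n_fragments, 3)
        One center per fragment.
    seed : int
    size : int, optional
        Number of independent draws; ``None`` returns a single (N_L, 3)
        array, an integer returns (size, N_L, 3).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape != (graph.n_fragments, 3):
        raise InputError(
            f"need one 3-vector center per fragment: expected "
            f"{(graph.n_fragments, 3)}, got {centers.shape}"
        )
    n_draws = 1 if size is None else int(size)
    rng = np.random.default_rng(seed)
    lap = graph.laplacian
    coords = np.zeros((n_draws, graph.n_atoms, 3))
    for f in range(graph.n_fragments):
        idx = np.flatnonzero(graph.fragment_id == f)
        sub = lap[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(sub)
        pos = evals > EIG_TOL
        if pos.any():
            std = 1.0 / np.sqrt(evals[pos])
            coeff = rng.standard_normal((n_draws, pos.sum(), 3)) * std[None, :, None]
            frag = np.einsum("ik,nkd->nid", evecs[:, pos], coeff)
        else:  # single atom: null space only
            frag = np.zeros((n_draws, len(idx), 3))
        frag = frag - frag.mean(axis=1, keepdims=True) + centers[f]
        coords[:, idx] = frag
    return coords[0] if size is None else coords


def sample_apo_protein(apo: ProteinStructure, noise: NoiseConfig) -> np.ndarray:
    """Apo coordinates plus i.i.d. isotropic Gaussian noise of scale sigma."""
    rng = np.random.default_rng(noise.seed)
    return apo.atom_coords + noise.sigma * rng.standard_normal(
        apo.atom_coords.shape
    )


def noise_holo_targets(state: ComplexState, noise: NoiseConfig) -> ComplexState:
    """Apply training-time target noise to a holo (t = 1) state.

    Independent Gaussian noise of scale ``sigma`` is added to both the
    protein and ligand target coordinates. Training-only: never applied
    when sampling trajectories at inference.
    """
    if state.time != 1.0:
        raise ContractError("holo target noising requires a t = 1 state")
    rng = np.random.default_rng(noise.seed)
    return ComplexState(
        protein_coords=state.protein_coords
        + noise.sigma * rng.standard_normal(state.protein_coords.shape),
        ligand_coords=state.ligand_coords
        + noise.sigma * rng.standard_normal(state.ligand_coords.shape),
        time=1.0,
    )


def assemble_prior_state(
    apo: ProteinStructure,
    graph: LigandGraph,
    noise: NoiseConfig,
    pocket_center: np.ndarray | None = None,
) -> PriorSample:
    """Draw a full t = 0 complex state.

    The protein part is the (optionally noised) apo structure; the ligand
    part is a harmonic prior draw with every fragment centered at the apo
    protein heavy-atom centroid (blind docking default) or at a user-supplied
    ``pocket_center``.
    """
    if pocket_center is None:
        center = apo.atom_coords.mean(axis=0)
        policy = "apo_centroid"
    else:
        center = np.asarray(pocket_center, dtype=float)
        policy = "pocket"
    centers = np.tile(center, (graph.n_fragments, 1))
    # independent streams for the protein and ligand parts
    protein = sample_apo_protein(apo, noise)
    ligand = sample_harmonic_ligand(graph, centers, seed=noise.seed + 1)
    state = ComplexState(protein_coords=protein, ligand_coords=ligand, time=0.0)
    return PriorSample(
        state=state,
        log_context={"centers": centers, "seed": noise.seed, "policy": policy},
    )
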