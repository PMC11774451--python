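"""Apo-to-holo pair assessment and dataset curation.

Training couples an unbound (apo) structure with its bound (holo) partner
only when the two are conformationally compatible: the pair is kept when
the pocket-weighted structural alignment yields TM-score >= ``tm_min``
(default 0.7) and Calpha RMSD < ``rmsd_max`` (default 5 Angstrom), together
with generous length caps. This filtered independent coupling is the
"unbalanced" coupling of the flow-matching objective: candidate pairs are
drawn independently and rejected when they fall outside the acceptance set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import LigandGraph, ProteinStructure, check_sequence_gaps
from .errors import ContractError, DegeneracyError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentResult:
    """Weighted rigid superposition: ``y ~ R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray
    weighted_rmsd: float
    ca_rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class CouplingConfig:
    """Apo-holo acceptance thresholds defining the coupling's acceptance set."""

    tm_min: float = 0.7
    rmsd_max: float = 5.0
    max_residues: int = 2000
    max_ligand_atoms: int = 400

    def __post_init__(self):
        if not 0.0 < self.tm_min <= 1.0:
            raise InputError("tm_min must lie in (0, 1]")
        if self.rmsd_max <= 0:
            raise InputError("rmsd_max must be positive")


@dataclass
class PairRecord:
    """One candidate apo/holo training pair with its ligand and label."""

    apo: ProteinStructure
    holo: ProteinStructure
    ligand_graph: LigandGraph
    holo_ligand_coords: np.ndarray
    affinity_pk: float | None = None
    full_sequence: str | None = None
    pair_id: str = ""
    accepted: bool | None = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.apo.sequence != self.holo.sequence:
            raise ContractError(
                "apo and holo must share a residue-level sequence correspondence"
            )
        self.holo_ligand_coords = np.asarray(self.holo_ligand_coords, dtype=float)
        if self.holo_ligand_coords.shape != (self.ligand_graph.n_atoms, 3):
            raise ContractError("holo ligand coordinate shape mismatch")


# --------------------------------------------------------------------------
# Alignment primitives
# --------------------------------------------------------------------------

def weighted_kabsch_align(
    mobile_ca: np.ndarray, target_ca: np.ndarray, weights: np.ndarray
) -> AlignmentResult:
    """Weighted rigid superposition of ``mobile_ca`` onto ``target_ca``.

    Finds the proper rotation R and translation t minimizing
    ``sum_i w_i ||R x_i + t - y_i||^2`` via the SVD of the weighted
    cross-covariance, with the usual determinant sign correction so that
    ``det(R) = +1``.

    Raises
    ------
    DegeneracyError
        Fewer than 3 positively weighted points, or the weighted point set
        is collinear/coincident so the rotation is underdetermined.
    """
    mobile = np.asarray(mobile_ca, dtype=float)
    target = np.asarray(target_ca, dtype=float)
    w = np.asarray(weights, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ContractError("point sets must share shape (M, 3)")
    if len(w) != len(mobile):
        raise ContractError("one weight per point required")
    if np.any(w < 0) or w.sum() <= 0:
        raise InputError("weights must be non-negative and not all zero")
    if np.count_nonzero(w) < 3 or len(mobile) < 3:
        raise DegeneracyError("need at least 3 positively weighted points")
    w = w / w.sum()

    mu_m = w @ mobile
    mu_t = w @ target
    xm = mobile - mu_m
    xt = target - mu_t
    # collinearity check on the weighted mobile cloud
    spread = np.linalg.svd(xm * np.sqrt(w)[:, None], compute_uv=False)
    if spread[1] <= 1e-10 * max(spread[0], 1.0):
        raise DegeneracyError("weighted point set is collinear or coincident")

    h = (xm * w[:, None]).T @ xt
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_t - rotation @ mu_m

    moved = mobile @ rotation.T + translation
    dev2 = np.sum((moved - target) ** 2, axis=1)
    weighted_rmsd = float(np.sqrt(np.sum(w * dev2)))
    unweighted = float(np.sqrt(np.mean(dev2)))
    return AlignmentResult(
        rotation=rotation,
        translation=translation,
        weighted_rmsd=weighted_rmsd,
        ca_rmsd=unweighted,
    )


def ligand_proximity_weights(
    ca_coords: np.ndarray, ligand_coords: np.ndarray, tau: float = 5.0
) -> np.ndarray:
    """Per-residue alignment weights concentrating on the binding pocket.

    ``w_i = exp(-d_i / tau)`` with ``d_i`` the minimum distance from residue
    i's Calpha to any ligand heavy atom; normalized to sum to one. ``tau``
    (default 5 Angstrom) sets the distance scale over which a residue's
    influence on the superposition decays by a factor of e.
    """
    if tau <= 0:
        raise InputError("tau must be positive")
    ligand = np.asarray(ligand_coords, dtype=float)
    if ligand.size == 0:
        raise InputError("empty ligand")
    ca = np.asarray(ca_coords, dtype=float)
    d = np.sqrt(
        ((ca[:, None, :] - ligand[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    w = np.exp(-d / tau)
    return w / w.sum()


def ca_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between matched coordinate sets.

    No superposition is performed: callers align first.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("coordinate shape mismatch")
    if len(a) < 1:
        raise InputError("empty coordinate set")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _tm_d0(m: int) -> float:
    if m > 15:
        return max(1.24 * (m - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def tm_score(mobile_ca: np.ndarray, target_ca: np.ndarray) -> float:
    """TM-score between residue-matched Calpha traces.

    Because apo and holo share a sequence, the residue correspondence is
    fixed and no alignment search is needed; only the superposition is
    optimized. Starting from the all-residue Kabsch fit, the fit is
    iteratively restricted to residues closer than a d0-scaled cutoff until
    the inclusion set is stable (max 20 iterations), and the best score over
    iterations is returned. Normalization is by the target length.
    """
    mobile = np.asarray(mobile_ca, dtype=float)
    target = np.asarray(target_ca, dtype=float)
    if mobile.shape != target.shape:
        raise ContractError("coordinate shape mismatch")
    m = len(mobile)
    if m == 0:
        raise InputError("empty structures")
    d0 = _tm_d0(m)
    if m < 3:
        # too short to superpose; score the raw coordinates
        d = np.linalg.norm(mobile - target, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    # several superposition seeds (whole chain and contiguous fragments),
    # each refined by TM-weighted re-fitting until the score is stable
    starts = [np.arange(m), np.arange(m // 2), np.arange(m // 2, m),
              np.arange(m // 4, (3 * m) // 4)]
    best = 0.0
    for start in starts:
        if len(start) < 3:
            continue
        w = np.zeros(m)
        w[start] = 1.0
        prev = -1.0
        for _ in range(20):
            try:
                aln = weighted_kabsch_align(mobile, target, w)
            except DegeneracyError:
                break
            d = np.linalg.norm(aln.transform(mobile) - target, axis=1)
            tm = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
            best = max(best, tm)
            if tm <= prev + 1e-9:
                break
            prev = tm
            # residues already close to the target dominate the next fit
            w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
        # fall through to the next start
    return best


# --------------------------------------------------------------------------
# Acceptance rule and curation
# --------------------------------------------------------------------------

def coupling_decision(
    tm: float,
    rmsd: float,
    n_residues: int,
    n_ligand_atoms: int,
    config: CouplingConfig = CouplingConfig(),
):
    """The acceptance rule on measured pair metrics.

    Accept iff ``tm >= tm_min`` and ``rmsd < rmsd_max`` and both length
    caps hold; equivalently, reject iff ``tm < tm_min`` or
    ``rmsd >= rmsd_max`` (boundary semantics: a pair exactly at
    ``rmsd_max`` is rejected, one exactly at ``tm_min`` is kept) or a
    length cap is exceeded.

    Returns
    -------
    (bool, str)
        Acceptance flag and reject reason ("" when accepted).
    """
    if tm < config.tm_min:
        return False, "tm_below_min"
    if rmsd >= config.rmsd_max:
        return False, "rmsd_above_max"
    if n_residues > config.max_residues:
        return False, "too_many_residues"
    if n_ligand_atoms > config.max_ligand_atoms:
        return False, "too_many_ligand_atoms"
    return True, ""


def accept_pair(pair: PairRecord, config: CouplingConfig = CouplingConfig()):
    """Apply the apo-to-holo acceptance rule to one candidate pair.

    The apo Calpha trace is aligned onto the holo trace with
    ligand-proximity weights (computed in the holo frame, where the crystal
    ligand lives), then TM-score and Calpha RMSD are measured. The pair is
    accepted iff ``tm >= tm_min`` and ``rmsd < rmsd_max`` and both length
    caps hold — mirroring the rejection rule "reject if tm < tm_min or
    rmsd >= rmsd_max".

    Returns
    -------
    (bool, dict)
        Acceptance flag and ``{"tm": ..., "ca_rmsd": ...}``. Both are also
        stored on the pair record.
    """
    apo_ca = pair.apo.ca_coords
    holo_ca = pair.holo.ca_coords
    weights = ligand_proximity_weights(holo_ca, pair.holo_ligand_coords)
    aln = weighted_kabsch_align(apo_ca, holo_ca, weights)
    moved = aln.transform(apo_ca)
    rmsd = ca_rmsd(moved, holo_ca)
    tm = tm_score(apo_ca, holo_ca)
    accepted, _ = coupling_decision(
        tm, rmsd, pair.apo.n_residues, pair.ligand_graph.n_atoms, config
    )
    pair.accepted = bool(accepted)
    pair.metrics = {"tm": float(tm), "ca_rmsd": float(rmsd)}
    return pair.accepted, pair.metrics


_MANIFEST_COLUMNS = [
    "pair_id", "tm", "ca_rmsd", "n_residues", "n_ligand_atoms",
    "accepted", "reject_reason",
]


def curate_dataset(
    pairs, config: CouplingConfig = CouplingConfig()
) -> pd.DataFrame:
    """Curate candidate pairs into a training manifest.

    Pairs whose crystal structure shows sequence gaps (resolved sequence
    differing from the declared full sequence) are dropped first; the
    remainder pass through :func:`accept_pair`. Returns a manifest with one
    row per pair and a ``reject_reason`` in {"", "sequence_gap",
    "tm_below_min", "rmsd_above_max", "too_many_residues",
    "too_many_ligand_atoms"}.
    """
    pairs = list(pairs)
    if not pairs:
        logger.warning("curate_dataset called with no pairs")
        return pd.DataFrame(columns=_MANIFEST_COLUMNS)

    rows = []
    counts: dict = {}
    for k, pair in enumerate(pairs):
        pid = pair.pair_id or f"pair_{k}"
        tm = np.nan
        rmsd = np.nan
        if pair.full_sequence is not None and not check_sequence_gaps(
            pair.full_sequence, pair.holo
        ):
            reason = "sequence_gap"
            accepted = False
            pair.accepted = False
        else:
            accepted, metrics = accept_pair(pair, config)
            tm, rmsd = metrics["tm"], metrics["ca_rmsd"]
            _, reason = coupling_decision(
                tm, rmsd, pair.apo.n_residues, pair.ligand_graph.n_atoms,
                config,
            )
        counts[reason or "accepted"] = counts.get(reason or "accepted", 0) + 1
        rows.append(
            {
                "pair_id": pid,
                "tm": tm,
                "ca_rmsd": rmsd,
                "n_residues": pair.apo.n_residues,
                "n_ligand_atoms": pair.ligand_graph.n_atoms,
                "accepted": bool(accepted),
                "reject_reason": reason,
            }
        )
    logger.info("curation counts: %s", counts)
    return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
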