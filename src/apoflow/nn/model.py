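"""Compact rotation-equivariant network over protein-ligand heavy atoms.

The network is the learned map ``v(x_t, t)`` of the flow: given an
interpolated complex state and the flow time it predicts the bound (holo)
coordinates directly, together with a per-residue confidence score in
[0, 1] (a predicted lDDT) and a binding affinity in pK units.

Architecture: message passing on a radius graph over all heavy atoms
(ligand bond edges always included), with EGNN-style coordinate updates
built purely from relative-position vectors so that the coordinate map
commutes with rigid motions and the scalar heads are invariant. The final
coordinate gates are zero-initialized, making the untrained network the
identity on coordinates — which stabilizes early ODE sampling (an
untrained model is a no-op flow).

Scalar features: one-hot residue type for protein atoms (plus a Calpha
flag), element and bond-degree one-hots for ligand atoms, and the flow
time ``t`` as a global scalar feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..chem import ComplexState, LigandGraph, ProteinStructure
from ..errors import ContractError, InputError
from .autodiff import Adam, Tensor, concat, parameter

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
_MAX_DEGREE = 4
_NODE_DIM = 2 + 20 + 1 + len(ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1


@dataclass(frozen=True)
class ModelConfig:
    """Network hyperparameters: width, depth, radius-graph cutoff, RBF count."""

    hidden_dim: int = 48
    n_layers: int = 3
    neighbor_cutoff: float = 6.0
    n_rbf: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise InputError("n_layers must be >= 1")
        if self.neighbor_cutoff <= 0:
            raise InputError("neighbor_cutoff must be positive")


@dataclass
class Prediction:
    """Model output: holo coordinate estimate, confidence, affinity."""

    pred_protein: np.ndarray
    pred_ligand: np.ndarray
    confidence: np.ndarray
    affinity_pk: float

    def __post_init__(self):
        if not (np.all(np.isfinite(self.pred_protein))
                and np.all(np.isfinite(self.pred_ligand))):
            raise ContractError("non-finite predicted coordinates")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ContractError("confidence must lie in [0, 1]")

    @property
    def mean_confidence(self) -> float:
        return float(self.confidence.mean())


class ComplexContext:
    """Static (coordinate-independent) featurization of one complex."""

    def __init__(self, graph: LigandGraph, protein: ProteinStructure):
        self.graph = graph
        self.protein = protein
        self.n_protein = protein.n_atoms
        self.n_ligand = graph.n_atoms
        self.n_total = self.n_protein + self.n_ligand

        feats = np.zeros((self.n_total, _NODE_DIM - 1))
        for k in range(self.n_protein):
            res = protein.atom_to_residue[k]
            feats[k, 0] = 1.0
            aa = AMINO_ACIDS.find(protein.sequence[res])
            if aa >= 0:
                feats[k, 2 + aa] = 1.0
            if protein.ca_index[res] == k:
                feats[k, 22] = 1.0
        off = 23
        for k in range(self.n_ligand):
            i = self.n_protein + k
            feats[i, 1] = 1.0
            el = graph.elements[k]
            if el in ELEMENTS:
                feats[i, off + ELEMENTS.index(el)] = 1.0
            else:
                feats[i, off + len(ELEMENTS)] = 1.0
            deg = min(int(graph.atom_degrees[k]), _MAX_DEGREE)
            feats[i, off + len(ELEMENTS) + 1 + deg] = 1.0
        self.node_feats = feats

        self.bond_edges = set()
        for i, j in graph.bonds:
            a, b = self.n_protein + i, self.n_protein + j
            self.bond_edges.add((a, b))
            self.bond_edges.add((b, a))
        self.atom_to_residue = protein.atom_to_residue


def _radius_edges(coords: np.ndarray, cutoff: float, bond_edges: set):
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    mask = (dist < cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)
    pairs = set(zip(src.tolist(), dst.tolist())) | bond_edges
    pairs = sorted(pairs)
    src = np.array([p[0] for p in pairs], dtype=int)
    dst = np.array([p[1] for p in pairs], dtype=int)
    return src, dst, dist[src, dst]


class FlowPredictor:
    """The learned flow map with confidence and affinity heads."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        edge_in = 2 * h + config.n_rbf + 4 + 1
        p: dict[str, Tensor] = {}
        p["w_in"] = parameter((_NODE_DIM, h), rng)
        p["b_in"] = parameter(np.zeros(h))
        for layer in range(config.n_layers):
            p[f"we1_{layer}"] = parameter((edge_in, h), rng)
            p[f"be1_{layer}"] = parameter(np.zeros(h))
            p[f"we2_{layer}"] = parameter((h, h), rng)
            p[f"be2_{layer}"] = parameter(np.zeros(h))
            # zero-init gates: untrained network is the identity on coords
            p[f"wx_{layer}"] = parameter(np.zeros((h, 1)))
            p[f"bx_{layer}"] = parameter(np.zeros(1))
            p[f"wh1_{layer}"] = parameter((2 * h, h), rng)
            p[f"bh1_{layer}"] = parameter(np.zeros(h))
            p[f"wh2_{layer}"] = parameter((h, h), rng)
            p[f"bh2_{layer}"] = parameter(np.zeros(h))
        p["wc1"] = parameter((h, h), rng)
        p["bc1"] = parameter(np.zeros(h))
        p["wc2"] = parameter((h, 1), rng)
        p["bc2"] = parameter(np.zeros(1))
        p["wa1"] = parameter((2 * h + 1, h), rng)
        p["ba1"] = parameter(np.zeros(h))
        p["wa2"] = parameter((h, 1), rng)
        p["ba2"] = parameter(np.zeros(1))
        self.params = p

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        np.savez(
            path,
            **{k: v.data for k, v in self.params.items()},
            __hidden_dim=self.config.hidden_dim,
            __n_layers=self.config.n_layers,
            __neighbor_cutoff=self.config.neighbor_cutoff,
            __n_rbf=self.config.n_rbf,
            __seed=self.config.seed,
        )

    @classmethod
    def load(cls, path) -> "FlowPredictor":
        blob = np.load(path)
        config = ModelConfig(
            hidden_dim=int(blob["__hidden_dim"]),
            n_layers=int(blob["__n_layers"]),
            neighbor_cutoff=float(blob["__neighbor_cutoff"]),
            n_rbf=int(blob["__n_rbf"]),
            seed=int(blob["__seed"]),
        )
        model = cls(config)
        for k in model.params:
            model.params[k].data = blob[k].astype(np.float64)
        return model

    # -- forward -------------------------------------------------------------
    def make_context(self, graph: LigandGraph, protein: ProteinStructure):
        return ComplexContext(graph, protein)

    def forward(self, context: ComplexContext, coords: np.ndarray, t: float):
        """Differentiable forward pass.

        Returns (coords, confidence, affinity) as autodiff Tensors; coords
        has shape (N_P + N_L, 3), confidence (S_P,) in [0, 1], affinity a
        scalar in pK units.
        """
        cfg = self.config
        p = self.params
        n = context.n_total
        if coords.shape != (n, 3):
            raise ContractError("coordinate/context shape mismatch")

        src, dst, d0 = _radius_edges(
            coords, cfg.neighbor_cutoff, context.bond_edges
        )
        # constant edge features: RBF of the input distance + type flags
        centers = np.linspace(0.0, cfg.neighbor_cutoff, cfg.n_rbf)
        width = cfg.neighbor_cutoff / cfg.n_rbf
        rbf = np.exp(-((d0[:, None] - centers[None, :]) / width) ** 2)
        is_p = np.arange(n) < context.n_protein
        flags = np.zeros((len(src), 4))
        flags[:, 0] = is_p[src] & is_p[dst]
        flags[:, 1] = is_p[src] ^ is_p[dst]
        flags[:, 2] = ~is_p[src] & ~is_p[dst]
        bond_mask = np.array(
            [(a, b) in context.bond_edges for a, b in zip(src, dst)], float
        )
        flags[:, 3] = bond_mask
        edge_const = Tensor(np.concatenate([rbf, flags], axis=1))

        counts = np.maximum(np.bincount(dst, minlength=n), 1).astype(float)
        inv_counts = Tensor(1.0 / counts[:, None])

        node_in = Tensor(
            np.concatenate(
                [context.node_feats, np.full((n, 1), float(t))], axis=1
            )
        )
        h = (node_in @ p["w_in"] + p["b_in"]).silu()
        x = Tensor(np.asarray(coords, dtype=np.float64))

        hd = self.config.hidden_dim
        n_const = edge_const.shape[1]
        for layer in range(cfg.n_layers):
            rel = x.take_rows(dst) - x.take_rows(src)
            dist = rel.norm(axis=1, keepdims=True)  # (E, 1)
            scaled = dist * (1.0 / cfg.neighbor_cutoff)
            # edge MLP evaluated as node-level matmuls plus gathers; the
            # weight rows are laid out as [h_src | h_dst | edge_const | d]
            we1 = p[f"we1_{layer}"]
            w_src = we1.take_rows(np.arange(hd))
            w_dst = we1.take_rows(np.arange(hd, 2 * hd))
            w_const = we1.take_rows(np.arange(2 * hd, 2 * hd + n_const))
            w_dist = we1.take_rows(np.arange(2 * hd + n_const, 2 * hd + n_const + 1))
            pre = (
                (h @ w_src).take_rows(src)
                + (h @ w_dst).take_rows(dst)
                + edge_const @ w_const
                + scaled @ w_dist
                + p[f"be1_{layer}"]
            )
            m = pre.silu()
            m = (m @ p[f"we2_{layer}"] + p[f"be2_{layer}"]).silu()

            gate = m @ p[f"wx_{layer}"] + p[f"bx_{layer}"]  # (E, 1)
            unit = rel / (dist + 1.0)
            delta = (unit * gate).segment_sum(dst, n) * inv_counts
            x = x + delta

            agg = m.segment_sum(dst, n) * inv_counts
            wh1 = p[f"wh1_{layer}"]
            hu = (
                h @ wh1.take_rows(np.arange(hd))
                + agg @ wh1.take_rows(np.arange(hd, 2 * hd))
                + p[f"bh1_{layer}"]
            ).silu()
            hu = hu @ p[f"wh2_{layer}"] + p[f"bh2_{layer}"]
            h = h + hu

        # confidence head: pool atom features per residue
        n_res = context.protein.n_residues
        res_counts = np.bincount(context.atom_to_residue, minlength=n_res)
        h_protein = h.take_rows(np.arange(context.n_protein))
        res_h = h_protein.segment_sum(context.atom_to_residue, n_res) * Tensor(
            1.0 / res_counts[:, None]
        )
        conf = (res_h @ p["wc1"] + p["bc1"]).silu()
        conf = (conf @ p["wc2"] + p["bc2"]).sigmoid().reshape(n_res)

        # affinity head: invariant global readout with an explicit size cue
        lig_idx = np.arange(context.n_protein, n)
        mean_p = h_protein.mean(axis=0, keepdims=True)
        mean_l = h.take_rows(lig_idx).mean(axis=0, keepdims=True)
        size = Tensor(np.array([[context.n_ligand / 10.0]]))
        a_in = concat([mean_p, mean_l, size], axis=1)
        aff = (a_in @ p["wa1"] + p["ba1"]).silu()
        aff = (aff @ p["wa2"] + p["ba2"]).reshape(())

        return x, conf, aff

    def predict(
        self,
        state: ComplexState,
        t: float,
        graph: LigandGraph,
        protein: ProteinStructure,
        context: ComplexContext | None = None,
    ) -> Prediction:
        """Non-differentiable convenience wrapper returning a Prediction."""
        if not 0.0 <= t <= 1.0:
            raise ContractError("t must lie in [0, 1]")
        state.validate_against(protein, graph)
        if context is None:
            context = self.make_context(graph, protein)
        coords = np.concatenate(
            [state.protein_coords, state.ligand_coords], axis=0
        )
        x, conf, aff = self.forward(context, coords, t)
        out = x.data
        return Prediction(
            pred_protein=out[: protein.n_atoms].copy(),
            pred_ligand=out[protein.n_atoms:].copy(),
            confidence=conf.data.copy(),
            affinity_pk=float(aff.data),
        )

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params, lr=lr)


# --------------------------------------------------------------------------
# Confidence labels and head losses
# --------------------------------------------------------------------------

def compute_lddt(
    pred: np.ndarray,
    reference: np.ndarray,
    atom_to_residue: np.ndarray,
    inclusion_radius: float = 15.0,
    thresholds=(0.5, 1.0, 2.0, 4.0),
) -> np.ndarray:
    """Local distance difference test, aggregated per residue.

    For every pair of atoms in *different* residues whose reference
    distance is below ``inclusion_radius``, the absolute change of the
    distance in ``pred`` is scored as the fraction of ``thresholds`` it
    stays within; each residue's score is the mean over the pairs its atoms
    participate in. Ligand atoms may be included by assigning them their
    own residue labels.
    """
    pred = np.asarray(pred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    atom_to_residue = np.asarray(atom_to_residue, dtype=int)
    if pred.shape != reference.shape:
        raise ContractError("coordinate shape mismatch")
    n_res = atom_to_residue.max() + 1
    if n_res < 2:
        raise InputError("lDDT needs at least two residues")

    d_ref = np.sqrt(
        ((reference[:, None] - reference[None, :]) ** 2).sum(axis=2)
    )
    d_pred = np.sqrt(((pred[:, None] - pred[None, :]) ** 2).sum(axis=2))
    diff_res = atom_to_residue[:, None] != atom_to_residue[None, :]
    included = (d_ref < inclusion_radius) & diff_res
    delta = np.abs(d_pred - d_ref)
    pair_score = np.zeros_like(delta)
    for thr in thresholds:
        pair_score += (delta <= thr).astype(float)
    pair_score /= len(thresholds)

    out = np.zeros(n_res)
    for r in range(n_res):
        mask = included[atom_to_residue == r]
        n_pairs = mask.sum()
        out[r] = (
            pair_score[atom_to_residue == r][mask].sum() / n_pairs
            if n_pairs
            else 1.0
        )
    return out


def confidence_head_loss(pred_conf, lddt_labels):
    """Mean squared error between predicted confidence and lDDT labels.

    ``pred_conf`` may be an autodiff Tensor (training) or ndarray.
    """
    labels = np.asarray(lddt_labels, dtype=float)
    if isinstance(pred_conf, Tensor):
        if pred_conf.shape != labels.shape:
            raise ContractError("confidence/label shape mismatch")
        diff = pred_conf - Tensor(labels)
        return (diff * diff).mean()
    pred_conf = np.asarray(pred_conf, dtype=float)
    if pred_conf.shape != labels.shape:
        raise ContractError("confidence/label shape mismatch")
    return float(np.mean((pred_conf - labels) ** 2))


def affinity_head_loss(pred_pk, label_pk, mask: bool = True):
    """Squared error in pK units; unlabeled complexes contribute zero."""
    if not mask or label_pk is None:
        if isinstance(pred_pk, Tensor):
            return pred_pk * 0.0
        return 0.0
    if isinstance(pred_pk, Tensor):
        diff = pred_pk - float(label_pk)
        return diff * diff
    return float(pred_pk - label_pk) ** 2
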