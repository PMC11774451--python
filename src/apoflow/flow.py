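"""Conditional flow matching: the linear conditional path, the regression
loss, and the training loop.

The conditional probability path between a prior draw ``x0`` (noised apo
protein + harmonic ligand) and a data point ``x1`` (noised holo complex) is
the straight-line interpolation ``x_t = (1 - t) x0 + t x1`` with
``t ~ U(0, 1)``. The network is trained as an x1-predictor: the loss
regresses its output at ``(x_t, t)`` directly against the holo target, the
conditional-optimal-transport form of the flow-matching objective on R^3.
Training consumes only pairs that pass the apo-to-holo acceptance filter
(the unbalanced coupling).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .chem import ComplexState
from .coupling import CouplingConfig, accept_pair
from .errors import ContractError, InputError
from .nn.autodiff import Tensor
from .nn.model import (
    FlowPredictor,
    affinity_head_loss,
    compute_lddt,
    confidence_head_loss,
)
from .priors import NoiseConfig, assemble_prior_state, noise_holo_targets

logger = logging.getLogger(__name__)


@dataclass
class PathSample:
    """One training draw on the conditional path."""

    xt: ComplexState
    t: float
    x1_target: ComplexState
    x0_source: ComplexState
    pair_index: int = 0
    pair_label: float | None = None

    def __post_init__(self):
        # the interpolation identity must hold to numerical precision
        for attr in ("protein_coords", "ligand_coords"):
            lhs = getattr(self.xt, attr)
            rhs = (1.0 - self.t) * getattr(self.x0_source, attr) + (
                self.t * getattr(self.x1_target, attr)
            )
            if np.max(np.abs(lhs - rhs)) > 1e-10:
                raise ContractError("xt is not the (1-t) x0 + t x1 interpolant")


@dataclass
class TrainConfig:
    steps: int = 1500
    batch_size: int = 4
    learning_rate: float = 1e-3
    lr_min: float | None = None  # cosine decay floor; None = constant lr
    sigma: float = 1e-4
    seed: int = 0
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    # ligands have far fewer atoms than receptors; upweighting keeps their
    # gradient signal from being diluted by the atom-count ratio
    ligand_weight: float = 4.0
    confidence_weight: float = 0.5
    affinity_weight: float = 0.1
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.steps < 1:
            raise InputError("steps must be >= 1")


def condot_interpolate(x0, x1, t: float):
    """Straight-line interpolant ``(1 - t) x0 + t x1``.

    Accepts either plain coordinate arrays or :class:`ComplexState` objects
    (protein and ligand interpolated jointly).
    """
    if not 0.0 <= t <= 1.0:
        raise ContractError("t must lie in [0, 1]")
    if isinstance(x0, ComplexState):
        if (
            x0.protein_coords.shape != x1.protein_coords.shape
            or x0.ligand_coords.shape != x1.ligand_coords.shape
        ):
            raise ContractError("state shape mismatch")
        return ComplexState(
            protein_coords=(1.0 - t) * x0.protein_coords
            + t * x1.protein_coords,
            ligand_coords=(1.0 - t) * x0.ligand_coords + t * x1.ligand_coords,
            time=t,
        )
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.shape != x1.shape:
        raise ContractError("coordinate shape mismatch")
    return (1.0 - t) * x0 + t * x1


def cfm_loss(pred, target, n_protein: int, ligand_weight: float = 1.0):
    """Flow-matching regression loss ``||v(x_t, t) - x1||^2``.

    Mean of squared coordinate errors over atoms and spatial dimensions,
    with ligand atoms weighted by ``ligand_weight`` relative to protein
    atoms (weighted mean, so the loss is size-invariant and reduces to the
    plain mean squared error at weight 1). ``pred``/``target`` are stacked
    (N_P + N_L, 3) arrays or autodiff Tensors.
    """
    is_tensor = isinstance(pred, Tensor)
    tgt = target.data if isinstance(target, Tensor) else np.asarray(target, float)
    shape = pred.shape if is_tensor else np.asarray(pred).shape
    if shape != tgt.shape:
        raise ContractError("prediction/target shape mismatch")
    if not np.all(np.isfinite(tgt)):
        raise InputError("non-finite target coordinates")
    n_total = shape[0]
    n_ligand = n_total - n_protein
    denom = 3.0 * (n_protein + ligand_weight * n_ligand)
    if is_tensor:
        diff = pred - Tensor(tgt)
        sq = diff * diff
        prot = sq.take_rows(np.arange(n_protein)).sum()
        lig = sq.take_rows(np.arange(n_protein, n_total)).sum()
        return (prot + ligand_weight * lig) / denom
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise InputError("non-finite predicted coordinates")
    sq = (pred - tgt) ** 2
    return float(
        (sq[:n_protein].sum() + ligand_weight * sq[n_protein:].sum()) / denom
    )


def make_training_batch(pairs, config: TrainConfig, rng) -> list:
    """Draw a batch of conditional-path samples from accepted pairs.

    Per element: pick a pair, draw ``t ~ U(0, 1)``, draw an independent
    prior state (the coupling is the filtered independent coupling; no
    minibatch optimal transport), noise the holo target, and interpolate.
    """
    pairs = list(pairs)
    if not pairs:
        raise InputError("no training pairs")
    batch = []
    for _ in range(config.batch_size):
        idx = int(rng.integers(len(pairs)))
        pair = pairs[idx]
        t = float(rng.uniform())
        seed = int(rng.integers(2**31 - 2))
        prior = assemble_prior_state(
            pair.apo, pair.ligand_graph, NoiseConfig(config.sigma, seed)
        )
        holo = ComplexState(
            protein_coords=pair.holo.atom_coords,
            ligand_coords=pair.holo_ligand_coords,
            time=1.0,
        )
        x1 = noise_holo_targets(holo, NoiseConfig(config.sigma, seed + 1))
        xt = condot_interpolate(prior.state, x1, t)
        batch.append(
            PathSample(
                xt=xt,
                t=t,
                x1_target=x1,
                x0_source=prior.state,
                pair_index=idx,
                pair_label=pair.affinity_pk,
            )
        )
    return batch


def _element_loss(model, context, sample: PathSample, config: TrainConfig):
    coords = np.concatenate(
        [sample.xt.protein_coords, sample.xt.ligand_coords], axis=0
    )
    target = np.concatenate(
        [sample.x1_target.protein_coords, sample.x1_target.ligand_coords],
        axis=0,
    )
    x, conf, aff = model.forward(context, coords, sample.t)
    n_protein = context.n_protein
    loss = cfm_loss(x, target, n_protein, config.ligand_weight)

    # confidence labels: lDDT of the predicted structure against the holo
    # target, with each ligand fragment as its own pseudo-residue
    n_res = context.protein.n_residues
    labels_map = np.concatenate(
        [
            context.protein.atom_to_residue,
            n_res + context.graph.fragment_id,
        ]
    )
    lddt = compute_lddt(x.data, target, labels_map)[:n_res]
    loss = loss + config.confidence_weight * confidence_head_loss(conf, lddt)

    loss = loss + config.affinity_weight * affinity_head_loss(
        aff, sample.pair_label, mask=sample.pair_label is not None
    )
    return loss


def train(dataset, model: FlowPredictor, config: TrainConfig):
    """Train the flow network on accepted apo/holo pairs.

    Pairs failing the acceptance filter are silently excluded, so the loss
    history depends only on the accepted subset. Fully seed-deterministic
    on CPU. Returns ``(model, loss_history)``; a checkpoint is written once
    per epoch when ``config.checkpoint_dir`` is set (one epoch =
    ``ceil(n_pairs / batch_size)`` steps).

    Raises
    ------
    RuntimeError
        If the loss becomes non-finite (divergence).
    """
    dataset = list(dataset)
    if not dataset:
        raise InputError("empty dataset")
    accepted = []
    for pair in dataset:
        ok, _ = accept_pair(pair, config.coupling)
        if ok:
            accepted.append(pair)
    if not accepted:
        raise InputError("no pairs pass the acceptance filter")
    logger.info("training on %d/%d accepted pairs", len(accepted), len(dataset))

    contexts = [model.make_context(p.ligand_graph, p.apo) for p in accepted]
    rng = np.random.default_rng(config.seed)
    optimizer = model.make_optimizer(config.learning_rate)
    epoch_steps = max(1, -(-len(accepted) // config.batch_size))

    history = []
    for step in range(config.steps):
        if config.lr_min is not None:
            frac = step / max(config.steps - 1, 1)
            optimizer.lr = config.lr_min + 0.5 * (
                config.learning_rate - config.lr_min
            ) * (1.0 + np.cos(np.pi * frac))
        batch = make_training_batch(accepted, config, rng)
        optimizer.zero_grad()
        total = None
        for sample in batch:
            loss = _element_loss(
                model, contexts[sample.pair_index], sample, config
            )
            total = loss if total is None else total + loss
        total = total / float(len(batch))
        value = total.item()
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at step {step}: loss = {value}"
            )
        total.backward()
        optimizer.step()
        history.append(value)
        if config.checkpoint_dir and (step + 1) % epoch_steps == 0:
            os.makedirs(config.checkpoint_dir, exist_ok=True)
            model.save(
                os.path.join(config.checkpoint_dir, "checkpoint_last.npz")
            )
        if step % 100 == 0:
            logger.info("step %d loss %.4f", step, value)
    return model, history
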