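"""VD-ODE / Euler integration, ranked generation, symmetry-corrected RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from apoflow.chem import parse_smiles
from apoflow.errors import ContractError, InputError
from apoflow.fixtures import ToyComplexSpec, make_toy_complex
from apoflow.nn.model import FlowPredictor, ModelConfig, Prediction
from apoflow.sampling import (
    SamplerConfig,
    euler_step,
    generate,
    ligand_rmsd_to_reference,
    vd_ode_step,
)


class ConstantOracle:
    """Stand-in model whose holo estimate is a fixed structure plus
    optional per-call noise — used to exercise the solvers in isolation."""

    def __init__(self, holo_coords, n_protein, noise=0.0, seed=0):
        self.holo = np.asarray(holo_coords, float)
        self.n_protein = n_protein
        self.noise = noise
        self.rng = np.random.default_rng(seed)

    def make_context(self, graph, protein):
        return None

    def predict(self, state, t, graph, protein, context=None):
        out = self.holo + self.noise * self.rng.standard_normal(self.holo.shape)
        conf = np.full(protein.n_residues, 0.5)
        return Prediction(
            pred_protein=out[: self.n_protein],
            pred_ligand=out[self.n_protein:],
            confidence=conf,
            affinity_pk=5.0,
        )


# --------------------------------------------------------------------------
# single steps
# --------------------------------------------------------------------------

def test_vd_ode_hand_derived_two_step(rng):
    # i = 2: first step is the exact midpoint, second lands on the
    # prediction up to the 1e-6 clamp
    config = SamplerConfig(n_steps=2, eta=1.0, n_samples=1)
    x0 = rng.standard_normal((5, 3))
    pred = rng.standard_normal((5, 3))
    x1 = vd_ode_step(x0, pred, 0, config)
    np.testing.assert_allclose(x1, 0.5 * x0 + 0.5 * pred, rtol=0, atol=1e-15)
    x2 = vd_ode_step(x1, pred, 1, config)
    np.testing.assert_allclose(x2, 1e-6 * x1 + (1 - 1e-6) * pred, atol=1e-15)
    np.testing.assert_allclose(x2, pred, rtol=1e-5, atol=1e-5)


def test_vd_ode_fixed_point(rng):
    config = SamplerConfig(n_steps=7)
    x = rng.standard_normal((4, 3))
    for n in range(7):
        np.testing.assert_allclose(vd_ode_step(x, x, n, config), x, atol=1e-12)


def test_vd_ode_coefficients_sum_to_eta():
    for i in (2, 5, 40):
        config = SamplerConfig(n_steps=i, eta=1.0)
        for n in range(i):
            t, s = n / i, (n + 1) / i
            r = (1 - s) / (1 - t)
            assert r + (1 - r) == pytest.approx(config.eta)
            # with eta = 1 each update is a convex combination
            x = np.array([[0.0, 0, 0]])
            pred = np.array([[1.0, 1.0, 1.0]])
            out = vd_ode_step(x, pred, n, config)
            assert np.all(out >= -1e-9) and np.all(out <= 1 + 1e-9)


def test_euler_constant_oracle_straight_line(rng):
    # with pred always equal to x1, Euler telescopes onto the exact
    # straight-line path and lands on x1 at the final step
    config = SamplerConfig(n_steps=10, solver="euler")
    x0 = rng.standard_normal((6, 3))
    x1 = rng.standard_normal((6, 3))
    x = x0.copy()
    for n in range(10):
        x = euler_step(x, x1, n, config)
        expected = x0 + (n + 1) / 10 * (x1 - x0)
        np.testing.assert_allclose(x, expected, atol=1e-10)
    np.testing.assert_allclose(x, x1, atol=1e-10)


def test_euler_single_step_and_stationary(rng):
    x = rng.standard_normal((3, 3))
    pred = rng.standard_normal((3, 3))
    np.testing.assert_allclose(
        euler_step(x, pred, 0, SamplerConfig(n_steps=1, solver="euler")), pred
    )
    np.testing.assert_allclose(
        euler_step(x, x, 2, SamplerConfig(n_steps=5, solver="euler")), x
    )


def test_step_contract_errors(rng):
    x = rng.standard_normal((2, 3))
    with pytest.raises(ContractError):
        vd_ode_step(x, x, 5, SamplerConfig(n_steps=5))
    with pytest.raises(ContractError):
        euler_step(x, x, -1, SamplerConfig(n_steps=5))
    with pytest.raises(InputError):
        SamplerConfig(n_steps=0)
    with pytest.raises(InputError):
        SamplerConfig(solver="rk4")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def test_generate_ranking_and_shapes(toy_pair):
    model = FlowPredictor(ModelConfig(seed=0, hidden_dim=16, n_layers=1))
    config = SamplerConfig(n_steps=5, n_samples=5, seed=0)
    trajs = generate(model, toy_pair.apo, toy_pair.ligand_graph, config)
    assert len(trajs) == 5
    confs = [tr.final.mean_confidence for tr in trajs]
    assert confs == sorted(confs, reverse=True)
    for tr in trajs:
        assert len(tr.states) == 6
        assert tr.states[0].time == 0.0 and tr.states[-1].time == 1.0


def test_generate_constant_oracle_contracts_to_holo(toy_pair):
    holo = np.concatenate(
        [toy_pair.holo.atom_coords, toy_pair.holo_ligand_coords]
    )
    oracle = ConstantOracle(holo, toy_pair.holo.n_atoms)
    config = SamplerConfig(n_steps=40, n_samples=2, seed=1)
    trajs = generate(oracle, toy_pair.apo, toy_pair.ligand_graph, config)
    for tr in trajs:
        np.testing.assert_allclose(
            tr.final_state.protein_coords, toy_pair.holo.atom_coords, atol=1e-5
        )
        np.testing.assert_allclose(
            tr.final_state.ligand_coords, toy_pair.holo_ligand_coords, atol=1e-5
        )


def test_generate_deterministic_under_seed(toy_pair):
    model = FlowPredictor(ModelConfig(seed=0, hidden_dim=16, n_layers=1))
    config = SamplerConfig(n_steps=4, n_samples=3, seed=11)
    a = generate(model, toy_pair.apo, toy_pair.ligand_graph, config)
    b = generate(model, toy_pair.apo, toy_pair.ligand_graph, config)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(
            ta.final_state.ligand_coords, tb.final_state.ligand_coords
        )
        assert ta.final.affinity_pk == tb.final.affinity_pk


def test_variance_diminishing_vs_euler(toy_pair):
    # the VD-ODE's defining property: under a noisy oracle the spread of
    # final states is strictly smaller than Euler's
    holo = np.concatenate(
        [toy_pair.holo.atom_coords, toy_pair.holo_ligand_coords]
    )
    n_protein = toy_pair.holo.n_atoms
    finals = {}
    for solver in ("vd_ode", "euler"):
        outs = []
        for rep in range(200):
            oracle = ConstantOracle(holo, n_protein, noise=0.5, seed=rep)
            config = SamplerConfig(
                n_steps=10, n_samples=1, seed=0, solver=solver
            )
            trajs = generate(
                oracle, toy_pair.apo, toy_pair.ligand_graph, config
            )
            outs.append(
                np.concatenate(
                    [
                        trajs[0].final_state.protein_coords,
                        trajs[0].final_state.ligand_coords,
                    ]
                )
            )
        finals[solver] = np.var(np.stack(outs), axis=0).mean()
    assert finals["vd_ode"] < finals["euler"]


# --------------------------------------------------------------------------
# symmetry-corrected RMSD
# --------------------------------------------------------------------------

def test_ligand_rmsd_basics():
    graph, coords = parse_smiles("CCO", seed=0)
    assert ligand_rmsd_to_reference(coords, coords, graph) == 0.0
    shifted = coords + np.array([2.0, 0, 0])
    assert ligand_rmsd_to_reference(shifted, coords, graph) == pytest.approx(2.0)
    with pytest.raises(ContractError):
        ligand_rmsd_to_reference(coords[:2], coords, graph)


def test_ligand_rmsd_symmetry_correction():
    # a regular 6-ring rotated by one position is chemically identical
    graph, _ = parse_smiles("c1ccccc1", seed=0)
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    ring = np.column_stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)])
    rotated = np.roll(ring, 1, axis=0)
    naive = np.sqrt(np.mean(np.sum((rotated - ring) ** 2, axis=1)))
    assert naive > 1.0
    assert ligand_rmsd_to_reference(rotated, ring, graph) == pytest.approx(0.0, abs=1e-12)
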