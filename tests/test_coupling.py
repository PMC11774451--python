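"""Weighted alignment, TM-score, RMSD and the apo-holo acceptance rule."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from apoflow.coupling import (
    CouplingConfig,
    accept_pair,
    ca_rmsd,
    coupling_decision,
    curate_dataset,
    ligand_proximity_weights,
    tm_score,
    weighted_kabsch_align,
)
from apoflow.errors import ContractError, DegeneracyError, InputError
from apoflow.fixtures import ToyComplexSpec, make_toy_complex


def _plain_kabsch(mobile, target):
    """Independent unweighted Kabsch oracle."""
    mm, mt = mobile.mean(0), target.mean(0)
    h = (mobile - mm).T @ (target - mt)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mt - r @ mm


# --------------------------------------------------------------------------
# weighted Kabsch
# --------------------------------------------------------------------------

def test_kabsch_identity(rng):
    pts = rng.standard_normal((10, 3))
    aln = weighted_kabsch_align(pts, pts, rng.uniform(0.1, 1.0, 10))
    np.testing.assert_allclose(aln.rotation, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(aln.translation, 0.0, atol=1e-10)
    assert aln.weighted_rmsd == pytest.approx(0.0, abs=1e-10)


def test_kabsch_exact_recovery(rng):
    mobile = rng.standard_normal((12, 3))
    rot = Rotation.random(rng=rng).as_matrix()
    shift = np.array([1.0, -2.0, 0.5])
    target = mobile @ rot.T + shift
    aln = weighted_kabsch_align(mobile, target, np.ones(12))
    np.testing.assert_allclose(aln.rotation, rot, atol=1e-6)
    assert aln.weighted_rmsd < 1e-6


def test_uniform_weights_equal_classical_kabsch(rng):
    for _ in range(100):
        mobile = rng.standard_normal((8, 3))
        target = rng.standard_normal((8, 3))
        aln = weighted_kabsch_align(mobile, target, np.ones(8))
        r, t = _plain_kabsch(mobile, target)
        np.testing.assert_allclose(aln.rotation, r, atol=1e-8)
        np.testing.assert_allclose(aln.translation, t, atol=1e-8)


def test_weighted_objective_beats_random_search(rng):
    # random-rotation-search oracle on the weighted objective
    for _ in range(3):
        mobile = rng.standard_normal((10, 3))
        target = rng.standard_normal((10, 3))
        w = rng.uniform(0.05, 1.0, 10)
        w = w / w.sum()
        aln = weighted_kabsch_align(mobile, target, w)
        obj = np.sum(w * np.sum((aln.transform(mobile) - target) ** 2, axis=1))
        rots = Rotation.random(5000, rng=rng)
        mu_m, mu_t = w @ mobile, w @ target
        best = np.inf
        for rot in rots:
            moved = rot.apply(mobile - mu_m) + mu_t
            best = min(best, np.sum(w * np.sum((moved - target) ** 2, axis=1)))
        assert obj <= best + 1e-9


def test_kabsch_degeneracies(rng):
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegeneracyError):
        weighted_kabsch_align(line, line + 1.0, np.ones(5))
    pts = rng.standard_normal((5, 3))
    with pytest.raises(DegeneracyError):
        weighted_kabsch_align(pts[:2], pts[:2], np.ones(2))
    w = np.zeros(5)
    w[:2] = 1.0
    with pytest.raises(DegeneracyError):
        weighted_kabsch_align(pts, pts, w)
    with pytest.raises(InputError):
        weighted_kabsch_align(pts, pts, np.zeros(5))


# --------------------------------------------------------------------------
# weights, RMSD, TM-score
# --------------------------------------------------------------------------

def test_proximity_weights():
    ca = np.array([[0.0, 0, 0], [0, 0, 5.0]])
    ligand = np.array([[0.0, 0, 0]])
    w = ligand_proximity_weights(ca, ligand, tau=5.0)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert w[0] / w[1] == pytest.approx(np.e)

    # equidistant residues get uniform weights
    ca = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    w = ligand_proximity_weights(ca, np.zeros((1, 3)))
    np.testing.assert_allclose(w, 1.0 / 3.0)

    with pytest.raises(InputError):
        ligand_proximity_weights(ca, np.zeros((0, 3)))


def test_ca_rmsd():
    a = np.zeros((4, 3))
    assert ca_rmsd(a, a) == 0.0
    assert ca_rmsd(a, a + [3.0, 0, 0]) == pytest.approx(3.0)
    # hand-computed two-point case: sqrt((1 + 1) / 2) = 1
    x = np.array([[0.0, 0, 0], [0.0, 0, 0]])
    y = np.array([[1.0, 0, 0], [0, 1.0, 0]])
    assert ca_rmsd(x, y) == pytest.approx(1.0)
    with pytest.raises(ContractError):
        ca_rmsd(a, a[:2])


def test_tm_score_identity(rng):
    pts = rng.standard_normal((30, 3)) * 5
    assert tm_score(pts, pts) == pytest.approx(1.0)


def test_tm_score_rigid_motion_invariance(rng):
    pts = rng.standard_normal((25, 3)) * 4
    noisy = pts + 0.5 * rng.standard_normal(pts.shape)
    base = tm_score(noisy, pts)
    for _ in range(50):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.standard_normal(3) * 10
        assert tm_score(noisy @ rot.T + shift, pts @ rot.T + shift) == pytest.approx(
            base, abs=1e-6
        )


def test_tm_score_matches_superposition_search_oracle(rng):
    # independent oracle: generic numerical maximization of the TM sum
    # over all 6 rigid-motion parameters from many random starts
    from scipy.optimize import minimize

    d0 = 0.5  # short chain: floored

    def neg_tm(params, mobile, target):
        rot = Rotation.from_rotvec(params[:3])
        moved = rot.apply(mobile) + params[3:]
        d = np.linalg.norm(moved - target, axis=1)
        return -np.mean(1.0 / (1.0 + (d / d0) ** 2))

    for _ in range(3):
        target = rng.standard_normal((8, 3)) * 3
        mobile = target + 0.6 * rng.standard_normal(target.shape)
        ours = tm_score(mobile, target)
        best = 0.0
        starts = [np.zeros(6)] + [
            np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.uniform(-3, 3, 3)])
            for _ in range(40)
        ]
        for x0 in starts:
            res = minimize(
                neg_tm, x0, args=(mobile, target), method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10},
            )
            best = max(best, -res.fun)
        assert ours == pytest.approx(best, abs=0.01)


# --------------------------------------------------------------------------
# acceptance rule
# --------------------------------------------------------------------------

@pytest.mark.parametrize("tm", [0.69, 0.70, 0.71])
@pytest.mark.parametrize("rmsd", [4.99, 5.00, 5.01])
def test_acceptance_boundary_semantics(tm, rmsd):
    accepted, reason = coupling_decision(tm, rmsd, 100, 20)
    expected = (tm >= 0.7) and (rmsd < 5.0)
    assert accepted is expected
    if tm < 0.7:
        assert reason == "tm_below_min"


def test_acceptance_monotone(rng):
    # tightening thresholds never converts rejected -> accepted
    for _ in range(200):
        tm = rng.uniform(0.3, 1.0)
        rmsd = rng.uniform(0.0, 8.0)
        loose = coupling_decision(tm, rmsd, 50, 10, CouplingConfig(0.7, 5.0))[0]
        tight = coupling_decision(tm, rmsd, 50, 10, CouplingConfig(0.8, 4.0))[0]
        assert not (tight and not loose)


def test_accept_pair_on_fixture(toy_pair):
    ok, metrics = accept_pair(toy_pair)
    assert ok
    assert 0.7 <= metrics["tm"] <= 1.0
    assert metrics["ca_rmsd"] < 5.0


def test_accept_pair_rejects_large_hinge():
    pair = make_toy_complex(ToyComplexSpec(seed=3, hinge_angle=60.0))
    ok, metrics = accept_pair(pair)
    assert not ok
    assert metrics["tm"] < 0.7


def test_curate_dataset_categories():
    ok = make_toy_complex(ToyComplexSpec(seed=1))
    tm_fail = make_toy_complex(ToyComplexSpec(seed=2, hinge_angle=60.0))
    gap = make_toy_complex(ToyComplexSpec(seed=3))
    gap.full_sequence = gap.full_sequence[:-1]  # declared sequence longer? no: resolved longer
    manifest = curate_dataset([ok, tm_fail, gap])
    assert list(manifest["reject_reason"]) == ["", "tm_below_min", "sequence_gap"]
    assert list(manifest["accepted"]) == [True, False, False]

    # determinism: rerun is byte-identical
    again = curate_dataset(
        [
            make_toy_complex(ToyComplexSpec(seed=1)),
            make_toy_complex(ToyComplexSpec(seed=2, hinge_angle=60.0)),
        ]
    )
    once = curate_dataset(
        [
            make_toy_complex(ToyComplexSpec(seed=1)),
            make_toy_complex(ToyComplexSpec(seed=2, hinge_angle=60.0)),
        ]
    )
    assert again.to_csv() == once.to_csv()


def test_curate_empty():
    manifest = curate_dataset([])
    assert len(manifest) == 0
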