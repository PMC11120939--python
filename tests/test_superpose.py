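"""Superposition, RMSD, GDT and comparison-matrix behaviour.

Independent oracles: an exhaustive rotation-grid search (2-degree Euler
steps) for Kabsch optimality on tiny instances, Biopython's
SVDSuperimposer for RMSD agreement on random pairs, and the closed-form
noise expectation E[d^2] = 3*sigma^2 for calibration.
"""

import numpy as np
import pytest
from Bio.PDB.Superimposer import SVDSuperimposer
from scipy.spatial.transform import Rotation
from scipy.stats import median_test

from aoskit import (
    ValidationError,
    distance_profile,
    gdt_curve,
    iterative_weighted_superpose,
    kabsch_superpose,
    make_coil,
    make_helix,
    pair_residues,
    pairwise_matrix,
    perturb,
    truncate_and_refold,
)
from aoskit.superpose import DEFAULT_GDT_THRESHOLDS


def grid_best_rmsd(a, b, step_deg=2.0):
    """Brute-force minimum RMSD over a dense Euler-angle rotation grid.

    Uses the identity rmsd^2 = (|a_c|^2 + |b_c|^2 - 2 tr(R H)) / n on
    centered coordinates, so only the 3x3 trace term varies per rotation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = bc.T @ ac
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    best_trace = -np.inf
    rz = Rotation.from_euler("z", angles[:, None]).as_matrix()  # (A,3,3)
    ry = Rotation.from_euler("y", half[:, None]).as_matrix()    # (B,3,3)
    for rz1 in rz:
        m = np.einsum("bij,jk->bik", ry, rz1 @ H)          # Ry @ Rz1 @ H
        traces = np.einsum("aij,bji->ab", rz, m)           # tr(Rz2 Ry Rz1 H)
        best_trace = max(best_trace, traces.max())
    n = len(a)
    ss = (ac**2).sum() + (bc**2).sum()
    return float(np.sqrt(max(ss - 2.0 * best_trace, 0.0) / n))


class TestPairing:
    def test_wild_type_vs_frameshift_lengths(self):
        # 1444-residue wild type vs 756-residue truncated variant
        a, b = make_helix(1444), make_helix(756)
        corr = pair_residues(a, b)
        assert corr.n_pairs == 756
        assert corr.unpaired_tail == 688

    def test_equal_lengths(self):
        corr = pair_residues(make_helix(10), make_helix(10))
        assert (corr.n_pairs, corr.unpaired_tail) == (10, 0)

    def test_unpaired_tail(self):
        assert pair_residues(make_helix(5), make_helix(3)).unpaired_tail == 2


class TestKabsch:
    def test_rigid_copy_has_zero_rmsd(self, rng):
        a = rng.normal(size=(50, 3)) * 10
        R = Rotation.random(rng=rng).as_matrix()
        b = a @ R.T + np.array([4.0, -2.0, 9.0])
        res = kabsch_superpose(a, b)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_hand_value(self):
        # centered residuals are (+-0.5 vs +-1): optimal rmsd 0.5
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        res = kabsch_superpose(a, b)
        assert res.rmsd == pytest.approx(0.5, abs=1e-9)
        assert not res.unique

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_beats_rotation_grid_oracle(self, n, rng):
        a = rng.normal(size=(n, 3)) * 5
        b = perturb_coords(a, rng, sigma=0.7)
        assert kabsch_superpose(a, b).rmsd <= grid_best_rmsd(a, b) + 1e-3

    def test_agrees_with_biopython_superimposer(self, rng):
        for _ in range(5):
            a = rng.normal(size=(40, 3)) * 8
            b = rng.normal(size=(40, 3)) * 8
            sup = SVDSuperimposer()
            sup.set(a, b)
            sup.run()
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                float(sup.get_rms()), abs=1e-8
            )

    def test_rigid_transform_invariance(self, rng):
        a = rng.normal(size=(30, 3)) * 6
        b = rng.normal(size=(30, 3)) * 6
        base = kabsch_superpose(a, b).rmsd
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-50, 50, 3)
            assert kabsch_superpose(a, b @ R.T + t).rmsd == pytest.approx(
                base, abs=1e-6
            )

    def test_single_point_and_empty(self):
        res = kabsch_superpose(np.zeros((1, 3)), np.ones((1, 3)))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert not res.unique
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((0, 3)), np.zeros((0, 3)))


def perturb_coords(a, rng, sigma):
    R = Rotation.random(rng=rng).as_matrix()
    return a @ R.T + rng.uniform(-5, 5, 3) + rng.normal(scale=sigma,
                                                        size=a.shape)


class TestIterativeWeighted:
    def test_identical_structures_converge_immediately(self):
        t = make_helix(80)
        res = iterative_weighted_superpose(t, t)
        assert res.iterations == 1
        assert res.converged
        assert res.weighted_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_planted_outlier_is_downweighted(self):
        t = make_helix(100)
        shifted = t.coords.copy()
        shifted[50] += np.array([50.0, 0.0, 0.0])
        res = iterative_weighted_superpose(t.coords, shifted)
        assert res.weights[50] < 0.05
        assert res.weighted_rmsd < res.rmsd
        assert res.converged

    def test_equal_distances_reduce_to_plain_kabsch(self):
        # pure translation: every pair distance equal -> weights equal
        t = make_helix(60)
        moved = t.coords + np.array([3.0, 0.0, 0.0])
        res = iterative_weighted_superpose(t.coords, moved)
        plain = kabsch_superpose(t.coords, moved)
        assert np.allclose(res.weights, res.weights[0])
        np.testing.assert_allclose(res.rotation, plain.rotation, atol=1e-9)
        assert res.weighted_rmsd == pytest.approx(plain.rmsd, abs=1e-9)

    def test_nonconvergence_reported_not_raised(self):
        a = make_coil(200, seed=1).coords
        b = make_coil(200, seed=2).coords
        res = iterative_weighted_superpose(a, b, tol=0.0, max_iter=3)
        assert res.iterations == 3
        assert not res.converged


class TestNoiseCalibration:
    def test_rmsd_matches_sigma_sqrt3(self):
        """iid Gaussian noise sigma=1 per coordinate on 2000 residues:
        E[d^2] = 3 sigma^2, so the unfitted rmsd is sigma*sqrt(3) +- 5%."""
        t = make_helix(2000)
        noisy = perturb(t, sigma=1.0, rigid=False, seed=11)
        d = distance_profile(t, noisy, refit=False)
        rmsd = float(np.sqrt((d**2).mean()))
        assert rmsd == pytest.approx(np.sqrt(3.0), rel=0.05)


class TestGdt:
    def test_identical_traces_fit_everywhere(self):
        t = make_helix(50)
        curve = gdt_curve(t, t)
        assert np.all(curve.fit_fraction == 1.0)
        assert np.all(curve.difference_fraction == 0.0)

    def test_half_displaced_without_refit(self):
        t = make_helix(100)
        moved = t.coords.copy()
        moved[50:] += np.array([10.0, 0.0, 0.0])
        d = distance_profile(t, _as_trace(moved), refit=False)
        assert np.mean(d <= 5.0) == pytest.approx(0.5)

    def test_threshold_above_max_distance_gives_one(self):
        t = make_helix(40)
        noisy = perturb(t, sigma=0.5, rigid=True, seed=3)
        d = distance_profile(t, noisy)
        curve = gdt_curve(t, noisy, thresholds=[float(d.max()) + 1.0])
        assert curve.fit_fraction[-1] == 1.0

    def test_monotone_and_bounded_on_random_pairs(self, rng):
        for i in range(20):
            n = int(rng.integers(10, 120))
            a = make_coil(n, seed=100 + i)
            b = make_coil(n, seed=200 + i)
            curve = gdt_curve(a, b)
            assert np.all(np.diff(curve.fit_fraction) >= 0)
            assert np.all((curve.fit_fraction >= 0) & (curve.fit_fraction <= 1))

    def test_default_grid_includes_quoted_threshold(self):
        assert 2.5 in DEFAULT_GDT_THRESHOLDS
        assert set(range(1, 21)) <= set(DEFAULT_GDT_THRESHOLDS)

    def test_empty_grid_rejected(self):
        t = make_helix(10)
        with pytest.raises(ValidationError):
            gdt_curve(t, t, thresholds=[])


def _as_trace(coords):
    from aoskit import CaTrace

    n = len(coords)
    return CaTrace("tmp", np.arange(1, n + 1), ["ALA"] * n, coords)


class TestDistanceProfile:
    def test_identical_all_zero(self):
        t = make_helix(30)
        assert np.allclose(distance_profile(t, t), 0.0)

    def test_translation_absorbed_by_refit(self):
        t = make_helix(30)
        moved = _as_trace(t.coords + np.array([3.0, 0.0, 0.0]))
        assert np.allclose(distance_profile(t, moved), 0.0, atol=1e-9)
        assert np.allclose(distance_profile(t, moved, refit=False), 3.0)

    def test_native_prefix_closer_than_refolded_tail(self):
        """Truncate-and-refold emulation: distances over the shared native
        prefix are statistically smaller than over the divergent tail."""
        wt = perturb(make_helix(400), sigma=0.3, rigid=False, seed=5,
                     model_id="wt")
        variant = truncate_and_refold(wt, point=201, tail_length=200, seed=6)
        d = distance_profile(wt, variant)
        prefix, tail = d[:200], d[200:]
        stat, p, *_ = median_test(prefix, tail)
        assert np.median(prefix) < np.median(tail)
        assert p < 0.05


class TestPairwiseMatrix:
    def test_six_structures_fifteen_tests(self):
        traces = [perturb(make_helix(60), sigma=1.0, seed=k,
                          model_id=f"m{k}") for k in range(6)]
        m = pairwise_matrix(traces)
        assert m.n_pairs == 15
        off_diag = m.rmsd[np.triu_indices(6, 1)]
        assert len(off_diag) == 15

    def test_two_structures_one_pair(self):
        traces = [make_helix(20, model_id="a"),
                  perturb(make_helix(20), sigma=1.0, seed=1, model_id="b")]
        assert pairwise_matrix(traces).n_pairs == 1

    def test_symmetry_and_zero_diagonal(self, rng):
        traces = [perturb(make_coil(40, seed=9), sigma=1.0, seed=k,
                          model_id=f"t{k}") for k in range(4)]
        m = pairwise_matrix(traces)
        np.testing.assert_allclose(m.rmsd, m.rmsd.T, atol=1e-6)
        np.testing.assert_allclose(m.weighted_rmsd, m.weighted_rmsd.T,
                                   atol=1e-6)
        assert np.all(np.diag(m.rmsd) == 0.0)

    def test_duplicate_labels_rejected(self):
        t = make_helix(10)
        with pytest.raises(ValidationError, match="duplicate"):
            pairwise_matrix([t, t])

    def test_single_trace_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_matrix([make_helix(10)])
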