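"""Sampling, PIC deposition, signatures and the transportation EMD."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, wasserstein_distance

from tetherswarm.cli import make_fixture
from tetherswarm.compare import (
    Signature,
    compare_micro_macro,
    emd,
    freedman_diaconis_bins,
    make_signature,
    optimal_grid_spacing,
    pic_density,
    sample_points,
)


class TestSamplePoints:
    def test_uniform_density_passes_chi_square(self):
        rng = np.random.default_rng(0)
        pts = sample_points(np.ones((32, 32)), 10_000, rng)
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                      bins=[10, 10], range=[[0, 1], [0, 1]])
        _, pval = chisquare(counts.ravel())
        assert pval > 0.01

    def test_concentrated_density_lands_in_cell(self):
        rho = np.zeros((16, 16))
        rho[3, 11] = 1.0
        rng = np.random.default_rng(1)
        pts = sample_points(rho, 200, rng)
        h = 1 / 16
        assert np.all((pts[:, 0] >= 3 * h) & (pts[:, 0] < 4 * h))
        assert np.all((pts[:, 1] >= 11 * h) & (pts[:, 1] < 12 * h))

    def test_seed_determinism(self):
        rho = np.ones((8, 8))
        a = sample_points(rho, 50, np.random.default_rng(3))
        b = sample_points(rho, 50, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestPicDensity:
    def test_point_at_cell_centre(self):
        rho = pic_density(np.array([[0.05, 0.25]]), 0.1)
        assert rho[0, 2] == pytest.approx(1 / 0.1**2, rel=1e-12)
        assert np.count_nonzero(rho) == 1

    def test_unit_mass_for_any_cloud(self, rng):
        pts = rng.uniform(0, 1, (137, 2))
        rho = pic_density(pts, 1 / 13)
        assert rho.sum() * (1 / 13) ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_point_deposition_loop(self, rng):
        pts = rng.uniform(0, 1, (100, 2))
        h, Nh = 1 / 12, 12
        fast = pic_density(pts, h)
        slow = np.zeros((Nh, Nh))
        for x, y in pts:
            ux, uy = x / h - 0.5, y / h - 0.5
            ix, iy = math.floor(ux), math.floor(uy)
            wx, wy = ux - ix, uy - iy
            for dx_, fx in ((0, 1 - wx), (1, wx)):
                for dy_, fy in ((0, 1 - wy), (1, wy)):
                    slow[(ix + dx_) % Nh, (iy + dy_) % Nh] += fx * fy
        slow /= 100 * h * h
        assert np.max(np.abs(fast - slow)) < 1e-12

    def test_non_divisor_spacing_rejected(self):
        with pytest.raises(ValueError):
            pic_density(np.zeros((1, 2)), 0.3)


class TestOptimalGrid:
    def test_finer_grids_for_more_points_on_clustered_density(self):
        rho = make_fixture("clustered", seed=0, nx=64)
        hs = []
        for N in (200, 2000, 20000):
            res = optimal_grid_spacing(rho, N, rng=np.random.default_rng(0))
            hs.append(res.h_tilde)
        assert hs[0] >= hs[1] >= hs[2]
        assert hs[0] > hs[2]

    def test_error_curve_u_shaped_for_clustered_density(self):
        rho = make_fixture("clustered", seed=1, nx=64)
        res = optimal_grid_spacing(rho, 2000, rng=np.random.default_rng(1))
        errs = res.l2_curve[:, 1]
        imin = int(np.argmin(errs))
        assert 0 < imin < len(errs) - 1      # interior minimum

    def test_smooth_density_prefers_coarser_grids(self):
        smooth = make_fixture("banded", seed=0, nx=64)
        clustered = make_fixture("clustered", seed=0, nx=64)
        h_smooth = optimal_grid_spacing(
            smooth, 2000, rng=np.random.default_rng(2)).h_tilde
        h_clustered = optimal_grid_spacing(
            clustered, 2000, rng=np.random.default_rng(2)).h_tilde
        assert h_smooth > h_clustered

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            optimal_grid_spacing(np.ones((16, 16)), 100, candidate_h=[])


class TestSignature:
    def test_hand_counted_example(self):
        sig = make_signature(np.array([[0.5, 1.5], [2.5, 3.5]]), 2)
        assert np.allclose(sig.points, [1.75, 3.5])
        assert np.array_equal(sig.weights, [2, 2])

    def test_constant_field_single_occupied_bin(self):
        sig = make_signature(np.full((6, 6), 2.0))
        assert sig.weights.sum() == 36
        assert np.count_nonzero(sig.weights) == 1

    def test_weights_partition_grid_cells(self, rng):
        rho = rng.uniform(0.1, 5.0, (20, 20))
        sig = make_signature(rho)
        assert sig.weights.sum() == rho.size
        assert sig.points[-1] == pytest.approx(rho.max())

    def test_freedman_diaconis_variant_flag(self, rng):
        vals = rng.uniform(0, 1, 400)
        standard = freedman_diaconis_bins(vals)
        variant = freedman_diaconis_bins(vals, exponent=1.5)
        # n^{3/2} in the denominator makes the widths much narrower
        assert variant > standard

    def test_invalid_signature_rejected(self):
        with pytest.raises(ValueError):
            Signature(points=np.array([2.0, 1.0]), weights=np.array([1, 1]))
        with pytest.raises(ValueError):
            Signature(points=np.array([1.0, 2.0]), weights=np.array([1, -1]))


class TestEMD:
    def test_identity(self):
        P = Signature(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert emd(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_single_unit_mass_moved(self):
        P = Signature(np.array([1e-12]), np.array([1.0]))
        Q = Signature(np.array([5.0]), np.array([1.0]))
        assert emd(P, Q) == pytest.approx(5.0, rel=1e-9)

    def test_two_sources_one_sink_hand_lp(self):
        # flows of 1 from 0 and from 10 into 5: total cost 10, flow 2
        P = Signature(np.array([1e-12, 10.0]), np.array([1.0, 1.0]))
        Q = Signature(np.array([5.0]), np.array([2.0]))
        assert emd(P, Q) == pytest.approx(5.0, rel=1e-9)

    def _random_balanced(self, rng, total=None):
        m = int(rng.integers(2, 10))
        p = np.sort(rng.uniform(0, 10, m)) + np.arange(m) * 1e-9
        w = rng.integers(1, 20, m).astype(float)
        if total is not None:
            w *= total / w.sum()
        return Signature(p, w)

    def test_matches_closed_form_wasserstein_on_balanced_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            P = self._random_balanced(rng, total=37.0)
            Q = self._random_balanced(rng, total=37.0)
            oracle = wasserstein_distance(P.points, Q.points,
                                          P.weights, Q.weights)
            assert emd(P, Q) == pytest.approx(oracle, abs=1e-8)

    def test_metric_axioms_on_balanced_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            P = self._random_balanced(rng, total=11.0)
            Q = self._random_balanced(rng, total=11.0)
            R = self._random_balanced(rng, total=11.0)
            dpq, dqp = emd(P, Q), emd(Q, P)
            dpr, dqr = emd(P, R), emd(Q, R)
            assert dpq >= 0
            assert dpq == pytest.approx(dqp, abs=1e-9)
            assert dpq <= dpr + dqr + 1e-9       # triangle inequality


class TestFullPipeline:
    def test_matched_cloud_closer_than_uniform_cloud(self):
        rho = make_fixture("clustered", seed=3, nx=64)
        rng = np.random.default_rng(3)
        matched = sample_points(rho, 2000, rng)
        uniform = make_fixture("cloud", seed=3, n_points=2000)
        e_match = compare_micro_macro(rho, matched,
                                      np.random.default_rng(4)).emd
        e_unif = compare_micro_macro(rho, uniform,
                                     np.random.default_rng(4)).emd
        assert e_match < e_unif

    def test_pic_of_samples_converges_to_density(self):
        # l2 error of the optimal reconstruction shrinks with N
        rho = make_fixture("clustered", seed=5, nx=64)
        errs = []
        for N in (100, 1000, 10000):
            res = optimal_grid_spacing(rho, N, rng=np.random.default_rng(5))
            errs.append(res.l2_curve[:, 1].min())
        assert errs[0] > errs[1] > errs[2]
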