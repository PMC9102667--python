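import math

import numpy as np
import pytest

from porescape import (
    InvalidInputError,
    ObservationWindow,
    PointPattern,
    auc_difference,
    cluster_sizes,
    csr_envelope,
    csr_test,
    empirical_F,
    nn_distances,
    points_from_mask,
    ripley_K,
    theoretical_F_csr,
    theoretical_K_csr,
)
from porescape.pointpattern import StatCurve, _sample_uniform, default_r_grid
from porescape.synthetic import sample_csr, sample_thomas
from _oracles import brute_F, brute_K, brute_nn
from conftest import pattern_on


class TestObservationWindow:
    def test_area(self, disc_window):
        assert disc_window.area_um2 == disc_window.mask.sum()

    def test_needs_true_pixels(self):
        with pytest.raises(InvalidInputError):
            ObservationWindow(np.zeros((5, 5), dtype=bool), 1.0)

    def test_boundary_distance_full_rect(self, square_window):
        d = square_window.boundary_distance_um(np.array([[49.5, 49.5], [0.0, 50.0]]))
        assert d[0] == pytest.approx(50.0)
        assert d[1] == pytest.approx(0.5)

    def test_boundary_distance_prefers_false_pixels(self, disc_window):
        # center of the disc: nearest complement is the disc rim, not the frame
        d = disc_window.boundary_distance_um(np.array([[19.5, 19.5]]))
        assert d[0] < 19.0


class TestPointsFromMask:
    def test_component_count(self, square_window):
        mask = np.zeros((100, 100), dtype=bool)
        for r, c in [(10, 10), (50, 50), (80, 20)]:
            mask[r : r + 3, c : c + 3] = True
        pattern = points_from_mask(mask, square_window, 1.0)
        assert pattern.n == 3

    def test_centroid_of_2x2_blob(self, square_window):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:12, 10:12] = True
        pattern = points_from_mask(mask, square_window, 1.0)
        assert pattern.points[0] == pytest.approx([10.5, 10.5])

    def test_centroids_match_pixel_mean_oracle(self):
        rng = np.random.default_rng(11)
        window = ObservationWindow(np.ones((60, 60), dtype=bool), 0.5)
        mask = rng.random((60, 60)) > 0.8
        pattern = points_from_mask(mask, window, 0.5)
        from skimage.measure import label, regionprops

        expected = []
        for reg in regionprops(label(mask, connectivity=2)):
            rows, cols = reg.coords[:, 0], reg.coords[:, 1]
            expected.append((cols.mean() * 0.5, rows.mean() * 0.5))
        got = sorted(map(tuple, pattern.points))
        assert np.allclose(got, sorted(expected), atol=1e-9)

    def test_outside_components_dropped_with_warning(self, disc_window):
        mask = np.zeros((40, 40), dtype=bool)
        mask[19:21, 19:21] = True  # inside the disc
        mask[0:2, 0:2] = True  # in the matrix corner
        with pytest.warns(UserWarning, match="dropped 1"):
            pattern = points_from_mask(mask, disc_window, 1.0)
        assert pattern.n == 1

    def test_frame_mismatch_rejected(self, square_window):
        with pytest.raises(InvalidInputError):
            points_from_mask(np.zeros((10, 10), dtype=bool), square_window, 1.0)


class TestTheoreticalCurves:
    def test_F_closed_form(self):
        assert theoretical_F_csr(0.01, 5) == pytest.approx(1 - math.exp(-0.7854), abs=1e-4)
        assert theoretical_F_csr(0.01, 5) == pytest.approx(0.5441, abs=1e-4)

    def test_F_limits(self):
        assert theoretical_F_csr(0.5, 0) == 0.0
        assert theoretical_F_csr(0.0, 7.3) == 0.0
        assert theoretical_F_csr(0.5, 1e3) == pytest.approx(1.0)

    def test_F_rejects_negative(self):
        with pytest.raises(InvalidInputError):
            theoretical_F_csr(-0.1, 1)
        with pytest.raises(InvalidInputError):
            theoretical_F_csr(0.1, -1)

    def test_K_is_pi_r_squared(self):
        assert theoretical_K_csr(0) == 0.0
        assert theoretical_K_csr(1) == pytest.approx(math.pi)
        assert theoretical_K_csr(10) == pytest.approx(100 * math.pi)
        with pytest.raises(InvalidInputError):
            theoretical_K_csr(-1)


class TestEmpiricalF:
    def test_single_central_point_area_fraction(self, square_window):
        # disc of radius 10 around the event covers π·10²/10⁴ of the window
        pattern = pattern_on(square_window, [[50.2, 50.3]])
        curve = empirical_F(pattern, np.array([0.0, 10.0]), correction="none")
        assert curve.value[0] == 0.0
        assert curve.value[1] == pytest.approx(math.pi * 100 / 1e4, abs=5e-3)

    def test_zero_at_r_zero(self, disc_window):
        pattern = pattern_on(disc_window, [[19.2, 19.3], [25.1, 15.2]])
        for correction in ("none", "border"):
            curve = empirical_F(pattern, np.array([0.0, 3.0, 6.0]), correction=correction)
            assert curve.value[0] == 0.0

    def test_uncorrected_bounded_and_monotone(self, disc_window):
        pattern = sample_csr(disc_window, 8, seed=5)
        r = np.linspace(0, 15, 40)
        vals = empirical_F(pattern, r, correction="none").value
        assert np.all(vals >= 0) and np.all(vals <= 1)
        assert np.all(np.diff(vals) >= 0)

    @pytest.mark.parametrize("correction", ["none", "border"])
    def test_matches_bruteforce_oracle(self, disc_window, correction):
        pattern = sample_csr(disc_window, 7, seed=2)
        r = np.linspace(0, 12, 25)
        got = empirical_F(pattern, r, correction=correction).value
        want = brute_F(pattern.points, disc_window.mask, 1.0, r, correction=correction)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_requires_events(self, square_window):
        with pytest.raises(InvalidInputError):
            empirical_F(pattern_on(square_window, np.empty((0, 2))), np.array([0.0, 1.0]))


class TestRipleyK:
    def test_two_points_hand_count(self, square_window):
        pattern = pattern_on(square_window, [[40.0, 50.0], [50.0, 50.0]])
        r = np.array([5.0, 15.0])
        curve = ripley_K(pattern, r, correction="none")
        assert curve.value[0] == 0.0
        assert curve.value[1] == pytest.approx(1e4, rel=1e-12)

    @pytest.mark.parametrize("correction", ["none", "border", "translation"])
    def test_matches_bruteforce_oracle_full_rect(self, square_window, correction):
        pattern = sample_csr(square_window, 12, seed=9)
        r = np.linspace(0, 25, 26)
        got = ripley_K(pattern, r, correction=correction).value
        want = brute_K(pattern.points, square_window.mask, 1.0, r, correction=correction)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("correction", ["none", "border"])
    def test_matches_bruteforce_oracle_masked(self, disc_window, correction):
        pattern = sample_csr(disc_window, 10, seed=13)
        r = np.linspace(0, 10, 21)
        got = ripley_K(pattern, r, correction=correction).value
        want = brute_K(pattern.points, disc_window.mask, 1.0, r, correction=correction)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9, equal_nan=True)

    def test_translation_requires_full_rect(self, disc_window):
        pattern = sample_csr(disc_window, 5, seed=1)
        with pytest.raises(InvalidInputError):
            ripley_K(pattern, np.array([0.0, 5.0]), correction="translation")

    def test_requires_two_events(self, square_window):
        with pytest.raises(InvalidInputError):
            ripley_K(pattern_on(square_window, [[1.0, 1.0]]), np.array([0.0, 1.0]))

    def test_unknown_correction(self, square_window):
        pattern = sample_csr(square_window, 5, seed=1)
        with pytest.raises(InvalidInputError):
            ripley_K(pattern, np.array([0.0, 1.0]), correction="isotropic")


class TestTranslationInvariance:
    def test_shifting_window_and_points_together(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disc = lambda cy, cx: (yy - cy) ** 2 + (xx - cx) ** 2 <= 15.0**2
        w1 = ObservationWindow(disc(20, 20), 1.0)
        w2 = ObservationWindow(disc(27, 24), 1.0)  # same disc shifted by (7, 4) px
        pts = np.array([[15.0, 18.0], [22.0, 25.0], [28.0, 14.0], [18.0, 27.0]])
        shift = np.array([4.0, 7.0])  # (x, y) μm
        r = np.linspace(0, 10, 21)
        for correction in ("none", "border"):
            k1 = ripley_K(PointPattern(pts, w1), r, correction=correction).value
            k2 = ripley_K(PointPattern(pts + shift, w2), r, correction=correction).value
            np.testing.assert_allclose(k1, k2, atol=1e-9, equal_nan=True)
        f1 = empirical_F(PointPattern(pts, w1), r).value
        f2 = empirical_F(PointPattern(pts + shift, w2), r).value
        np.testing.assert_allclose(f1, f2, atol=1e-9, equal_nan=True)


class TestEnvelope:
    def test_deterministic_under_seed(self, disc_window):
        r = np.linspace(0, 8, 17)
        env1 = csr_envelope(disc_window, 10, r, statistic="K", nsim=19, seed=4)
        env2 = csr_envelope(disc_window, 10, r, statistic="K", nsim=19, seed=4)
        np.testing.assert_array_equal(env1.lo, env2.lo)
        np.testing.assert_array_equal(env1.hi, env2.hi)

    def test_coverage_formula(self, disc_window):
        env = csr_envelope(disc_window, 5, np.array([0.0, 4.0]), nsim=49, seed=0)
        assert env.coverage == pytest.approx(0.96)

    def test_band_brackets_theory_most_of_the_grid(self):
        # rank-1 band from 49 CSR sims should contain the CSR expectation
        window = ObservationWindow(np.ones((64, 64), dtype=bool), 1.0)
        r = np.linspace(0, 16, 17)
        inside = []
        for seed in range(50):
            env = csr_envelope(window, 20, r, statistic="K", nsim=49, seed=seed)
            ok = (env.lo[1:] <= env.theoretical[1:]) & (env.theoretical[1:] <= env.hi[1:])
            inside.append(ok.mean())
        assert np.mean(inside) >= 0.90

    def test_rejects_bad_statistic(self, disc_window):
        with pytest.raises(InvalidInputError):
            csr_envelope(disc_window, 5, np.array([0.0, 1.0]), statistic="G")


class TestAucDifference:
    def test_identical_curves_zero(self):
        r = np.linspace(0, 10, 11)
        c = StatCurve(r, r**2, "K")
        assert auc_difference(c, StatCurve(r, r**2, "K")) == 0.0

    def test_constant_offset(self):
        r = np.linspace(0, 7, 15)
        emp = StatCurve(r, np.full_like(r, 2.5), "K")
        theo = StatCurve(r, np.zeros_like(r), "K")
        assert auc_difference(emp, theo) == pytest.approx(2.5 * 7, abs=1e-12)
        assert auc_difference(emp, theo, r_range=(0, 3.5)) == pytest.approx(2.5 * 3.5, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = StatCurve(np.linspace(0, 1, 5), np.zeros(5), "K")
        b = StatCurve(np.linspace(0, 2, 5), np.zeros(5), "K")
        with pytest.raises(InvalidInputError):
            auc_difference(a, b)

    def test_thomas_auc_positive_for_K(self):
        # clustered patterns put extra mass at short distances -> AUC_K > 0
        window = ObservationWindow(np.ones((100, 100), dtype=bool), 1.0)
        r = np.linspace(0, 25, 26)
        theo = StatCurve(r, np.asarray(theoretical_K_csr(r)), "K")
        positive = 0
        total = 100
        for seed in range(total):
            pattern, _ = sample_thomas(window, 8e-4, 4.0, 8.0, seed=seed)
            if pattern.n < 2:
                total -= 1
                continue
            emp = ripley_K(pattern, r, correction="border")
            positive += auc_difference(emp, theo) > 0
        assert positive / total >= 0.95


class TestCsrTestFlag:
    def test_clustered_pattern_flagged(self, square_window):
        pattern, _ = sample_thomas(square_window, 8e-4, 4.0, 10.0, seed=3)
        res = csr_test(pattern, statistic="K", nsim=49, seed=42)
        assert res["clustered"]
        assert res["auc"] > 0

    def test_csr_pattern_not_flagged(self, square_window):
        pattern = sample_csr(square_window, 40, seed=8)
        res = csr_test(pattern, statistic="K", nsim=49, seed=42)
        assert not res["clustered"]


class TestNNDistances:
    def test_collinear_forced_distances(self, square_window):
        pattern = pattern_on(square_window, [[0.0, 0.0], [10.0, 0.0], [25.0, 0.0]])
        np.testing.assert_allclose(nn_distances(pattern), [10, 10, 15])

    def test_equilateral_triangle(self, square_window):
        s = 6.0
        pts = [[10, 10], [10 + s, 10], [10 + s / 2, 10 + s * math.sqrt(3) / 2]]
        np.testing.assert_allclose(nn_distances(pattern_on(square_window, pts)), [s, s, s])

    def test_matches_bruteforce(self, square_window):
        pattern = sample_csr(square_window, 200, seed=21)
        np.testing.assert_allclose(nn_distances(pattern), brute_nn(pattern.points), atol=1e-12)

    def test_requires_two_points(self, square_window):
        with pytest.raises(InvalidInputError):
            nn_distances(pattern_on(square_window, [[1.0, 1.0]]))


class TestClusterSizes:
    def test_all_singletons_beyond_threshold(self, square_window):
        pattern = pattern_on(square_window, [[0, 0], [20, 0], [40, 0], [60, 0]])
        sizes = cluster_sizes(pattern, 5.0)
        assert sorted(sizes) == [1, 1, 1, 1]

    def test_chaining_at_exact_threshold(self, square_window):
        pattern = pattern_on(square_window, [[0.0, 0.0], [5.0, 0.0], [11.0, 0.0]])
        assert list(cluster_sizes(pattern, 6.0)) == [3]

    def test_sizes_sum_to_n(self, square_window):
        for seed in range(5):
            pattern = sample_csr(square_window, 30, seed=seed)
            assert cluster_sizes(pattern, 7.0).sum() == 30

    def test_rejects_bad_inputs(self, square_window):
        with pytest.raises(InvalidInputError):
            cluster_sizes(pattern_on(square_window, np.empty((0, 2))), 5.0)
        with pytest.raises(InvalidInputError):
            cluster_sizes(pattern_on(square_window, [[1.0, 1.0]]), 0.0)


class TestStatCurveValidation:
    def test_grid_must_increase(self):
        with pytest.raises(InvalidInputError):
            StatCurve(np.array([0.0, 2.0, 1.0]), np.zeros(3), "K")

    def test_default_r_grid_quarter_extent(self, square_window):
        r = default_r_grid(square_window)
        assert r[0] == 0.0
        assert r[-1] == pytest.approx(25.0)
        assert len(r) == 129
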