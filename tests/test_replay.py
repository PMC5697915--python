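"""Line fitting: oracle equivalence, analytic cases, shuffle test, labels."""

import numpy as np
import pytest

from replaykit.decoding import PosteriorMatrix
from replaykit.replay import (LineFit, fit_line, intercept_grid, label_replay,
                              period_label_shuffle, rotate_ratemaps,
                              spatial_shuffle_test, velocity_grid)


def brute_force_fit(P, v_grid, c_grid, t_bin_s=0.01, bin_size_cm=2.0, band_cm=30.0):
    """Independent oracle for the exhaustive line search.

    Line centers are integer millimeters (every grid velocity and intercept
    lands on exact mm), so band membership |x - center| <= d has no
    floating-point ambiguity.  The search evaluates every (V, c) cell with
    plain boolean band masks (no prefix sums, no striding); exact score ties
    resolve to the first cell in (V, c) grid order, like a nested loop with a
    strict ">" running maximum.  The winning score is then re-evaluated by
    direct mask summation.
    """
    n_t, n_pos = P.shape
    x_mm = np.round((np.arange(n_pos) + 0.5) * bin_size_cm * 10).astype(int)
    d_mm = int(round(band_cm * 10))
    c_grid = np.asarray(c_grid, dtype=float)
    total = np.sum(P)
    best_v = best_c = None
    best_score = -np.inf
    for v in v_grid:
        scores_c = np.zeros(c_grid.size)
        for t in range(n_t):
            centers = np.rint((v * t * t_bin_s + c_grid) * 1000.0).astype(int)
            mask = np.abs(x_mm[None, :] - centers[:, None]) <= d_mm
            scores_c += mask @ P[t]
        ic = int(np.argmax(scores_c))            # first max within this v
        if scores_c[ic] > best_score:            # strict: keeps first v
            best_score = scores_c[ic]
            best_v, best_c = float(v), float(c_grid[ic])
    masses = []
    for t in range(n_t):
        center_mm = int(round((best_v * t * t_bin_s + best_c) * 1000.0))
        masses.append(P[t][np.abs(x_mm - center_mm) <= d_mm].sum())
    return best_v, best_c, float(np.sum(masses) / total)


class TestGridSearchOracle:
    def test_matches_brute_force_exactly(self):
        """Fast strided search equals the nested-loop oracle bit-for-bit on
        random matrices (coarse grids keep the oracle tractable)."""
        rng = np.random.default_rng(0)
        vg = velocity_grid()[::8]
        cg = intercept_grid(c_step=0.25)
        for _ in range(12):
            P = rng.uniform(0, 1, size=(5, 20))
            fit = fit_line(P, v_grid=vg, c_grid=cg)
            v, c, score = brute_force_fit(P, vg, cg)
            assert fit.v_mps == v and fit.c_m == c
            assert fit.score == score

    def test_velocity_grid_counts(self):
        assert velocity_grid().size == 194
        assert intercept_grid().size == 3601
        v = velocity_grid()
        assert 2.0 in v and -2.0 in v and not ((np.abs(v) < 2).any())


class TestFitLineAnalytic:
    def _delta_line_matrix(self, v, c, n_t=10, n_pos=300):
        """All mass exactly on x(t) = v*t*T + c."""
        P = np.zeros((n_t, n_pos))
        for t in range(n_t):
            x_m = v * t * 0.01 + c
            j = int(x_m * 100 / 2)
            P[t, j] = 1.0
        return P

    def test_all_mass_on_line(self):
        """Mass exactly on x(t) = 3t*T + 1 m: perfect score, and the best
        line tracks the true trajectory within the 30 cm band everywhere
        (short events admit whole families of perfect lines, so (V, c) itself
        is not unique)."""
        P = self._delta_line_matrix(3.0, 1.0)
        fit = fit_line(P)
        assert fit.score == pytest.approx(1.0)
        t = np.arange(P.shape[0]) * 0.01
        dev = np.abs((fit.v_mps * t + fit.c_m) - (3.0 * t + 1.0))
        assert dev.max() <= 0.30 + 0.01

    def test_uniform_matrix_interior_line_score(self):
        """Uniform mass on a 6 m track: any interior line captures the 60 cm
        band, i.e. 0.6/6 = 0.1 of the mass."""
        from replaykit.replay import _direct_score
        P = np.full((8, 300), 1.0 / 300)
        s = _direct_score(P, 0.0, 3.0, 0.01, 2.0, 30.0)
        assert s == pytest.approx(0.1, abs=1e-12)

    def test_score_invariant_to_scaling(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(0, 1, size=(6, 40))
        vg, cg = velocity_grid()[::4], intercept_grid(c_step=0.1)
        a = fit_line(P, v_grid=vg, c_grid=cg)
        b = fit_line(37.5 * P, v_grid=vg, c_grid=cg)
        assert (a.v_mps, a.c_m) == (b.v_mps, b.c_m)
        assert a.score == pytest.approx(b.score, rel=1e-12)

    def test_time_reversal_negates_velocity(self):
        """Reversing the time axis negates the best-fit V and maps the
        intercept to V*(n-1)*T + c (exact grid bijection)."""
        rng = np.random.default_rng(4)
        n_t = 9                       # odd so the mapped intercept stays on grid
        P = rng.uniform(0, 1, size=(n_t, 40))
        fwd = fit_line(P)
        rev = fit_line(P[::-1])
        assert rev.v_mps == -fwd.v_mps
        assert rev.c_m == pytest.approx(fwd.v_mps * (n_t - 1) * 0.01 + fwd.c_m,
                                        abs=1e-9)
        assert rev.score == pytest.approx(fwd.score, rel=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_line(np.zeros((4, 20)))
        P = np.zeros((4, 20))
        P[0, 3] = 1.0
        with pytest.raises(ValueError):
            fit_line(P)           # a single non-empty bin is not a trajectory


class TestSpatialShuffle:
    def test_pvalue_lower_bound(self):
        """Add-one estimator: p can never reach zero (minimum 1/101)."""
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.1, 10.0, size=(20, 300))
        rates[:, 100:120] += 40 * np.exp(-0.5 * ((np.arange(20) - 10) / 3) ** 2)
        counts = np.zeros((6, 20))
        counts[np.arange(6), rng.integers(0, 20, 6)] = 2
        mask = np.zeros(300, dtype=bool)
        p, is_rep, scores = spatial_shuffle_test(
            counts, np.arange(7) * 0.01, rates, mask, "outbound",
            n_shuffles=50, rng=1, c_grid=intercept_grid(c_step=0.1))
        assert p >= 1.0 / 51.0
        assert scores.size == 50

    def test_rotation_preserves_rate_mass(self):
        rng = np.random.default_rng(2)
        rates = rng.uniform(0, 5, size=(7, 50))
        rot = rotate_ratemaps(rates, rng.integers(1, 50, 7))
        np.testing.assert_allclose(np.sort(rot, axis=1), np.sort(rates, axis=1))

    def test_deterministic_given_seed(self):
        rng_rates = np.random.default_rng(3)
        rates = rng_rates.uniform(0.1, 8.0, size=(10, 300))
        counts = np.zeros((5, 10))
        counts[:, :3] = 1
        args = (counts, np.arange(6) * 0.01, rates,
                np.zeros(300, dtype=bool), "outbound")
        kw = dict(n_shuffles=20, c_grid=intercept_grid(c_step=0.1))
        p1, _, s1 = spatial_shuffle_test(*args, rng=7, **kw)
        p2, _, s2 = spatial_shuffle_test(*args, rng=7, **kw)
        assert p1 == p2
        np.testing.assert_array_equal(s1, s2)


class TestLabels:
    def _pm(self, mean_bin):
        P = np.zeros((4, 300))
        P[:, mean_bin] = 1.0
        return PosteriorMatrix(direction="outbound", t_edges=np.arange(5) * 0.01,
                               P=P, empty_bins=np.zeros(4, dtype=bool))

    def _fit(self, v, c):
        return LineFit(v_mps=v, c_m=c, score=0.9, direction="outbound", n_nonempty=4)

    def test_congruent_and_local(self):
        ev = label_replay(0, self._fit(5.0, 1.0), 0.01, self._pm(55),
                          animal_x_cm=100.0, current_direction="outbound",
                          duration_s=0.04)
        assert ev.congruent and ev.is_replay
        assert ev.local            # decoded mean 111 cm, animal at 100 cm
        assert ev.order == "forward" and ev.prospective

    def test_local_boundary_strict(self):
        """Mean decoded position 61 cm away is not local (inclusive 60 cm)."""
        ev = label_replay(0, self._fit(5.0, 1.0), 0.01, self._pm(80),
                          animal_x_cm=100.0, current_direction="outbound",
                          duration_s=0.04)
        assert ev.mean_distance_cm == pytest.approx(61.0)
        assert not ev.local

    def test_reverse_and_retrospective(self):
        ev = label_replay(0, self._fit(-4.0, 2.0), 0.5, self._pm(40),
                          animal_x_cm=100.0, current_direction="outbound",
                          duration_s=0.1)
        assert ev.order == "reverse"
        assert not ev.is_replay
        assert not ev.prospective     # mean 81 cm is behind an outbound animal

    def test_incongruent_direction(self):
        fit = LineFit(v_mps=5.0, c_m=1.0, score=0.9, direction="inbound",
                      n_nonempty=4)
        ev = label_replay(0, fit, 0.01, self._pm(55), animal_x_cm=100.0,
                          current_direction="outbound", duration_s=0.04)
        assert not ev.congruent


class TestPeriodLabelShuffle:
    def test_extreme_segregation(self):
        """All congruent events engaged: observed engaged proportion is 1,
        chance is near the overall rate."""
        sections = np.array(["engaged"] * 50 + ["disengaged"] * 50)
        flags = np.array([True] * 50 + [False] * 50)
        res = period_label_shuffle(sections, flags, n_shuffles=200, rng=0)
        assert res["observed"]["engaged"] == 1.0
        assert abs(res["chance"]["engaged"] - 0.5) < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        sections = rng.choice(["engaged", "disengaged"], 80)
        flags = rng.random(80) < 0.6
        a = period_label_shuffle(sections, flags, rng=5)
        b = period_label_shuffle(sections, flags, rng=5)
        assert a == b

    def test_single_section_rejected(self):
        with pytest.raises(ValueError):
            period_label_shuffle(["engaged"] * 5, [True] * 5)
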