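"""Statistical battery: generalized differencing, rank correlations, Mann-Whitney."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from fossilcomp.errors import InsufficientDataError, UndefinedStatisticError
from fossilcomp.stats import (
    generalized_difference,
    gd_correlate,
    kendall,
    mann_whitney,
    spearman,
)


def gd_oracle(y, t):
    """Independent closed-form oracle: OLS detrend then lag-1 quasi-difference."""
    y, t = np.asarray(y, float), np.asarray(t, float)
    slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
    r = y - (y.mean() - slope * t.mean()) - slope * t
    rho = np.corrcoef(r[:-1], r[1:])[0, 1]
    out = np.concatenate([[r[0]], r[1:] - rho * r[:-1]])
    return out


class TestGeneralizedDifference:
    def test_linear_series_reduces_to_zeros(self):
        t = np.array([1.0, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="linear"):
            out = generalized_difference(3.0 - 2.0 * t, t)
        assert np.array_equal(out, np.zeros(5))

    def test_zero_autocorrelation_leaves_detrended_residuals(self):
        # series whose detrended residuals (0.4,-0.1,-0.6,-0.1,0.4) have
        # exactly zero lag-1 correlation, so quasi-differencing is a no-op
        t = np.arange(5.0)
        y = np.array([-3.0, -3.0, -3.0, -2.0, -1.0])
        r = np.array([0.4, -0.1, -0.6, -0.1, 0.4])
        assert np.corrcoef(r[:-1], r[1:])[0, 1] == pytest.approx(0.0, abs=1e-12)
        out = generalized_difference(y, t)
        assert np.allclose(out, r)

    def test_five_point_series_matches_hand_oracle(self):
        t = np.array([150.0, 148, 145, 141, 138])
        y = np.array([3.0, 7, 2, 9, 5])
        assert np.allclose(generalized_difference(y, t), gd_oracle(y, t))

    def test_output_autocorrelation_shrinks_on_ar1_series(self):
        """Quasi-differencing dampens lag-1 autocorrelation on simulated AR(1)."""
        wins = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 40
            t = np.arange(n, dtype=float)
            e = rng.normal(size=n)
            y = np.empty(n)
            y[0] = e[0]
            for i in range(1, n):
                y[i] = 0.7 * y[i - 1] + e[i]
            slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
            r = y - (y.mean() - slope * t.mean()) - slope * t
            rho_in = np.corrcoef(r[:-1], r[1:])[0, 1]
            d = generalized_difference(y, t)[1:]
            rho_out = np.corrcoef(d[:-1], d[1:])[0, 1]
            if abs(rho_out) <= abs(rho_in):
                wins += 1
        assert wins / n_seeds > 0.9

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            generalized_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_series_hits_plus_minus_one(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_brute_force_rank_pearson(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(rho_oracle)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = spearman(x, y)
        transformed = spearman(np.exp(x), y**3)
        assert transformed.statistic == pytest.approx(base.statistic)
        assert transformed.p_value == pytest.approx(base.p_value)

    def test_constant_input_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKendall:
    def test_concordant_pairs_give_tau_one(self):
        assert kendall([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_three_point_example_by_pair_enumeration(self):
        """{(1,1),(2,3),(3,2)}: of the 3 pairs, 2 concordant, 1 discordant -> 1/3."""
        x, y = [1, 2, 3], [1, 3, 2]
        concordant = discordant = 0
        for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
            s = np.sign(xi - xj) * np.sign(yi - yj)
            concordant += s > 0
            discordant += s < 0
        assert (concordant, discordant) == (2, 1)
        assert kendall(x, y).statistic == pytest.approx(1.0 / 3.0)

    def test_all_tied_y_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kendall([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert kendall(np.exp(x), y).statistic == pytest.approx(kendall(x, y).statistic)


class TestMannWhitney:
    def test_fully_separated_groups_have_u_zero(self):
        """a={1,2}, b={3,4}: no a value exceeds any b value, so U = 0."""
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.u_statistic == 0.0

    def test_identical_groups_have_u_half_product(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u_statistic == pytest.approx(3 * 3 / 2)

    def test_shuffled_identical_samples_give_p_near_one(self):
        a = [3.0, 1.0, 4.0, 1.5, 5.0]
        b = [4.0, 1.5, 3.0, 5.0, 1.0]
        assert mann_whitney(a, b, method="exact").p_value > 0.9

    def test_u_conservation_against_enumeration(self):
        """U_a + U_b = n1*n2 for every assignment, cross-checked by rank sums."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(0, 10, size=rng.integers(2, 6)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(2, 6)).astype(float)
            ranks = sps.rankdata(np.concatenate([a, b]))
            u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2
            u_b = ranks[a.size:].sum() - b.size * (b.size + 1) / 2
            assert u_a + u_b == pytest.approx(a.size * b.size)
            assert mann_whitney(a, b).u_statistic == pytest.approx(min(u_a, u_b))

    def test_exact_and_normal_p_agree_at_n20(self):
        """Full-enumeration p vs tie-corrected normal approximation within 0.02."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=10)
            b = rng.normal(loc=rng.uniform(0, 1.5), size=10)
            p_exact = mann_whitney(a, b, method="exact").p_value
            p_norm = mann_whitney(a, b, method="normal").p_value
            assert abs(p_exact - p_norm) < 0.02

    def test_exact_p_handles_ties_via_midranks(self):
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 3.0, 3.0, 4.0]
        res = mann_whitney(a, b, method="exact")
        assert 0.0 < res.p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


class TestGdCorrelate:
    def test_pairwise_missing_bins_dropped(self):
        t = np.arange(8, dtype=float)
        x = np.array([1.0, 2, np.nan, 4, 3, 6, 5, 8])
        y = np.array([2.0, 3, 4, np.nan, 5, 7, 6, 9])
        res = gd_correlate(x, y, t, method="spearman", gd=False)
        assert res.n == 6

    def test_gd_changes_the_inference_for_co_trending_series(self):
        """Two independently noisy but co-trending series decorrelate after GD."""
        rng = np.random.default_rng(9)
        t = np.arange(30, dtype=float)
        x = t + rng.normal(0, 0.5, 30)
        y = t + rng.normal(0, 0.5, 30)
        raw = gd_correlate(x, y, t, gd=False)
        corrected = gd_correlate(x, y, t, gd=True)
        assert raw.statistic > 0.95
        assert abs(corrected.statistic) < abs(raw.statistic)
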