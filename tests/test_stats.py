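"""Classical tests against independent oracles and error-rate simulations."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from scatniche.stats import (
    DegenerateDataError,
    chi_square_independence,
    fisher_exact_2x2,
    one_way_anova,
    paired_t,
    simple_ols,
    slope_equality_f,
    studentized_range_sf,
    tukey_hsd,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# chi-square


def pearson_oracle(table):
    """Textbook Pearson formula, written independently of the implementation."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


class TestChiSquare:
    def test_perfect_independence(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_evaluated_2x2(self):
        res = chi_square_independence([[20, 5], [5, 20]])
        assert res.statistic == pytest.approx(18.0)
        assert res.df == 1

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            shape = rng.choice([2, 3, 4], size=2)
            table = rng.integers(1, 40, size=shape)
            res = chi_square_independence(table)
            assert res.statistic == pytest.approx(pearson_oracle(table), abs=1e-12)
            ref = sps.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_margin_permutation_invariance(self):
        table = np.array([[7, 2, 9], [4, 11, 3]])
        base = chi_square_independence(table).statistic
        assert chi_square_independence(table[::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(table[:, ::-1]).statistic == pytest.approx(base)

    def test_integer_scaling_property(self):
        table = np.array([[7, 2], [4, 11]])
        assert chi_square_independence(3 * table).statistic == pytest.approx(
            3 * chi_square_independence(table).statistic
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_independence([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# Fisher's exact


def fisher_oracle(table):
    """Two-sided p by brute-force enumeration from binomial coefficients."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = []
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((aa, math.comb(r1, aa) * math.comb(r2, c1 - aa) / denom))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[2, 3], [3, 2]]).p_value == pytest.approx(1.0)

    def test_extreme_diagonal_table(self):
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_equals_enumeration_oracle_on_all_small_tables(self):
        """Every 2x2 table with N <= 40 matches brute-force enumeration."""
        max_n = 40
        checked = 0
        for n in range(1, max_n + 1):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        res = fisher_exact_2x2(table)
                        assert abs(res.p_value - fisher_oracle(table)) < 1e-12, (
                            f"table {table}"
                        )
                        checked += 1
        # every composition of every N <= 40 into four cells was visited
        assert checked == math.comb(max_n + 4, 4) - 1

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            table = rng.integers(0, 25, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = fisher_exact_2x2(table)
            _, p_ref = sps.fisher_exact(table, alternative="two-sided")
            assert ours.p_value == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_odds_ratio_reported(self):
        res = fisher_exact_2x2([[6, 2], [3, 9]])
        assert res.statistic == pytest.approx(6 * 9 / (2 * 3))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# ANOVA and Tukey-Kramer


class TestOneWayAnova:
    def test_two_group_case_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
        f = one_way_anova([x, y])
        t = two_sample_t(x, y)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(101)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            if one_way_anova(groups).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_against_shifted_group(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        assert one_way_anova(groups).p_value < 0.001

    def test_zero_within_variance_flagged(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert res.degenerate


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df",
        [(3.0, 3, 10), (3.5, 4, 20), (2.5, 2, 5), (4.5, 6, 30), (5.5, 3, 8)],
    )
    def test_matches_scipy_distribution(self, q, k, df):
        ours = studentized_range_sf(q, k, df)
        ref = sps.studentized_range.sf(q, k, df)
        assert ours == pytest.approx(ref, abs=2e-6)

    def test_textbook_critical_point(self):
        # classic tabulated value: q_{0.05}(k=3, df=12) = 3.77
        assert studentized_range_sf(3.77, 3, 12) == pytest.approx(0.05, abs=5e-4)


class TestTukeyHsd:
    def test_identical_means_adjusted_p_near_one(self):
        g = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        for res in tukey_hsd(g):
            assert res.p_value > 0.999

    def test_equal_n_case_matches_scipy_tukey(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 1.5)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for (i, j), k in pairs.items():
            assert ours[k].p_value == pytest.approx(ref.pvalue[i, j], abs=1e-4)

    def test_unequal_n_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, n) for n in (8, 14, 23)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for (i, j), k in pairs.items():
            assert ours[k].p_value == pytest.approx(ref.pvalue[i, j], abs=1e-4)

    def test_familywise_error_under_global_null(self):
        rng = np.random.default_rng(12)
        k, n, df = 4, 10, 36
        reps = 2000
        # critical point found once from our own sf by bisection
        lo, hi = 1.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if studentized_range_sf(mid, k, df) > 0.05:
                lo = mid
            else:
                hi = mid
        q_crit = (lo + hi) / 2
        fwer = 0
        for _ in range(reps):
            groups = rng.normal(0, 1, (k, n))
            means = groups.mean(axis=1)
            msw = groups.var(axis=1, ddof=1).mean()
            q = (means.max() - means.min()) / math.sqrt(msw / n)
            if q > q_crit:
                fwer += 1
        assert fwer / reps <= 0.065


class TestPairedT:
    def test_strong_paired_shift_detected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.5, 0.1, 135)
        y = x + rng.normal(0.5, 0.1, 135)
        res = paired_t(x, y)
        assert res.df == 134
        assert res.p_value < 1e-10

    def test_pair_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)
        base = paired_t(x, y)
        perm = rng.permutation(30)
        assert paired_t(x[perm], y[perm]).statistic == pytest.approx(base.statistic)

    def test_breaking_pairing_shrinks_t(self):
        rng = np.random.default_rng(6)
        reps = 200
        shrunk = 0
        for _ in range(reps):
            x = rng.normal(0, 1, 40)
            y = x + rng.normal(0.3, 0.2, 40)  # tightly paired
            t_paired = abs(paired_t(x, y).statistic)
            t_broken = abs(paired_t(x, rng.permutation(y)).statistic)
            shrunk += t_broken < t_paired
        assert shrunk / reps > 0.9

    def test_zero_variance_differences_flagged(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate


class TestSlopeEqualityF:
    def test_identical_lines_give_zero_f(self):
        x = np.arange(7.0)
        y = 2.0 * x + 1.0
        res = slope_equality_f((x, y), (x, y))
        assert res.statistic == pytest.approx(0.0)
        assert res.df == (1, 10)

    def test_type_one_error_under_equal_slopes(self):
        rng = np.random.default_rng(14)
        reps = 2000
        x = np.linspace(0, 3, 7)
        rejections = 0
        for _ in range(reps):
            ya = 1.0 + 0.8 * x + rng.normal(0, 0.3, 7)
            yb = 0.2 + 0.8 * x + rng.normal(0, 0.3, 7)
            if slope_equality_f((x, ya), (x, yb)).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_different_slopes_detected_at_low_noise(self):
        rng = np.random.default_rng(15)
        x = np.linspace(0, 3, 8)
        ya = 1.0 + 1.0 * x + rng.normal(0, 0.05, 8)
        yb = 1.0 + 2.0 * x + rng.normal(0, 0.05, 8)
        assert slope_equality_f((x, ya), (x, yb)).p_value < 0.01

    def test_collinear_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            slope_equality_f(([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),
                             ([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]))


class TestSimpleOls:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = simple_ols(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_slope_with_noise(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 50)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.01, 50)
        fit = simple_ols(x, y)
        assert fit.slope == pytest.approx(2.0, abs=1e-2)
        assert fit.intercept == pytest.approx(1.0, abs=5e-2)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(33)
        x = rng.normal(0, 2, 40)
        y = 0.7 * x - 1.2 + rng.normal(0, 0.5, 40)
        fit = simple_ols(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        ref = sps.linregress(x, y)
        assert fit.se_slope == pytest.approx(ref.stderr, rel=1e-10)
        assert fit.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            simple_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_all_p_values_within_unit_interval():
    rng = np.random.default_rng(77)
    for _ in range(50):
        table = rng.integers(1, 30, size=(2, 2))
        assert 0.0 <= chi_square_independence(table).p_value <= 1.0
        assert 0.0 <= fisher_exact_2x2(table).p_value <= 1.0
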