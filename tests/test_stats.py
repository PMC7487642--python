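"""Statistical layer: closed forms, degenerate inputs, null behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from orbitmorph.errors import DegenerateTest, SampleSizeError
from orbitmorph.stats import (
    GroupSummary,
    dahlberg,
    icc,
    linear_regression,
    paired_t,
    power_two_sample,
    shapiro_wilk,
    unpaired_t,
    unpaired_t_summary,
)


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            shapiro_wilk(np.ones(20))

    def test_size_limits(self):
        with pytest.raises(SampleSizeError):
            shapiro_wilk([1.0, 2.0])

    def test_null_p_values_uniform(self, rng):
        """Under normal data the p-value is uniform (KS check over seeds)."""
        ps = [shapiro_wilk(rng.standard_normal(500))[1] for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_bimodal(self, rng):
        x = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
        _, p = shapiro_wilk(x)
        assert p < 0.01


class TestPairedT:
    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateTest):
            paired_t(x, x)

    def test_constant_shift_degenerate_but_reports_direction(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateTest, match="mean_diff = 1"):
            paired_t(x, x + 1.0)

    def test_strong_shift_always_significant(self, rng):
        """T1/T2 shift at the volumetric-study scale: p < 1e-4 in >=99% of runs."""
        hits = 0
        for _ in range(500):
            x1 = rng.normal(24.0, 1.7, 40)
            x2 = x1 + rng.normal(0.64, 0.07, 40)
            _, p, _ = paired_t(x1, x2)
            hits += p < 1e-4
        assert hits >= 495

    def test_type_one_error_near_alpha(self, rng):
        reps, n = 2000, 20
        x1 = rng.standard_normal((reps, n))
        x2 = x1 + rng.standard_normal((reps, n))
        rejections = sum(paired_t(a, b)[1] < 0.05 for a, b in zip(x1, x2))
        assert abs(rejections / reps - 0.05) < 0.015


class TestUnpairedT:
    def test_identical_summaries(self):
        g = GroupSummary(40, 0.64, 0.07)
        t, p, md = unpaired_t_summary(g, g)
        assert t == 0.0 and p == 1.0 and md == 0.0

    def test_summary_equals_raw_pooled_t(self, rng):
        x1 = rng.normal(0.0, 1.0, 25)
        x2 = rng.normal(0.3, 1.4, 31)
        t_raw, p_raw = sps.ttest_ind(x1, x2, equal_var=True)
        t_sum, p_sum, _ = unpaired_t_summary(
            GroupSummary.from_sample(x1), GroupSummary.from_sample(x2)
        )
        # raw-vs-summary order flips the sign convention only
        assert abs(abs(t_sum) - abs(t_raw)) < 1e-12
        assert abs(p_sum - p_raw) < 1e-12

    def test_welch_flag(self):
        g1 = GroupSummary(40, 0.64, 0.07)
        g2 = GroupSummary(40, 0.77, 0.22)
        t_p, p_p, _ = unpaired_t_summary(g1, g2)
        t_w, p_w, _ = unpaired_t_summary(g1, g2, equal_var=False)
        assert p_p != p_w  # grossly unequal SDs: the two tests must differ
        assert p_w < 0.05

    def test_small_sample_agrees_with_permutation_oracle(self, rng):
        x1 = rng.normal(0.0, 1.0, 5)
        x2 = rng.normal(1.0, 1.0, 5)
        t_obs, p_t, _ = unpaired_t(x1, x2)
        pooled = np.concatenate([x1, x2])
        count = 0
        total = 0
        for pick in itertools.combinations(range(10), 5):
            a = pooled[list(pick)]
            b = pooled[[i for i in range(10) if i not in pick]]
            t_perm, _, _ = unpaired_t(a, b)
            count += abs(t_perm) >= abs(t_obs) - 1e-12
            total += 1
        p_perm = count / total
        assert abs(p_perm - p_t) < 0.07

    def test_degenerate(self):
        with pytest.raises(DegenerateTest):
            unpaired_t_summary(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 1.0, 0.0))

    def test_type_one_error_near_alpha(self, rng):
        reps, n = 2000, 15
        rejections = 0
        for _ in range(reps):
            _, p, _ = unpaired_t(rng.standard_normal(n), rng.standard_normal(n))
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.015


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        rep = linear_regression(x, 2.0 * x + 1.0)
        assert rep.r == pytest.approx(1.0)
        assert rep.coefficient_b == pytest.approx(2.0)
        assert rep.r_squared == pytest.approx(rep.r**2, abs=1e-9)
        assert rep.ci_lower <= rep.coefficient_b <= rep.ci_upper

    def test_null_correlation_small(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(linear_regression(x, y).r) < 0.05

    def test_slope_ci_coverage(self, rng):
        hits = 0
        for _ in range(1000):
            x = rng.standard_normal(50)
            y = 0.5 * x + rng.standard_normal(50)
            rep = linear_regression(x, y)
            hits += rep.ci_lower <= 0.5 <= rep.ci_upper
        assert 0.93 <= hits / 1000 <= 0.97

    def test_zero_variance_predictor(self):
        with pytest.raises(DegenerateTest):
            linear_regression(np.ones(10), np.arange(10.0))


class TestIcc:
    def test_perfect_agreement(self, rng):
        x = rng.normal(24.0, 1.7, 20)
        assert icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        table = rng.standard_normal((1000, 2))
        assert abs(icc(table)) < 0.1

    def test_variance_ratio(self, rng):
        """sigma_subject^2 = 4, sigma_err^2 = 1 -> ICC ~ 0.8."""
        subj = rng.normal(0.0, 2.0, 2000)
        table = subj[:, None] + rng.normal(0.0, 1.0, (2000, 2))
        assert icc(table) == pytest.approx(0.8, abs=0.03)

    def test_matches_independent_implementation(self, rng):
        """Cross-check against pingouin's two-way absolute-agreement ICC."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(24.0, 1.7, 15)
        table = np.column_stack([x + rng.normal(0, 0.5, 15), x + rng.normal(0.2, 0.5, 15)])
        ours = icc(table)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile([0, 1], 15),
            "score": table.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        row = ref["Type"].isin(["ICC(A,1)", "ICC2"])
        theirs = float(ref.loc[row, "ICC"].iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestDahlberg:
    def test_equal_pairs_zero(self):
        assert dahlberg([[1.0, 1.0], [2.0, 2.0]]) == 0.0

    def test_single_difference_closed_form(self):
        assert dahlberg([[1.0, 2.0]]) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_two_unit_differences(self):
        assert dahlberg([[0.0, 1.0], [3.0, 2.0]]) == pytest.approx(0.7071, abs=1e-4)

    def test_squared_identity(self, rng):
        """dahlberg^2 equals half the mean squared difference."""
        table = rng.standard_normal((50, 2))
        d = table[:, 0] - table[:, 1]
        assert dahlberg(table) ** 2 == pytest.approx(np.mean(d**2) / 2.0)


class TestPower:
    def test_equal_means_power_is_alpha(self):
        g = GroupSummary(40, 0.5, 0.2)
        assert power_two_sample(g, g, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n(self):
        powers = [
            power_two_sample(GroupSummary(n, 0.64, 0.07), GroupSummary(n, 0.77, 0.22))
            for n in (10, 40, 160)
        ]
        assert powers[0] < powers[1] < powers[2]
        assert powers[2] > 0.999
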