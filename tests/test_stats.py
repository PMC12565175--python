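"""Statistical layer vs closed-form and simulation oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from tcisim import (
    linear_fit,
    logistic_fit,
    two_by_two_test,
    two_sample_t,
    wilson_ci,
)
from tcisim.stats import DegenerateTestError, SeparationError


def wilson_closed_form(k, n, level=0.95):
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    p = k / n
    center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    return center - half, center + half


def moment_matched_samples(n, mean, sd, rng):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestWilson:
    @pytest.mark.parametrize("k,n", [(0, 50), (8, 50), (20, 50), (25, 50), (50, 50), (3, 7)])
    def test_matches_closed_form(self, k, n):
        got = wilson_ci(k, n)
        lo, hi = wilson_closed_form(k, n)
        assert got.ci_low == pytest.approx(max(lo, 0.0), abs=1e-12)
        assert got.ci_high == pytest.approx(min(hi, 1.0), abs=1e-12)

    def test_boundary_zero_successes(self):
        assert wilson_ci(0, 50).ci_low == 0.0

    @pytest.mark.parametrize(
        "k,n,printed",
        [(8, 50, (8, 29)), (20, 50, (27, 54)), (25, 50, (36, 64))],
    )
    def test_reproduces_printed_intervals(self, k, n, printed):
        """The study's whole-percent CIs match under outward rounding."""
        w = wilson_ci(k, n)
        assert (math.floor(100 * w.ci_low), math.ceil(100 * w.ci_high)) == printed

    def test_undefined_for_empty(self):
        with pytest.raises(DegenerateTestError):
            wilson_ci(0, 0)


class TestTwoSampleT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(x, x)
        assert res.difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_printed_delivery_time_comparison(self):
        """Elective vs emergency incision-to-delivery summaries."""
        res = two_sample_t((29, 7.2, 3.3), (21, 4.7, 2.6))
        assert res.difference == pytest.approx(2.5)
        assert res.ci_low == pytest.approx(0.7555, abs=2e-4)
        assert res.ci_high == pytest.approx(4.2445, abs=2e-4)
        assert res.p_value == pytest.approx(0.0059, abs=2e-4)

    def test_summary_equals_moment_matched_samples(self):
        rng = np.random.default_rng(0)
        x = moment_matched_samples(29, 7.2, 3.3, rng)
        y = moment_matched_samples(21, 4.7, 2.6, rng)
        a = two_sample_t(x, y)
        b = two_sample_t((29, 7.2, 3.3), (21, 4.7, 2.6))
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-9)
        assert a.ci_high == pytest.approx(b.ci_high, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateTestError):
            two_sample_t((1, 5.0, 0.0), (10, 4.0, 1.0))
        with pytest.raises(DegenerateTestError):
            two_sample_t((5, 5.0, 0.0), (5, 5.0, 0.0))


class TestTwoByTwo:
    def test_identical_proportions(self):
        res = two_by_two_test([[20, 20], [20, 20]])
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "chi-square"

    def test_reconstructed_pause_delivery_table(self):
        # 13/21 emergency vs 7/29 elective pause deliveries (sums to 20/50)
        assert 13 + 7 == 20
        res = two_by_two_test([[13, 8], [7, 22]])
        assert res.p_value < 0.05

    def test_small_expected_counts_use_fisher(self):
        res = two_by_two_test([[1, 0], [0, 1]])
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(1.0)

    def test_empty_margin_undefined(self):
        with pytest.raises(DegenerateTestError):
            two_by_two_test([[0, 0], [3, 4]])


class TestLogisticFit:
    def test_single_binary_predictor_equals_cross_product_ratio(self):
        # 2x2 data: outcome x exposure with counts a=30, b=10, c=15, d=25
        rows = (
            [{"y": 1, "x": 1.0}] * 30 + [{"y": 0, "x": 1.0}] * 10
            + [{"y": 1, "x": 0.0}] * 15 + [{"y": 0, "x": 0.0}] * 25
        )
        df = pd.DataFrame(rows)
        fit = logistic_fit(df, "y", ["x"])
        assert fit.table.loc["x", "estimate"] == pytest.approx((30 * 25) / (10 * 15), rel=1e-4)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame({"y": [0] * 10 + [1] * 10, "x": list(range(20))})
        with pytest.raises(SeparationError):
            logistic_fit(df, "y", ["x"])

    def test_null_coverage_of_or_intervals(self):
        """Under outcome independent of predictors, OR CIs cover 1 in >= 90% of seeds."""
        cover = 0
        n_sim = 40
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "y": rng.integers(0, 2, 120),
                    "age": rng.normal(32, 4, 120),
                    "bmi": rng.normal(30, 6, 120),
                }
            )
            fit = logistic_fit(df, "y", ["age", "bmi"])
            ok = all(
                row.ci_low <= 1.0 <= row.ci_high for _, row in fit.table.iterrows()
            )
            cover += ok
        assert cover / n_sim >= 0.90

    def test_needs_both_classes(self):
        df = pd.DataFrame({"y": [1] * 20, "x": range(20)})
        with pytest.raises(DegenerateTestError):
            logistic_fit(df, "y", ["x"])


class TestLinearFit:
    def test_exact_linear_outcome_gives_r2_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"age": rng.normal(32, 4, 60), "bmi": rng.normal(30, 6, 60)})
        df["y"] = 2.0 + 0.5 * df.age - 0.3 * df.bmi
        fit = linear_fit(df, "y", ["age", "bmi"])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.table.loc["age", "estimate"] == pytest.approx(0.5)

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"y": rng.normal(size=5000), "age": rng.normal(size=5000), "bmi": rng.normal(size=5000)}
        )
        assert linear_fit(df, "y", ["age", "bmi"]).r_squared < 0.01

    def test_rank_deficient_design_named(self):
        df = pd.DataFrame({"y": range(20), "a": range(20)})
        df["b"] = 2 * df.a
        with pytest.raises(ValueError, match="rank-deficient"):
            linear_fit(df, "y", ["a", "b"])

    def test_recovers_urgency_effect_from_generator(self):
        """The urgency coefficient tracks the generator's group difference."""
        from tcisim import default_config, generate_cohort
        from tcisim.cohort import cohort_to_frame

        hits = 0
        for seed in range(20):
            df = cohort_to_frame(generate_cohort(default_config(), seed=seed))
            df["bmi"] = df.weight_kg / (df.height_cm / 100) ** 2
            df = df.rename(columns={"age_y": "age"})
            fit = linear_fit(df, "incision_to_delivery_min", ["urgency", "age", "bmi"])
            row = fit.table.loc["urgency[emergency]"]
            # generator truth: emergency deliveries are ~2.4 min faster
            hits += row.ci_low <= -2.4 <= row.ci_high
        assert hits / 20 >= 0.90
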