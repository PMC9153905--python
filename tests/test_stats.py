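"""The statistical battery: t tests, effect sizes, Bayes factors,
correlations and the study-level composition."""

import math

import numpy as np
import pandas as pd
import pytest

from stopsignal.stats import (
    BFPrior,
    analyze_study,
    compare_paired,
    evidence_label,
    fisher_exact_2x2,
    fisher_z_ci,
    jzs_paired_bf10,
    paired_t,
    pearson_r_ci,
    welch_t,
)


class TestPairedT:
    def test_textbook_differences(self):
        """diffs {1,2,3,4}: mean 2.5, SD 1.291, t = 2.5/(1.291/2) = 3.873."""
        res = paired_t([1.0, 2.0, 3.0, 4.0])
        assert res["t"] == pytest.approx(3.873, abs=5e-4)
        assert res["df"] == 3
        assert res["cohen_d"] == pytest.approx(2.5 / np.std([1, 2, 3, 4], ddof=1))

    def test_identical_pairs_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([0.0, 0.0, 0.0])

    def test_null_differences(self):
        res = paired_t([-1.0, 1.0, -1.0, 1.0])
        assert res["t"] == 0.0
        assert res["cohen_d"] == 0.0
        assert res["ci95"][0] < 0 < res["ci95"][1]

    def test_dz_identity(self):
        """The paired effect size equals |t|/sqrt(n) by construction."""
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 1.0, 37)
        res = paired_t(d)
        assert res["cohen_d"] == pytest.approx(abs(res["t"]) / math.sqrt(37))

    def test_ci_from_t_quantile(self):
        rng = np.random.default_rng(1)
        d = rng.normal(2.0, 3.0, 25)
        res = paired_t(d)
        from scipy import stats as st

        se = d.std(ddof=1) / 5.0
        lo = d.mean() - st.t.ppf(0.975, 24) * se
        assert res["ci95"][0] == pytest.approx(lo)


def bf_oracle(t: float, n: int, scale: float = 0.707) -> float:
    """Independent fine-grid trapezoid evaluation of the JZS integral in its
    g (mixing-variance) form, with the tan^2 substitution mapping (0, inf)
    to a finite interval."""
    nu = n - 1
    theta = np.linspace(1e-7, np.pi / 2 - 1e-7, 200_001)
    g = np.tan(theta) ** 2
    jac = 2 * np.tan(theta) / np.cos(theta) ** 2
    a = 1 + n * g * scale**2
    log_int = (
        -0.5 * np.log(a)
        - (nu + 1) / 2 * np.log1p(t * t / (a * nu))
        - 0.5 * np.log(2 * np.pi)
        - 1.5 * np.log(g)
        - 1 / (2 * g)
        + np.log(jac)
    )
    num = np.trapezoid(np.exp(log_int), theta)
    return float(num / (1 + t * t / nu) ** (-(nu + 1) / 2))


class TestBayesFactor:
    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0, 4.0, 6.61])
    @pytest.mark.parametrize("n", [25, 121, 123])
    def test_agrees_with_quadrature_oracle(self, t, n):
        assert jzs_paired_bf10(t, n) == pytest.approx(bf_oracle(t, n), rel=1e-3)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(1.5, 30), (4.12, 123), (0.44, 121)]:
            assert jzs_paired_bf10(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-6
            )

    def test_symmetric_in_sign(self):
        assert jzs_paired_bf10(-2.23, 123) == pytest.approx(jzs_paired_bf10(2.23, 123))

    def test_monotone_in_t_and_below_one_at_null(self):
        for n in (10, 50, 123):
            values = [jzs_paired_bf10(t, n) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
            assert all(a < b for a, b in zip(values, values[1:]))
            assert values[0] < 1.0

    def test_wider_prior_shrinks_null_bf(self):
        assert jzs_paired_bf10(0.0, 50, BFPrior(scale=1.0)) < jzs_paired_bf10(0.0, 50)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_paired_bf10(float("nan"), 30)
        with pytest.raises(ValueError):
            jzs_paired_bf10(1.0, 1)


class TestEvidenceLabel:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (242.35, "very_strong_h1"),
            (30.0, "very_strong_h1"),  # boundary -> stronger band
            (15.0, "strong_h1"),
            (10.0, "strong_h1"),
            (3.0, "moderate_h1"),
            (1.5, "anecdotal_h1"),
            (1.0, "anecdotal_h1"),
            (0.5, "anecdotal_h0"),
            (0.11, "moderate_h0"),
            (0.10, "strong_h0"),
            (0.05, "strong_h0"),
            (0.03, "very_strong_h0"),
            (0.001, "very_strong_h0"),
        ],
    )
    def test_bands(self, bf, label):
        assert evidence_label(bf) == label

    def test_positive_only(self):
        with pytest.raises(ValueError):
            evidence_label(0.0)


class TestCorrelation:
    def test_hand_dataset_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0, 8.5])
        res = pearson_r_ci(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.r == pytest.approx(oracle)

    def test_perfectly_linear(self):
        res = pearson_r_ci([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert res.r == pytest.approx(1.0)

    def test_fisher_z_interval_from_r_and_n(self):
        lo, hi = fisher_z_ci(0.48, 123)
        assert (round(lo, 2), round(hi, 2)) == (0.33, 0.61)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestWelch:
    def test_satterthwaite_limit_equal_variances(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]
        res = welch_t(x, y)
        assert res["df"] == pytest.approx(6.0)

    def test_hand_satterthwaite(self):
        """{1,2,3} vs {2,4,6}: se^2 = 1/3 + 4/3, df = (5/3)^2 / (17/18)."""
        res = welch_t([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res["t"] == pytest.approx(-2.0 / math.sqrt(5.0 / 3.0))
        assert res["df"] == pytest.approx((5.0 / 3.0) ** 2 / ((1 / 9 + 16 / 9) / 2))

    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)


class TestFisherExact:
    def test_enumeration_oracle(self):
        """Classic 2x2: sum hypergeometric probabilities <= observed."""
        from scipy.stats import hypergeom

        a, b, c, d = 1, 9, 11, 3
        n_row1, n_col1, total = a + b, a + c, a + b + c + d
        rv = hypergeom(total, n_row1, n_col1)
        p_obs = rv.pmf(a)
        oracle = sum(
            rv.pmf(k)
            for k in range(max(0, n_row1 + n_col1 - total), min(n_row1, n_col1) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-12)
        )
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(oracle)
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(0.002759, abs=5e-7)

    def test_proportional_table(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_zero_margin(self):
        assert fisher_exact_2x2(0, 0, 3, 4) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


def _metrics_frame(rng, n=24, ssrt_shift=0.0):
    """Synthetic per-session metrics table for analyze_study tests."""
    rows = []
    base_ssrt = rng.normal(240, 35, n)
    for i in range(n):
        for cond in ("lab", "independent"):
            shift = ssrt_shift if cond == "independent" else 0.0
            rows.append(
                {
                    "participant_id": f"p{i}",
                    "condition": cond,
                    "order": "independent_first" if i % 2 == 0 else "lab_first",
                    "go_accuracy": rng.normal(97.5, 1.5),
                    "go_rt_mean": rng.normal(490, 60),
                    "go_omissions": rng.normal(0.6, 0.5),
                    "go_errors": rng.normal(1.8, 1.0),
                    "go_error_rt_mean": rng.normal(420, 80),
                    "intraindividual_sd": rng.normal(84, 24),
                    "stop_accuracy": rng.normal(50, 2),
                    "failed_stop_correct_key_rt_mean": rng.normal(450, 50),
                    "failed_stop_incorrect_key_rt_mean": np.nan if i < 4 else rng.normal(380, 60),
                    "ssd_meta_mean": rng.normal(240, 70),
                    "ssrt": base_ssrt[i] + shift + rng.normal(0, 15),
                }
            )
    return pd.DataFrame(rows)


class TestAnalyzeStudy:
    def test_single_variable_matches_manual_composition(self):
        rng = np.random.default_rng(5)
        df = _metrics_frame(rng)
        report = analyze_study(df)
        row = next(c for c in report.comparisons if c.variable == "Go accuracy")
        wide = df.pivot(index="participant_id", columns="condition")["go_accuracy"]
        manual = compare_paired(
            wide["lab"].to_numpy(), wide["independent"].to_numpy(), "Go accuracy"
        )
        assert row.t == pytest.approx(manual.t)
        assert row.bf10 == pytest.approx(manual.bf10)
        assert row.df == manual.df == 23

    def test_missing_stratum_reduces_df_pairwise(self):
        rng = np.random.default_rng(6)
        report = analyze_study(_metrics_frame(rng))
        row = next(
            c
            for c in report.comparisons
            if c.variable == "Failed (incorrect key) stop RT (ms)"
        )
        assert row.n_pairs == 20 and row.df == 19

    def test_order_subgroup_correlations_present(self):
        rng = np.random.default_rng(7)
        report = analyze_study(_metrics_frame(rng))
        assert set(report.ssrt_correlation_by_order) == {
            "independent_first",
            "lab_first",
        }
        assert report.ssrt_correlation.n == 24

    def test_retained_filter_applies(self):
        rng = np.random.default_rng(8)
        df = _metrics_frame(rng)
        report = analyze_study(df, retained={f"p{i}" for i in range(10)})
        assert report.n_retained == 10

    def test_condition_effect_detected_and_null_respected(self):
        rng = np.random.default_rng(9)
        effect = analyze_study(_metrics_frame(rng, n=120, ssrt_shift=22.0))
        ssrt_row = next(
            c for c in effect.comparisons if c.variable == "Stop-signal reaction time (ms)"
        )
        assert ssrt_row.significant_at_005 and ssrt_row.t < 0

        null = analyze_study(_metrics_frame(rng, n=120, ssrt_shift=0.0))
        ssrt_null = next(
            c for c in null.comparisons if c.variable == "Stop-signal reaction time (ms)"
        )
        assert not ssrt_null.significant_at_005
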