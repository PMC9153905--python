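"""The statistical analysis layer for two-condition within-subject studies.

Implements the battery used to compare laboratory-based and independent
sessions: dependent-samples t tests with the paired-design effect size
d_z = |mean diff| / SD(diff) = |t|/sqrt(n), 95% CIs of the difference,
the default JZS Bayes factor for paired designs (Cauchy(0, 0.707) prior
on the standardized effect size, marginalized by adaptive quadrature),
Pearson correlations with Fisher-z confidence intervals, Welch t tests,
and the Fisher exact test.  ``analyze_study`` composes these over a
per-session metrics table into one comparison row per variable plus the
SSRT test-retest correlations, flagging significance at the study's
multiplicity-corrected critical P of .005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import integrate, stats

__all__ = [
    "BFPrior",
    "PairedComparison",
    "CorrelationResult",
    "StudyReport",
    "paired_t",
    "compare_paired",
    "jzs_paired_bf10",
    "evidence_label",
    "pearson_r_ci",
    "fisher_z_ci",
    "welch_t",
    "fisher_exact_2x2",
    "shapiro_wilk",
    "analyze_study",
    "STUDY_VARIABLES",
    "CRITICAL_P",
]

CRITICAL_P = 0.005


class BFPrior(BaseModel):
    """Cauchy prior on the standardized effect size for the JZS Bayes factor."""

    scale: float = Field(0.707, gt=0.0)


@dataclass(frozen=True)
class PairedComparison:
    """One paired-comparison row: descriptives, t test, effect size, BF10."""

    variable: str
    n_pairs: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: int
    p: float
    ci95_diff: tuple[float, float]  # on the a - b scale
    cohen_d: float                  # d_z = |t| / sqrt(n)
    bf10: float
    evidence_label: str
    significant_at_005: bool
    estimable: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci95: tuple[float, float]
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def paired_t(diffs: Sequence[float]) -> dict:
    """One-sample t test on paired differences.

    Returns t, df, two-sided p, the 95% CI of the mean difference and
    the paired-design effect size d_z = |mean| / SD(diff).
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(0.95)
    return {
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
        "ci95": (float(ci.low), float(ci.high)),
        "cohen_d": float(abs(d.mean()) / sd),
        "n": n,
    }


def jzs_paired_bf10(t: float, n: int, prior: Optional[BFPrior] = None) -> float:
    """Default JZS Bayes factor BF10 for a one-sample/paired t design.

    Marginalizes the noncentral-t likelihood of the observed t statistic
    over a Cauchy(0, scale) prior on the standardized effect size delta
    (noncentrality delta*sqrt(n)) and divides by the null (central-t)
    likelihood.  The half-infinite tails are handled by adaptive
    quadrature on the folded integrand; BF10 is symmetric in t ↔ -t.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    prior = prior or BFPrior()
    t = abs(float(t))
    nu = n - 1
    root_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        like = stats.nct.pdf(t, nu, delta * root_n)
        return like * stats.cauchy.pdf(delta, 0.0, prior.scale)

    # fold the symmetric prior: integrate each half on (0, inf)
    num = 0.0
    for sign in (1.0, -1.0):
        val, err = integrate.quad(
            lambda d: integrand(sign * d), 0.0, np.inf, epsrel=1e-8, epsabs=0.0, limit=300
        )
        if not math.isfinite(val) or (val > 0 and err / val > 1e-4):
            raise ArithmeticError(
                f"BF quadrature did not converge (value {val}, abs err {err})"
            )
        num += val
    denom = stats.t.pdf(t, nu)
    return float(num / denom)


_H1_BANDS = [(30.0, "very_strong_h1"), (10.0, "strong_h1"), (3.0, "moderate_h1")]
_H0_BANDS = [(0.03, "very_strong_h0"), (0.10, "strong_h0"), (1.0 / 3.0, "moderate_h0")]


def evidence_label(bf10: float) -> str:
    """Map a Bayes factor onto the conventional evidence bands.

    BF10 > 1 favors the alternative (anecdotal 1-3, moderate 3-10,
    strong 10-30, very strong >30); BF10 < 1 favors the null with the
    reciprocal bands.  Exact boundary values go to the stronger band;
    BF10 = 1 is anecdotal.
    """
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 >= 1.0:
        for cut, label in _H1_BANDS:
            if bf10 >= cut:
                return label
        return "anecdotal_h1"
    for cut, label in _H0_BANDS:
        if bf10 <= cut:
            return label
    return "anecdotal_h0"


def pearson_r_ci(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> CorrelationResult:
    """Pearson correlation with two-sided p and Fisher-z confidence interval.

    CI: tanh(atanh(r) ± z * 1/sqrt(n-3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a margin")
    r, p = stats.pearsonr(x, y)
    # Fisher z diverges at |r| = 1; clamp so degenerate inputs give a point CI
    z = math.atanh(max(min(r, 1.0 - 1e-15), -1.0 + 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    ci = (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))
    return CorrelationResult(r=float(r), p=float(p), ci95=ci, n=int(n))


def fisher_z_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation given only r and n."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    return (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))


def welch_t(x: Sequence[float], y: Sequence[float]) -> dict:
    """Welch two-sample t test with Satterthwaite (fractional) df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std() == 0 and y.std() == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric summation)."""
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def shapiro_wilk(x: Sequence[float]) -> dict:
    """Shapiro-Wilk normality test (offered as a convenience check)."""
    res = stats.shapiro(np.asarray(x, dtype=float))
    return {"w": float(res.statistic), "p": float(res.pvalue)}


# Table rows: (variable key in the metrics table, human label)
STUDY_VARIABLES: list[tuple[str, str]] = [
    ("go_accuracy", "Go accuracy"),
    ("go_rt_mean", "Go reaction time (ms)"),
    ("go_omissions", "Go omissions"),
    ("go_errors", "Go errors"),
    ("go_error_rt_mean", "Go errors reaction time (ms)"),
    ("intraindividual_sd", "Intraindividual SD"),
    ("stop_accuracy", "Stop accuracy"),
    ("failed_stop_correct_key_rt_mean", "Failed (correct key) stop RT (ms)"),
    ("failed_stop_incorrect_key_rt_mean", "Failed (incorrect key) stop RT (ms)"),
    ("ssd_meta_mean", "Meta stop-signal delay (ms)"),
    ("ssrt", "Stop-signal reaction time (ms)"),
]


def _not_estimable(variable: str, n: int) -> PairedComparison:
    nan = float("nan")
    return PairedComparison(
        variable=variable,
        n_pairs=n,
        mean_a=nan,
        mean_b=nan,
        sd_a=nan,
        sd_b=nan,
        t=nan,
        df=max(n - 1, 0),
        p=nan,
        ci95_diff=(nan, nan),
        cohen_d=nan,
        bf10=nan,
        evidence_label="not_estimable",
        significant_at_005=False,
        estimable=False,
    )


def compare_paired(
    a: Sequence[float],
    b: Sequence[float],
    variable: str = "",
    prior: Optional[BFPrior] = None,
) -> PairedComparison:
    """Full paired comparison of condition a vs condition b (diff = a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    core = paired_t(a - b)
    bf = jzs_paired_bf10(core["t"], core["n"], prior)
    return PairedComparison(
        variable=variable,
        n_pairs=core["n"],
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=core["t"],
        df=core["df"],
        p=core["p"],
        ci95_diff=core["ci95"],
        cohen_d=core["cohen_d"],
        bf10=bf,
        evidence_label=evidence_label(bf),
        significant_at_005=core["p"] < CRITICAL_P,
    )


@dataclass(frozen=True)
class StudyReport:
    """Comparisons for every study variable plus SSRT correlations."""

    comparisons: list[PairedComparison]
    ssrt_correlation: CorrelationResult
    ssrt_correlation_by_order: dict[str, CorrelationResult]
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.comparisons])

    def as_dict(self) -> dict:
        return {
            "n_retained": self.n_retained,
            "comparisons": [c.as_dict() for c in self.comparisons],
            "ssrt_correlation": self.ssrt_correlation.as_dict(),
            "ssrt_correlation_by_order": {
                k: v.as_dict() for k, v in self.ssrt_correlation_by_order.items()
            },
        }


def analyze_study(
    metrics: pd.DataFrame,
    retained: Optional[set[str]] = None,
    prior: Optional[BFPrior] = None,
) -> StudyReport:
    """Run the full lab-vs-independent comparison battery.

    ``metrics`` has one row per session with columns ``participant_id``,
    ``condition`` ("lab"/"independent"), optionally ``order``, and the
    variable battery.  Comparisons are lab (a) vs independent (b).  Each
    variable uses pairwise-complete participants (both sessions non-null
    for that variable), so strata that some participants lack — e.g.
    incorrect-key failed stops — get a reduced df rather than biasing
    the row.  Rows with fewer than 2 complete pairs, or zero-variance
    differences, are reported as not estimable instead of being dropped.
    """
    df = metrics.copy()
    if retained is not None:
        df = df[df["participant_id"].isin(retained)]
    wide = df.pivot(index="participant_id", columns="condition")
    participants = wide.index
    if len(participants) < 4:
        raise ValueError("need at least 4 retained participants")

    comparisons = []
    for key, label in STUDY_VARIABLES:
        if key not in df.columns:
            continue
        lab = wide[(key, "lab")]
        ind = wide[(key, "independent")]
        ok = lab.notna() & ind.notna()
        if ok.sum() < 2:
            comparisons.append(_not_estimable(label, int(ok.sum())))
            continue
        try:
            comparisons.append(
                compare_paired(lab[ok].to_numpy(), ind[ok].to_numpy(), label, prior)
            )
        except ValueError:
            comparisons.append(_not_estimable(label, int(ok.sum())))

    lab_ssrt = wide[("ssrt", "lab")]
    ind_ssrt = wide[("ssrt", "independent")]
    overall = pearson_r_ci(lab_ssrt.to_numpy(), ind_ssrt.to_numpy())

    by_order: dict[str, CorrelationResult] = {}
    if "order" in metrics.columns:
        orders = metrics.drop_duplicates("participant_id").set_index("participant_id")[
            "order"
        ]
        for arm in sorted(orders.loc[participants].unique()):
            sel = orders.loc[participants] == arm
            if sel.sum() >= 4:
                by_order[str(arm)] = pearson_r_ci(
                    lab_ssrt[sel].to_numpy(), ind_ssrt[sel].to_numpy()
                )
    return StudyReport(
        comparisons=comparisons,
        ssrt_correlation=overall,
        ssrt_correlation_by_order=by_order,
        n_retained=int(len(participants)),
    )
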