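"""Frequentist group statistics for burst-rate analyses.

A 2 x 3 mixed ANOVA (between-subjects GROUP, within-subjects TRIAL TYPE)
with partial eta squared effect sizes, planned paired / independent t-tests
with Cohen's d, and uncorrected sample-wise t-tests over burst-rate time
courses.  No sphericity correction is applied (uncorrected degrees of
freedom are reported), and sample-wise tests are deliberately left
uncorrected for multiple comparisons; both choices are recorded in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "mixed_anova_2x3",
    "paired_t",
    "independent_t",
    "samplewise_tests",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    sphericity_correction: str = "none"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    kind: str
    flagged: bool = False  # zero-variance / undefined statistic


def mixed_anova_2x3(rates: pd.DataFrame, dv: str = "normalized_rate",
                    within: str = "trial_type", between: str = "group",
                    subject: str = "subject") -> list[AnovaResult]:
    """Mixed ANOVA on a long-format burst-rate table.

    Requires a balanced within-factor (every subject has every trial type);
    missing cells raise.  Returns main effects (between, within) and the
    interaction, each with partial eta squared
    ``SS_effect / (SS_effect + SS_error)``.
    """
    import pingouin as pg

    counts = rates.groupby([subject, within], observed=True)[dv].count()
    n_levels = rates[within].nunique()
    per_subject = counts.groupby(level=0).count()
    if (per_subject != n_levels).any() or (counts != 1).any():
        raise ValueError("missing or duplicated cells in the within-factor")

    n_groups = rates[between].nunique()
    n_subj = rates[subject].nunique()
    df_sw = n_subj - n_groups
    df_cond = n_levels - 1
    if np.isclose(rates[dv].var(ddof=0), 0.0):
        # Degenerate constant table: every effect is exactly zero.
        return [
            AnovaResult("group", 0.0, n_groups - 1, df_sw, 1.0, 0.0),
            AnovaResult("trial_type", 0.0, df_cond, df_sw * df_cond, 1.0, 0.0),
            AnovaResult("interaction", 0.0, (n_groups - 1) * df_cond,
                        df_sw * df_cond, 1.0, 0.0),
        ]

    aov = pg.mixed_anova(data=rates, dv=dv, within=within, between=between,
                         subject=subject, correction=False)
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = []
    for _, row in aov.iterrows():
        if row["Source"] == between:
            effect = "group"
        elif row["Source"] == within:
            effect = "trial_type"
        else:
            effect = "interaction"
        out.append(AnovaResult(
            effect=effect, F=float(row["F"]), df1=float(row["DF1"]),
            df2=float(row["DF2"]), p=float(row[p_col]),
            partial_eta_sq=float(row["np2"]),
        ))
    return out


def paired_t(a, b) -> TTestResult:
    """Paired-samples t-test; Cohen's d = mean(diff) / SD(diff)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return TTestResult(t=float("nan"), df=len(a) - 1, p=float("nan"),
                           cohens_d=float("nan"), kind="paired", flagged=True)
    t, p = sps.ttest_rel(a, b)
    d = diff.mean() / sd
    return TTestResult(t=float(t), df=len(a) - 1, p=float(p),
                       cohens_d=float(d), kind="paired")


def independent_t(a, b) -> TTestResult:
    """Independent-samples t-test; Cohen's d uses the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        return TTestResult(t=float("nan"), df=na + nb - 2, p=float("nan"),
                           cohens_d=float("nan"), kind="independent",
                           flagged=True)
    t, p = sps.ttest_ind(a, b)
    d = (a.mean() - b.mean()) / pooled
    return TTestResult(t=float(t), df=na + nb - 2, p=float(p),
                       cohens_d=float(d), kind="independent")


def samplewise_tests(timecourse_a: np.ndarray, timecourse_b: np.ndarray,
                     paired: bool = True, alpha: float = 0.05):
    """Per-sample t-tests along aligned time courses (subjects x times).

    Returns ``(p_values, significant_mask)``; the mask is thresholded at
    ``alpha`` without any multiple-comparison correction.  Samples with zero
    variance in the test statistic yield p = NaN and are never flagged.
    """
    a = np.asarray(timecourse_a, dtype=float)
    b = np.asarray(timecourse_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("time axes must be aligned")
    n_t = a.shape[1]
    p = np.full(n_t, np.nan)
    for i in range(n_t):
        x, y = a[:, i], b[:, i]
        if paired:
            both = np.isfinite(x) & np.isfinite(y)
            x, y = x[both], y[both]
            if len(x) < 2 or (x - y).std(ddof=1) == 0:
                continue
            p[i] = sps.ttest_rel(x, y).pvalue
        else:
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if min(len(x), len(y)) < 2 or (x.std(ddof=1) == 0
                                           and y.std(ddof=1) == 0):
                continue
            p[i] = sps.ttest_ind(x, y).pvalue
    mask = np.where(np.isfinite(p), p < alpha, False)
    return p, mask
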