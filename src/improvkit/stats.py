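"""Inferential layer: one-way repeated-measures ANOVA with Bonferroni
pairwise comparisons and partial eta squared, and independent two-sample
t-tests (pooled and Welch) with Cohen's d.

The rm-ANOVA uses the classic subject x condition sum-of-squares
decomposition: F = MS_condition / MS_error with df1 = k-1 and
df2 = (n-1)(k-1) on complete cases.  Partial eta squared is
SS_condition / (SS_condition + SS_error).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "PairwiseComparison",
    "rm_anova",
    "two_sample_t",
    "cohens_d",
    "compare_collectives",
    "significance_stars",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    p_adjusted: float  # Bonferroni: min(1, raw p * number of pairs)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_sq: float  # partial eta squared
    pairwise: tuple[PairwiseComparison, ...]
    n_used: int
    n_dropped: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    alternative: str  # "two-sided" | "greater" | "less"
    d: float  # Cohen's d, pooled-sd standardised
    variant: str  # "pooled" | "welch"
    n1: int = 0
    n2: int = 0


def rm_anova(
    values, conditions: list[str] | None = None, missing: str = "complete"
) -> AnovaResult:
    """One-way within-subject ANOVA on a subject x condition matrix.

    ``values`` is array-like or a DataFrame (columns = conditions), NaN
    allowed.  missing='complete' drops subjects with any missing
    condition (count logged); missing='impute' fills a missing cell with
    the additive expectation subject mean + condition mean - grand mean
    and removes one error df per imputed cell.
    """
    if isinstance(values, pd.DataFrame):
        conditions = conditions or [str(c) for c in values.columns]
        mat = values.to_numpy(dtype=float)
    else:
        mat = np.asarray(values, dtype=float)
        conditions = conditions or [f"c{i}" for i in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 conditions")

    n_total = mat.shape[0]
    incomplete = np.isnan(mat).any(axis=1)
    n_imputed = 0
    if missing == "complete":
        mat = mat[~incomplete]
        n_dropped = int(incomplete.sum())
        if n_dropped:
            logger.info("rm_anova: dropped %d incomplete subjects", n_dropped)
    elif missing == "impute":
        mat = mat[~np.isnan(mat).all(axis=1)]
        n_dropped = n_total - mat.shape[0]
        mask = np.isnan(mat)
        n_imputed = int(mask.sum())
        if n_imputed:
            subj_mean = np.nanmean(mat, axis=1, keepdims=True)
            cond_mean = np.nanmean(mat, axis=0, keepdims=True)
            grand = np.nanmean(mat)
            fill = subj_mean + cond_mean - grand
            mat = np.where(mask, fill, mat)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")

    n, k = mat.shape
    if n < 3:
        raise ValueError("need at least 3 usable subjects")

    grand = mat.mean()
    cond_means = mat.mean(axis=0)
    subj_means = mat.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((mat - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj

    df1 = k - 1
    df2 = (n - 1) * (k - 1) - n_imputed
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2 if df2 > 0 else float("nan")
    if ms_err <= 0 or not np.isfinite(ms_err):
        F, p = 0.0, 1.0
    else:
        F = ms_cond / ms_err
        p = float(sps.f.sf(F, df1, df2))
    eta_sq = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0

    pairs = list(itertools.combinations(range(k), 2))
    pairwise = []
    for i, j in pairs:
        diff = float(mat[:, i].mean() - mat[:, j].mean())
        d = mat[:, i] - mat[:, j]
        if np.allclose(d, d[0]):  # constant difference: sd = 0
            raw_p = 1.0 if diff == 0 else 0.0
        else:
            raw_p = float(sps.ttest_rel(mat[:, i], mat[:, j]).pvalue)
        pairwise.append(
            PairwiseComparison(
                pair=(conditions[i], conditions[j]),
                mean_difference=diff,
                p_adjusted=min(1.0, raw_p * len(pairs)),
            )
        )
    return AnovaResult(
        F=float(F), df1=df1, df2=df2, p=float(p), eta_sq=float(eta_sq),
        pairwise=tuple(pairwise), n_used=n, n_dropped=n_dropped,
    )


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled standard deviation denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled_var = (
        (n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var == 0:
        return 0.0
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def two_sample_t(
    x, y, variant: str = "pooled", alternative: str = "two-sided"
) -> TTestResult:
    """Independent two-sample t-test with Cohen's d.

    variant='pooled' assumes equal variances (df = n1+n2-2);
    variant='welch' uses the Satterthwaite df.  A fully degenerate input
    (zero variance in both groups, equal means) returns t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")

    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2 if variant == "pooled" else float(len(x) + len(y) - 2)
        return TTestResult(0.0, float(df), 1.0, alternative, 0.0, variant,
                           n1=len(x), n2=len(y))

    res = sps.ttest_ind(
        x, y, equal_var=(variant == "pooled"), alternative=alternative
    )
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        alternative=alternative, d=cohens_d(x, y), variant=variant,
        n1=len(x), n2=len(y),
    )


def significance_stars(p: float) -> str:
    """Table-footnote star convention: * p<.05, ** p<.01, *** p<.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_collectives(
    frame: pd.DataFrame,
    grouping,
    variant: str = "pooled",
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sample t-test per parameter between the two groups of a
    demographic split (gender, proficiency, age median split, ...).

    Returns one row per parameter with t, df, p (two-sided), Cohen's d,
    one-sided direction, the group means, and significance stars.
    Parameters with fewer than 2 usable values in a group are flagged.
    """
    from .metrics import SCALAR_FIELDS, group_labels

    params = parameters or [c for c in SCALAR_FIELDS if c in frame.columns]
    labels = group_labels(frame, grouping)
    names = sorted(labels.dropna().unique())
    if len(names) != 2:
        raise ValueError(f"grouping must yield exactly 2 groups, got {names}")
    g1, g2 = names
    rows = []
    for p in params:
        x = pd.to_numeric(frame.loc[labels == g1, p], errors="coerce").dropna()
        y = pd.to_numeric(frame.loc[labels == g2, p], errors="coerce").dropna()
        row = {
            "parameter": p, "group_1": g1, "group_2": g2,
            "n1": len(x), "n2": len(y),
            "mean_1": x.mean() if len(x) else np.nan,
            "mean_2": y.mean() if len(y) else np.nan,
        }
        if len(x) < 2 or len(y) < 2:
            row.update(t=np.nan, df=np.nan, p=np.nan, d=np.nan,
                       stars="", direction="insufficient data")
        else:
            res = two_sample_t(x, y, variant=variant)
            direction = g1 if res.t > 0 else (g2 if res.t < 0 else "none")
            row.update(t=res.t, df=res.df, p=res.p, d=res.d,
                       stars=significance_stars(res.p), direction=direction)
        rows.append(row)
    return pd.DataFrame(rows)
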