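"""Inferential statistics for cohort comparisons.

Implements, from their defining formulas, every test used downstream of the
HS scores: unpaired two-tailed t tests with the 95% CI of the mean
difference, chi-square tests with Woolf (log-scale) odds-ratio CIs, Pearson
correlation with Fisher-z CIs, Mann-Whitney ROC/AUC with Hanley-McNeil CIs,
Benjamini-Yekutieli FDR control, and the group main effect of a two-way
(group x location) repeated-measures ANOVA. Distribution quantiles come
from scipy; the arithmetic of each statistic is written out so it can be
checked against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cube import HSScoreTable, LOCATIONS
from .errors import StatsError

__all__ = [
    "TTestResult",
    "OddsRatioResult",
    "CorrelationResult",
    "RocResult",
    "FdrResult",
    "AnovaResult",
    "ttest_from_summary",
    "ttest_from_samples",
    "odds_ratio_2x2",
    "pearson_corr",
    "roc_auc",
    "by_fdr",
    "rm_anova_group_effect",
]


@dataclass
class TTestResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    variant: Literal["pooled", "welch"]


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    chi2: float
    p: float
    orientation: str


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class FdrResult:
    pvalues: np.ndarray
    reject: np.ndarray
    q: float
    threshold_index: int  # number of rejected hypotheses in sorted order


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def ttest_from_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    variant: Literal["pooled", "welch"] = "pooled",
) -> TTestResult:
    """Unpaired two-tailed t test from group summaries.

    The effect size is ``mean2 - mean1`` with its 95% CI. The pooled
    variant (classical Student t) is the default.
    """
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise StatsError("standard deviations must be non-negative")
    diff = mean2 - mean1
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if se > 0 else n1 + n2 - 2
    if se == 0:
        if diff == 0:
            return TTestResult(0.0, 0.0, 0.0, np.nan, df, np.nan, variant)
        t = np.inf if diff > 0 else -np.inf
        return TTestResult(diff, diff, diff, t, df, 0.0, variant)
    t = diff / se
    tcrit = sps.t.ppf(0.975, df)
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(diff, diff - tcrit * se, diff + tcrit * se, t, df, p, variant)


def ttest_from_samples(
    x1: Sequence[float], x2: Sequence[float],
    variant: Literal["pooled", "welch"] = "pooled",
) -> TTestResult:
    """Unpaired t test from raw samples; effect size is mean(x2) - mean(x1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return ttest_from_summary(
        len(x1), x1.mean(), x1.std(ddof=1),
        len(x2), x2.mean(), x2.std(ddof=1),
        variant=variant,
    )


def odds_ratio_2x2(a: int, b: int, c: int, d: int, orientation: str = "") -> OddsRatioResult:
    """Odds ratio and chi-square test for a 2x2 table ``[[a, b], [c, d]]``.

    OR = (a*d)/(b*c); the 95% CI uses the Woolf log method
    ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))`` and is unavailable
    (None) when any cell is zero — no continuity correction is applied. The
    chi-square statistic is the classical Pearson form without Yates
    correction. ``orientation`` is a free-text record of which category is
    the event and which group is the numerator, because published tables
    are not always consistent about this.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or not np.allclose(cells, np.round(cells)):
        raise StatsError("cell counts must be non-negative integers")
    n = cells.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise StatsError("a margin of the 2x2 table is zero")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = sps.chi2.sf(chi2, df=1)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    if np.all(cells > 0):
        log_se = np.sqrt((1 / cells).sum())
        ci_low = float(np.exp(np.log(odds) - 1.96 * log_se))
        ci_high = float(np.exp(np.log(odds) + 1.96 * log_se))
    else:
        ci_low = ci_high = None
    return OddsRatioResult(float(odds), ci_low, ci_high, float(chi2), float(p), orientation)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with Fisher-z 95% CI and t-based two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise StatsError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("correlation undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        ci_low = ci_high = r  # degenerate: Fisher z diverges at |r| = 1
    else:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        ci_low, ci_high = np.tanh(z - half), np.tanh(z + half)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(r, float(ci_low), float(ci_high), float(p), n)


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> RocResult:
    """ROC curve and Mann-Whitney AUC of 'case' over 'control' scores.

    Ties count one half. The 95% CI uses the Hanley-McNeil standard error;
    the p value tests AUC = 0.5 by normal approximation with the same SE.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = scores[labels == "case"]
    control = scores[labels == "control"]
    n1, n0 = len(case), len(control)
    if n1 == 0 or n0 == 0:
        raise StatsError("both classes must be present")
    greater = (case[:, None] > control[None, :]).sum()
    ties = (case[:, None] == control[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (n1 * n0))

    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    tpr = np.array([(case >= t).mean() for t in thresholds])
    fpr = np.array([(control >= t).mean() for t in thresholds])

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    ci_low = float(np.clip(auc - 1.96 * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + 1.96 * se, 0.0, 1.0))
    # null SE of the Mann-Whitney AUC without ties: sqrt((n1+n0+1)/(12 n1 n0))
    se_null = np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))
    p = float(2 * sps.norm.sf(abs(auc - 0.5) / se_null))
    return RocResult(auc, ci_low, ci_high, p, fpr, tpr)


def by_fdr(pvalues: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini-Yekutieli FDR control, valid under arbitrary dependence.

    Rejects the hypotheses with the i* smallest p values, where
    ``i* = max{i : p_(i) <= i*q / (m*c(m))}`` and ``c(m) = sum_{j<=m} 1/j``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return FdrResult(p, np.zeros(0, dtype=bool), q, 0)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p values must lie in [0, 1]")
    m = p.size
    cm = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = np.arange(1, m + 1) * q / (m * cm)
    passing = np.nonzero(sorted_p <= thresholds)[0]
    i_star = int(passing[-1] + 1) if passing.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:i_star]] = True
    return FdrResult(p, reject, q, i_star)


def rm_anova_group_effect(table: HSScoreTable, locations: Sequence[str] = LOCATIONS) -> AnovaResult:
    """Between-subjects group main effect of a two-way mixed ANOVA.

    The design is group (between, 2 levels) x location (within, repeated
    over the six retinal sampling regions). The group effect is tested
    against subjects-within-groups: ``F = MS_group / MS_subj(group)`` with
    df (1, n_subjects - 2). Requires complete data (every location for
    every subject); missing cells raise rather than impute.
    """
    frame = table.frame[table.frame["location_id"].isin(locations)]
    wide = frame.pivot_table(index=["subject_id", "label"], columns="location_id",
                             values="score", aggfunc="first")
    if wide.isna().any().any() or wide.shape[1] != len(locations):
        missing = wide.columns[wide.isna().any()].tolist() if wide.shape[1] == len(locations) else locations
        raise StatsError(f"incomplete score table for locations {list(missing)}")
    labels = wide.index.get_level_values("label").to_numpy()
    groups = np.unique(labels)
    if len(groups) != 2:
        raise StatsError("exactly two groups required")
    Y = wide.to_numpy()  # subjects x locations
    n, L = Y.shape
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    ss_group = 0.0
    ss_subj_within = 0.0
    for g in groups:
        sel = labels == g
        g_mean = Y[sel].mean()
        ss_group += sel.sum() * L * (g_mean - grand) ** 2
        ss_subj_within += L * ((subj_means[sel] - g_mean) ** 2).sum()
    df1, df2 = 1, n - 2
    ms_group = ss_group / df1
    ms_subj = ss_subj_within / df2
    if ms_subj == 0:
        raise StatsError("zero between-subject variance; F undefined")
    F = ms_group / ms_subj
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p)
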