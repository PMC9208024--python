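"""Cognitive classification, covariate-adjusted group statistics, ROC.

Implements the statistical toolkit of the analysis: the z-score rule
that splits patients into cognitively impaired (CI) versus preserved
(CP), general-linear-model group comparisons with covariates and
pairwise contrasts, Pearson/Spearman correlations, Bonferroni alpha
adjustment, and rank-based ROC evaluation of coupling values as a
candidate biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupComparison",
    "ROCResult",
    "classify_cognitive_status",
    "glm_group_compare",
    "correlate",
    "bonferroni_alpha",
    "roc_analysis",
]

COGNITIVE_DOMAINS = (
    "verbal_memory",
    "visuospatial_memory",
    "information_processing_speed",
    "working_memory",
    "verbal_fluency",
    "executive_function",
    "attention",
)


def classify_cognitive_status(
    domain_z: np.ndarray,
    threshold: float = -2.0,
    min_domains: int = 2,
) -> str:
    """Label a patient CI or CP from cognitive-domain z-scores.

    A patient is cognitively impaired (CI) when at least ``min_domains``
    domain z-scores fall at or below ``threshold`` (z <= -2 by default,
    i.e. two HC standard deviations below the HC mean); otherwise
    cognitively preserved (CP).  Missing values are not imputed.
    """
    z = np.asarray(domain_z, dtype=float)
    if z.ndim != 1 or z.size < min_domains:
        raise ValueError(
            f"need at least {min_domains} domain z-scores, got {z.size}"
        )
    if np.any(np.isnan(z)):
        raise ValueError("missing domain z-scores; classification requires all domains")
    return "CI" if int(np.sum(z <= threshold)) >= min_domains else "CP"


@dataclass
class GroupComparison:
    """Omnibus and pairwise results of a covariate-adjusted group model."""

    outcome: str
    F: float
    p: float
    df_num: int
    df_den: int
    adjusted_means: dict[str, float]
    pairwise: dict[tuple[str, str], float]
    covariates: list[str] = field(default_factory=list)
    n: int = 0


def glm_group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | dict | None = None,
    outcome: str = "outcome",
    group_order: list[str] | None = None,
) -> GroupComparison:
    """General linear model comparing an outcome between groups.

    Fits ordinary least squares with group indicator variables plus the
    supplied covariates (e.g. age and sex), reports the omnibus F test
    for the group factor, covariate-adjusted group means (predictions at
    the sample-mean covariate values), and pairwise group contrasts on
    the full adjusted model with unadjusted p-values, to be gated by a
    Bonferroni-corrected alpha downstream.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 1 or groups.shape != values.shape:
        raise ValueError("values and groups must be 1-d with equal length")
    if np.any(np.isnan(values)):
        keep = ~np.isnan(values)
        values, groups = values[keep], groups[keep]
        covariates = (
            None
            if covariates is None
            else pd.DataFrame(covariates).loc[keep].reset_index(drop=True)
        )
    levels = group_order if group_order is not None else sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    counts = pd.Series(groups).value_counts()
    thin = [g for g in levels if counts.get(g, 0) < 2]
    if thin:
        raise ValueError(f"need at least 2 subjects per group; too few in {thin}")

    n = values.size
    cov_df = pd.DataFrame(index=range(n))
    if covariates is not None:
        cov_df = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
    # reference coding: intercept + dummies for all but the first level
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X = np.column_stack([np.ones(n), dummies, cov_df.to_numpy()]) if cov_df.shape[1] else np.column_stack([np.ones(n), dummies])
    colnames = (
        ["intercept"]
        + [f"group[{g}]" for g in levels[1:]]
        + list(cov_df.columns.astype(str))
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"check collinearity among columns {colnames}"
        )
    model = sm.OLS(values, X).fit()

    k = len(levels) - 1
    R = np.zeros((k, X.shape[1]))
    for i in range(k):
        R[i, 1 + i] = 1.0
    ftest = model.f_test(R)
    F = float(np.squeeze(ftest.fvalue))
    p = float(ftest.pvalue)

    cov_means = cov_df.to_numpy().mean(axis=0) if cov_df.shape[1] else np.empty(0)
    beta = model.params
    adjusted_means = {}
    for g in levels:
        row = np.zeros(X.shape[1])
        row[0] = 1.0
        if g != levels[0]:
            row[1 + levels[1:].index(g)] = 1.0
        row[1 + k :] = cov_means
        adjusted_means[g] = float(row @ beta)

    pairwise: dict[tuple[str, str], float] = {}
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            ga, gb = levels[a], levels[b]
            contrast = np.zeros(X.shape[1])
            if ga != levels[0]:
                contrast[1 + levels[1:].index(ga)] = 1.0
            if gb != levels[0]:
                contrast[1 + levels[1:].index(gb)] -= 1.0
            tt = model.t_test(contrast)
            pairwise[(ga, gb)] = float(np.squeeze(tt.pvalue))

    return GroupComparison(
        outcome=outcome,
        F=F,
        p=p,
        df_num=int(ftest.df_num),
        df_den=int(ftest.df_denom),
        adjusted_means=adjusted_means,
        pairwise=pairwise,
        covariates=list(cov_df.columns.astype(str)),
        n=n,
    )


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    The p-value uses the exact t transform with n - 2 degrees of
    freedom; for Spearman it is applied to the rank-transformed data.
    The choice of method is explicit (Spearman for outcomes judged
    non-normal), never inferred automatically.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        r, _ = sps.pearsonr(rx, ry)
        n = x.size
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'pearson' or 'spearman'")
    return float(r), float(p)


def bonferroni_alpha(base_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-adjusted significance level: base_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0 < base_alpha < 1:
        raise ValueError("base_alpha must lie in (0, 1)")
    return base_alpha / n_tests


@dataclass
class ROCResult:
    """ROC summary for a continuous score classifying CI vs CP."""

    auc: float
    p: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_positive: int = 0
    n_negative: int = 0


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    n1, n0 = pos.size, neg.size
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    positive: str = "CI",
    n_bootstrap: int | None = None,
    rng: np.random.Generator | None = None,
) -> ROCResult:
    """ROC analysis of a score as a classifier of the positive class.

    The AUC is the rank-based (Mann-Whitney) estimate with ties counted
    as 1/2; orientation is fixed so that a higher score predicts the
    positive class.  The two-sided p-value against AUC = 0.5 uses a
    normal approximation with the Hanley-McNeil standard error evaluated
    under the null.  The optimal cutoff maximizes sensitivity +
    specificity over all observed score thresholds (predict positive
    when score >= cutoff), with ties broken toward the lower threshold.
    An optional bootstrap p-value resamples subjects within classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d with equal length")
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"both classes must be non-empty (positive={pos.size}, negative={neg.size})"
        )
    auc = _auc_mann_whitney(pos, neg)
    n1, n0 = pos.size, neg.size
    # Hanley-McNeil SE under H0: AUC = 0.5 (Q1 = Q2 = 1/3)
    se0 = np.sqrt((0.25 + (n1 + n0 - 2) / 12.0) / (n1 * n0))
    z = (auc - 0.5) / se0
    p = float(2.0 * sps.norm.sf(abs(z)))
    if n_bootstrap:
        gen = rng if rng is not None else np.random.default_rng(0)
        null_shift = np.concatenate([pos - pos.mean(), neg - neg.mean()])
        stats = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bp = gen.choice(null_shift, size=n1, replace=True)
            bn = gen.choice(null_shift, size=n0, replace=True)
            stats[b] = _auc_mann_whitney(bp, bn)
        p = float((1.0 + np.sum(np.abs(stats - 0.5) >= abs(auc - 0.5))) / (n_bootstrap + 1.0))

    cutoff, sens, spec, best = np.nan, np.nan, np.nan, -np.inf
    for c in np.unique(scores):  # ascending, so ties resolve to the lower threshold
        s = float(np.mean(pos >= c))
        sp = float(np.mean(neg < c))
        if s + sp > best + 1e-12:
            best, cutoff, sens, spec = s + sp, float(c), s, sp
    return ROCResult(
        auc=auc,
        p=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_positive=n1,
        n_negative=n0,
    )
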