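"""Cohort statistics: covariate-adjusted group comparisons, effect sizes,
FDR control, correlations and paired longitudinal tests.

The group comparison is an ANCOVA-style linear model ``y ~ group + age +
sex``; with an empty covariate set it reduces exactly to classical one-way
ANOVA. Multiplicity is controlled per declared analysis family with
Benjamini-Hochberg FDR; pairwise contrasts are model-based, without an
additional Tukey layer, so exactly one multiplicity scheme applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError


@dataclass
class Contrast:
    pair: tuple[str, str]          # (a, b): estimate = adjusted mean(a) - mean(b)
    estimate: float
    p: float
    cohens_d: float
    p_fdr: float | None = None


@dataclass
class GroupComparison:
    outcome: str
    f_stat: float
    df_num: int
    df_den: int
    p_omnibus: float
    contrasts: list[Contrast]
    covariates: tuple[str, ...]
    group_means: dict[str, float] = field(default_factory=dict)


@dataclass
class CorrelationRecord:
    x: str
    y: str
    method: str
    n: int
    r: float
    p: float
    p_fdr: float | None = None


@dataclass
class PairedComparison:
    outcome: str
    n_pairs: int
    mean_difference: float  # follow-up minus baseline
    t_stat: float
    p: float
    p_fdr: float | None = None
    degenerate_variance: bool = False


def cohens_d(x, y) -> float:
    """Cohen's d: mean difference over the pooled standard deviation.

    Uses Cohen's original pooling, sqrt((SS_x + SS_y) / (n_x + n_y)) with
    maximum-likelihood (n-denominator) sums of squares; for two unit-SD
    samples the pooled SD is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("cohens_d needs at least two values per sample")
    pooled_var = (x.size * x.var(ddof=0) + y.size * y.var(ddof=0)) / (x.size + y.size)
    if pooled_var <= 0:
        raise ValidationError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ancova_compare(
    y,
    group,
    covariates: pd.DataFrame | None = None,
    outcome: str = "y",
) -> GroupComparison:
    """Compare an outcome across groups adjusting for covariates.

    Fits ``y ~ group + covariates`` by OLS with dummy-coded groups; the
    omnibus F tests the joint group effect (a partial F against the
    covariate-only model, which is the classical one-way ANOVA F when no
    covariates are supplied). Pairwise contrasts are differences of
    adjusted group means from the same fit; each carries Cohen's d taken
    as the adjusted difference scaled by the two groups' pooled raw SD so
    effect-size sign always matches the contrast.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=object)
    if y.shape[0] != group.shape[0]:
        raise ValidationError("y and group lengths differ")
    levels = sorted(set(group))
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    for g in levels:
        if (group == g).sum() < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 subjects")
    if np.ptp(y) == 0:
        raise ValidationError(f"{outcome}: outcome is constant; model is degenerate")

    n = y.shape[0]
    cov_names: tuple[str, ...] = ()
    cov_block = np.empty((n, 0))
    if covariates is not None and len(covariates.columns) > 0:
        if len(covariates) != n:
            raise ValidationError("covariate table length differs from y")
        if covariates.isna().any().any():
            raise ValidationError("covariates contain missing values")
        cols = []
        names = []
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype == object or str(v.dtype) == "category":
                codes, uniq = pd.factorize(v)
                for lev_i, lev in enumerate(uniq[1:], start=1):
                    cols.append((codes == lev_i).astype(float))
                    names.append(f"{c}[{lev}]")
            else:
                cols.append(v.to_numpy(dtype=float))
                names.append(str(c))
        cov_block = np.column_stack(cols) if cols else np.empty((n, 0))
        cov_names = tuple(names)

    # dummy coding: first level is the reference
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    X_full = np.column_stack([np.ones(n), dummies, cov_block])
    X_red = np.column_stack([np.ones(n), cov_block])

    full = OLS(y, X_full).fit()
    red = OLS(y, X_red).fit()
    df_num = len(levels) - 1
    df_den = int(full.df_resid)
    if df_den <= 0:
        raise ValidationError("model has no residual degrees of freedom")
    ss_diff = red.ssr - full.ssr
    if full.ssr <= 0:
        raise ValidationError(f"{outcome}: saturated model; omnibus F undefined")
    f_stat = (ss_diff / df_num) / (full.ssr / df_den)
    p_omnibus = float(sps.f.sf(f_stat, df_num, df_den))

    # adjusted group means at mean covariate values
    beta = full.params
    cov_mean = cov_block.mean(axis=0) if cov_block.size else np.empty(0)
    adj_means = {}
    for gi, g in enumerate(levels):
        x = np.concatenate(
            [[1.0], np.eye(len(levels))[gi][1:], cov_mean]
        )
        adj_means[g] = float(x @ beta)

    contrasts = []
    for a, b in combinations(levels, 2):
        # contrast vector for adjusted mean(a) - adjusted mean(b)
        ca = np.zeros(X_full.shape[1])
        if a != levels[0]:
            ca[levels.index(a)] += 1.0
        if b != levels[0]:
            ca[levels.index(b)] -= 1.0
        tt = full.t_test(ca)
        est = float(np.atleast_1d(tt.effect)[0])
        p = float(np.atleast_1d(tt.pvalue)[0])
        xa, xb = y[group == a], y[group == b]
        na, nb = xa.size, xb.size
        pooled = (na * xa.var(ddof=0) + nb * xb.var(ddof=0)) / (na + nb)
        d = est / np.sqrt(pooled) if pooled > 0 else np.sign(est) * np.inf
        contrasts.append(Contrast(pair=(a, b), estimate=est, p=p, cohens_d=float(d)))

    return GroupComparison(
        outcome=outcome,
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_omnibus=p_omnibus,
        contrasts=contrasts,
        covariates=cov_names,
        group_means=adj_means,
    )


def adjust_contrast_family(comparisons: list[GroupComparison]) -> None:
    """Apply BH-FDR across all pairwise contrasts of one analysis family."""
    flat = [c for gc in comparisons for c in gc.contrasts]
    if not flat:
        return
    adj = fdr_bh([c.p for c in flat])
    for c, q in zip(flat, adj):
        c.p_fdr = float(q)


def is_normal(x, alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov-type normality pre-check (Lilliefors variant,
    since mean and SD are estimated from the sample)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False
    return lilliefors(x, dist="norm")[1] >= alpha


def correlate(x, y, method: str = "pearson", x_name: str = "x", y_name: str = "y") -> CorrelationRecord:
    """Pearson or Spearman correlation with a two-sided p-value.

    ``method="auto"`` picks Pearson when both variables pass the normality
    pre-check and Spearman otherwise (the choice is recorded in the result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in x or y")
    if method == "auto":
        method = "pearson" if (is_normal(x) and is_normal(y)) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return CorrelationRecord(
        x=x_name, y=y_name, method=method, n=int(x.size), r=float(r), p=float(p)
    )


def adjust_correlation_family(records: list[CorrelationRecord]) -> None:
    adj = fdr_bh([r.p for r in records]) if records else []
    for rec, q in zip(records, adj):
        rec.p_fdr = float(q)


def paired_compare(baseline, followup, outcome: str = "y") -> PairedComparison:
    """Paired t-test on follow-up minus baseline differences."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape:
        raise ValidationError("baseline and follow-up must be aligned 1:1")
    ok = np.isfinite(b) & np.isfinite(f)
    b, f = b[ok], f[ok]
    if b.size < 3:
        raise ValidationError("paired comparison needs at least 3 complete pairs")
    d = f - b
    if np.all(d == 0):
        return PairedComparison(outcome, int(b.size), 0.0, 0.0, 1.0)
    if d.std(ddof=1) == 0:
        # nonzero constant differences: t diverges, p -> 0
        return PairedComparison(
            outcome, int(b.size), float(d.mean()),
            float(np.sign(d.mean()) * np.inf), 0.0, degenerate_variance=True,
        )
    t, p = sps.ttest_rel(f, b)
    return PairedComparison(outcome, int(b.size), float(d.mean()), float(t), float(p))
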