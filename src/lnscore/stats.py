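"""Statistics shared across the pipeline.

Simple linear regression with F-test and confidence/prediction bands (via
statsmodels OLS), one-way ANOVA in both raw-data and summary-statistics
forms (the latter lets published per-group n/mean/SD tables be re-analysed
without raw data), a pairwise-complete Spearman correlation matrix, and a
cluster-robust two-group comparison for episode-level data where repeated
episodes of one patient are correlated (an independence-working-model
estimating-equation analysis with a sandwich variance, i.e. the identity
link GEE case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError, ValidationError


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    x: np.ndarray
    fitted: np.ndarray
    confidence_band: np.ndarray  # (n, 2) 95% CI for the conditional mean
    prediction_band: np.ndarray  # (n, 2) 95% interval for a new observation
    level: float = 0.95


@dataclass
class AnovaResult:
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r_squared: float  # SS_between / SS_total
    ss_between: float
    ss_within: float
    group_stats: list[tuple[int, float, float]]  # (n, mean, sd) per group


@dataclass
class CorrelationMatrix:
    names: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame  # complete pairs per cell


@dataclass
class ClusteredComparison:
    groups: tuple[str, str]
    mean_difference: float  # mean(second) - mean(first)
    robust_se: float
    wald_z: float
    p_value: float


def ols_fit(x, y, level: float = 0.95) -> RegressionFit:
    """Least-squares line of y on x with F-test and 95 % bands."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise DomainError("x is constant: degenerate design")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    conf = pred.conf_int(obs=False, alpha=1 - level)
    predb = pred.conf_int(obs=True, alpha=1 - level)
    fvalue = float(fit.fvalue)
    pvalue = float(fit.f_pvalue)
    rsq = float(fit.rsquared)
    if not np.isfinite(fvalue):
        if fit.ess <= 1e-12 * (1 + abs(float(np.mean(y)))):  # flat response
            fvalue, pvalue, rsq = 0.0, 1.0, 0.0
        else:  # y exactly on a non-degenerate line
            fvalue, pvalue, rsq = np.inf, 0.0, 1.0
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        f_stat=fvalue,
        df=(1, int(fit.df_resid)),
        p_value=pvalue,
        r_squared=rsq,
        x=x,
        fitted=np.asarray(fit.fittedvalues),
        confidence_band=np.asarray(conf),
        prediction_band=np.asarray(predb),
        level=level,
    )


def _anova_from_ss(ssb: float, ssw: float, k: int, n_total: int, group_stats) -> AnovaResult:
    df1, df2 = k - 1, n_total - k
    if df1 < 1 or df2 < 1:
        raise InsufficientDataError("need k >= 2 groups and N - k >= 1")
    sst = ssb + ssw
    if sst <= 0:  # all values identical
        return AnovaResult(0.0, (df1, df2), 1.0, 0.0, 0.0, 0.0, group_stats)
    if ssw == 0:
        return AnovaResult(np.inf, (df1, df2), 0.0, 1.0, ssb, 0.0, group_stats)
    f = (ssb / df1) / (ssw / df2)
    return AnovaResult(
        float(f), (df1, df2), float(sps.f.sf(f, df1, df2)), float(ssb / sst),
        float(ssb), float(ssw), group_stats,
    )


def oneway_anova(groups: list) -> AnovaResult:
    """Classic one-way ANOVA (no Welch adjustment) on raw per-group data."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise InsufficientDataError("need >= 2 groups, each with >= 1 value")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    stats = [
        (int(a.size), float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else float("nan"))
        for a in arrays
    ]
    return _anova_from_ss(ssb, ssw, len(arrays), n_total, stats)


def anova_from_summary(group_stats: list[tuple[int, float, float]]) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, sd) summary statistics.

    Identical to :func:`oneway_anova` applied to raw data with the same
    summaries: SSB = Σ nᵢ(mᵢ − m̄)², SSW = Σ (nᵢ − 1) sᵢ².
    """
    if len(group_stats) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for n, _, sd in group_stats:
        if n < 2 and sd not in (0.0, None) and not np.isnan(sd):
            raise ValidationError(f"group with n={n} cannot carry a nonzero sd")
    ns = np.array([g[0] for g in group_stats], dtype=float)
    ms = np.array([g[1] for g in group_stats], dtype=float)
    sds = np.array([0.0 if (g[0] < 2 or g[2] is None) else g[2] for g in group_stats])
    n_total = int(ns.sum())
    grand = float((ns * ms).sum() / n_total)
    ssb = float((ns * (ms - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    stats = [(int(n), float(m), float(s)) for n, m, s in zip(ns, ms, sds)]
    return _anova_from_ss(ssb, ssw, len(group_stats), n_total, stats)


def merge_summary_groups(
    group_stats: list[tuple[int, float, float]], partition: list[list[int]]
) -> list[tuple[int, float, float]]:
    """Pool summary groups exactly (merged mean weighted; merged SS preserved).

    Pooling keeps the total sum of squares unchanged, so a two-group ANOVA on
    the merged summaries tests the coarser grouping against the same SST.
    """
    out = []
    for idx in partition:
        ns = np.array([group_stats[i][0] for i in idx], dtype=float)
        ms = np.array([group_stats[i][1] for i in idx], dtype=float)
        sds = np.array([group_stats[i][2] for i in idx], dtype=float)
        n = ns.sum()
        m = (ns * ms).sum() / n
        ss = ((ns - 1) * sds**2).sum() + (ns * (ms - m) ** 2).sum()
        out.append((int(n), float(m), float(np.sqrt(ss / (n - 1)))))
    return out


def spearman_matrix(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman rank-correlation matrix with p-values.

    Ties get average ranks; p-values use the t approximation.  Cells with
    fewer than ``min_pairs`` complete pairs are NaN (flagged via ``n``).
    """
    names = list(table.columns)
    k = len(names)
    rho = np.eye(k)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, 0.0)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = table[names[i]].notna().sum()
        for j in range(i + 1, k):
            pair = table[[names[i], names[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_pairs:
                rho[i, j] = rho[j, i] = np.nan
                continue
            r, pv = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(
        names,
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
        pd.DataFrame(n, index=names, columns=names),
    )


def clustered_compare(values, cluster_ids, group_ids) -> ClusteredComparison:
    """Two-group mean comparison with cluster-robust (sandwich) inference.

    Point estimates come from an independence working model (plain group
    means); the variance treats each cluster (patient) as the independent
    unit, so repeated episodes of one patient do not inflate precision.
    Each group's variance uses the cluster-level sandwich with a G/(G−1)
    small-sample factor (G clusters in the group), which reduces exactly to
    the classic Welch two-sample comparison when every cluster holds one
    episode.  Clusters must be nested in groups.
    """
    y = np.asarray(values, dtype=float)
    clusters = np.asarray(cluster_ids)
    groups = np.asarray(group_ids)
    if not (y.size == clusters.size == groups.size):
        raise ValidationError("values, cluster_ids and group_ids must align")
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    group_means = {}
    group_var = {}
    seen_clusters: dict = {}
    for lev in levels:
        mask = groups == lev
        cl = clusters[mask]
        uniq = pd.unique(cl)
        for c in uniq:
            if c in seen_clusters and seen_clusters[c] != lev:
                raise ValidationError(f"cluster {c!r} appears in both groups")
            seen_clusters[c] = lev
        g_count = len(uniq)
        if g_count < 2:
            raise InsufficientDataError(f"group {lev!r} has < 2 clusters")
        n_g = int(mask.sum())
        mean_g = float(y[mask].mean())
        resid = y[mask] - mean_g
        cluster_sums = np.array([resid[cl == c].sum() for c in uniq])
        group_means[lev] = mean_g
        group_var[lev] = (g_count / (g_count - 1)) * float((cluster_sums**2).sum()) / n_g**2
    diff = group_means[levels[1]] - group_means[levels[0]]
    se = float(np.sqrt(group_var[levels[0]] + group_var[levels[1]]))
    if se == 0:
        z, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
    else:
        z = diff / se
        p = float(2 * sps.norm.sf(abs(z)))
    return ClusteredComparison((str(levels[0]), str(levels[1])), float(diff), se, float(z), p)
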