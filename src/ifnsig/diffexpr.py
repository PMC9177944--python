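"""Two-group differential expression on negative-binomial counts.

A deliberately transparent re-implementation of the median-of-ratios +
NB Wald-test workflow: per-gene dispersions are method-of-moments estimates
shrunk toward a baseMean-binned trend (no empirical-Bayes machinery), the
log2 fold change is computed from group means of normalized counts with a
0.5 pseudocount, and the Wald statistic log2FC / SE(log2FC) is referred to
the standard normal.  False-discovery control is Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, NormalizedMatrix, normalize, size_factors

__all__ = ["nb_wald_test", "bh_adjust", "classify_degs", "volcano_table"]

_LN2 = np.log(2.0)
_MIN_DISPERSION = 1e-8
_PSEUDOCOUNT = 0.5


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} p_(j) * m / j, clipped to [0, 1], reported
    in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def _dispersion_trend(base_mean: np.ndarray, phi_mom: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Median moment dispersion in log-baseMean bins, interpolated back."""
    ok = base_mean > 0
    logm = np.log10(base_mean[ok])
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return np.full_like(phi_mom, max(np.median(phi_mom[ok]), _MIN_DISPERSION))
    which = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, len(edges) - 2)
    centers, medians = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() >= 3:
            centers.append(logm[sel].mean())
            medians.append(np.median(phi_mom[ok][sel]))
    trend = np.full(base_mean.shape, np.median(phi_mom[ok]))
    if len(centers) >= 2:
        trend[ok] = np.interp(logm, centers, medians)
    return np.maximum(trend, _MIN_DISPERSION)


def nb_wald_test(
    matrix: CountMatrix,
    alpha: float = 0.05,
    shrinkage: float = 0.7,
) -> pd.DataFrame:
    """Per-gene FM-vs-CTL Wald test under an NB model.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc`` (FM relative to CTL), ``se``, ``stat``, ``p``, ``fdr`` and
    ``direction`` in {up, down, ns}.

    ``shrinkage`` is the weight pulling each moment dispersion toward the
    baseMean-trended median across genes; 0 disables shrinkage.
    """
    if matrix.groups is None:
        raise ValueError("count matrix needs CTL/FM group labels")
    ctl = matrix.samples_in_group("CTL")
    fm = matrix.samples_in_group("FM")
    if len(ctl) < 2 or len(fm) < 2:
        raise ValueError("each group needs at least 2 samples")
    counts = matrix.counts
    if (counts.sum(axis=1) == 0).any():
        bad = counts.index[counts.sum(axis=1) == 0][0]
        raise ValueError(f"all-zero gene reached the test stage: {bad!r}; filter first")

    s = size_factors(matrix)
    q = counts.div(s, axis=1)  # normalized counts
    base_mean = q.mean(axis=1).to_numpy()

    q_ctl = q[ctl].to_numpy()
    q_fm = q[fm].to_numpy()
    n1, n2 = len(ctl), len(fm)
    m1 = q_ctl.mean(axis=1)
    m2 = q_fm.mean(axis=1)
    log2fc = np.log2(m2 + _PSEUDOCOUNT) - np.log2(m1 + _PSEUDOCOUNT)

    # method-of-moments dispersion from pooled within-group variance:
    # Var(k_j / s_j) = mu / s_j + phi * mu^2
    inv_s = (1.0 / s).to_numpy()
    inv_s1 = inv_s[[matrix.sample_ids.index(x) for x in ctl]]
    inv_s2 = inv_s[[matrix.sample_ids.index(x) for x in fm]]
    v1 = q_ctl.var(axis=1, ddof=1)
    v2 = q_fm.var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu_pool = (n1 * m1 + n2 * m2) / (n1 + n2)
    shot = mu_pool * inv_s.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = (pooled_var - shot) / np.square(mu_pool)
    phi_mom = np.where(np.isfinite(phi_mom), phi_mom, _MIN_DISPERSION)
    phi_mom = np.maximum(phi_mom, _MIN_DISPERSION)

    trend = _dispersion_trend(base_mean, phi_mom)
    phi = np.maximum(shrinkage * trend + (1.0 - shrinkage) * phi_mom, _MIN_DISPERSION)

    # Var(log2 group mean) by the delta method on the normalized-count mean
    var_m1 = (m1 * inv_s1.mean() / n1) + phi * np.square(m1) / n1
    var_m2 = (m2 * inv_s2.mean() / n2) + phi * np.square(m2) / n2
    se = np.sqrt(
        var_m1 / np.square((m1 + _PSEUDOCOUNT) * _LN2)
        + var_m2 / np.square((m2 + _PSEUDOCOUNT) * _LN2)
    )
    se = np.maximum(se, 1e-12)
    stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    fdr = bh_adjust(p)

    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "fdr": fdr,
        },
        index=counts.index,
    )
    res["direction"] = np.where(
        res["fdr"] < alpha, np.where(res["log2fc"] > 0, "up", "down"), "ns"
    )
    return res


def classify_degs(results: pd.DataFrame, alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """Split genes into (up, down) sets at BH-adjusted p < alpha."""
    sig = results[results["fdr"] < alpha]
    up = set(sig.index[sig["log2fc"] > 0])
    down = set(sig.index[sig["log2fc"] < 0])
    return up, down


def volcano_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """log2FC vs -log10 p coordinates with a significance flag."""
    p = np.clip(results["p"].to_numpy(), np.finfo(float).tiny, None)
    return pd.DataFrame(
        {
            "log2fc": results["log2fc"],
            "neg_log10_p": -np.log10(p),
            "significant": results["fdr"] < alpha,
        },
        index=results.index,
    )
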