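"""Interferon-regulated gene annotation, enrichment and the IFN score.

The IFN score standardizes each panel gene against the control group:
z_gi = (x_gi - mu_g) / sigma_g with mu_g, sigma_g the mean and sample SD
(ddof=1) of the gene's expression in controls, and sums the six per-gene
scores per individual.  By construction the control-group mean of the
summed score is exactly 0 and the control SD of each gene's score row is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_PANEL",
    "load_gene_list",
    "annotate_ifn",
    "fisher_ifn_enrichment",
    "IfnScorePanel",
    "compute_ifn_score",
    "compare_ifn_scores",
]

logger = logging.getLogger(__name__)

#: six-gene interferon-score panel
DEFAULT_PANEL = ("IFI27", "IFI44L", "IFIT1", "ISG15", "RSAD2", "SIGLEC1")


def load_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' comment lines ignored."""
    symbols = set()
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            symbols.add(ln)
    if not symbols:
        raise ValueError(f"gene list {path} is empty")
    return symbols


def annotate_ifn(results: pd.DataFrame, ifn_genes: Iterable[str]) -> pd.DataFrame:
    """Add a boolean ``ifn_regulated`` column by case-insensitive membership."""
    ifn_set = {g.upper() for g in ifn_genes}
    if not ifn_set:
        raise ValueError("empty IFN annotation")
    flags = [str(g).upper() in ifn_set for g in results.index]
    out = results.copy()
    out["ifn_regulated"] = flags
    n_unmatched = len(flags) - sum(flags)
    logger.info("annotate_ifn: %d/%d genes not in the IFN list", n_unmatched, len(flags))
    return out


def fisher_ifn_enrichment(
    up_total: int, up_ifn: int, down_total: int, down_ifn: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test of IFN-membership between up and down DEGs.

    The 2x2 table is [[up_ifn, up_other], [down_ifn, down_other]]; the
    two-sided p sums hypergeometric outcomes with probability <= that of the
    observed table (minimum-likelihood rule).  Returns (sample odds ratio,
    p).
    """
    for name, total, k in (("up", up_total, up_ifn), ("down", down_total, down_ifn)):
        if not 0 <= k <= total:
            raise ValueError(f"inconsistent counts for {name} genes: {k}/{total}")
    table = [[up_ifn, up_total - up_ifn], [down_ifn, down_total - down_ifn]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class IfnScorePanel:
    """Standardized per-gene expression scores and their per-sample sum."""

    panel_genes: tuple[str, ...]
    control_mean: pd.Series
    control_sd: pd.Series
    expression_scores: pd.DataFrame  # genes x samples
    ifn_score: pd.Series  # per sample
    scale: str = "log2"


def compute_ifn_score(
    norm_expr: pd.DataFrame,
    control_ids: Sequence[str],
    panel: Sequence[str] = DEFAULT_PANEL,
    scale: str = "log2",
) -> IfnScorePanel:
    """Control-standardized expression scores and their six-gene sum.

    ``norm_expr`` is a gene x sample expression matrix (log2 normalized by
    default); ``control_ids`` are the samples defining mu_g and sigma_g
    (sample SD, ddof=1).  Scores are computed for every sample, control and
    case alike.
    """
    panel = tuple(panel)
    missing = [g for g in panel if g not in norm_expr.index]
    if missing:
        raise KeyError(f"panel gene(s) missing from expression matrix: {missing}")
    controls = [c for c in control_ids if c in norm_expr.columns]
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples")
    x = norm_expr.loc[list(panel)]
    mu = x[controls].mean(axis=1)
    sd = x[controls].std(axis=1, ddof=1)
    zero_sd = sd[sd == 0].index.tolist()
    if zero_sd:
        raise ValueError(f"zero control SD for panel gene(s): {zero_sd}")
    z = x.sub(mu, axis=0).div(sd, axis=0)
    score = z.sum(axis=0)
    score.name = "ifn_score"
    return IfnScorePanel(panel, mu, sd, z, score, scale=scale)


def compare_ifn_scores(
    scores: pd.Series,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Unpaired two-sided t-test between two groups of samples.

    Welch (unequal variances) by default; ``variant='student'`` pools the
    variance.  Returns (t, df, p).
    """
    a = scores.loc[list(group_a_ids)].to_numpy(dtype=float)
    b = scores.loc[list(group_b_ids)].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif variant == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return float(res.statistic), float(res.df), float(res.pvalue)
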