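"""Preranked gene-set enrichment (weighted Kolmogorov-Smirnov running sum).

Genes are ranked by r = sign(log2FC) * -log10(p).  Walking down the ranked
list, genes in the set increment the running sum by |r|^weight normalized
by the in-set total, genes outside decrement it by 1/(N - set size); the
enrichment score (ES) is the running-sum value of maximal absolute
deviation.  The null is a gene-label permutation: set members are assigned
to uniformly random positions of the same ranked list.  NES divides ES by
the mean |ES| of same-sign permutations, the permutation p-value uses the
(1 + exceedances) / (1 + same-sign permutations) estimator, and FDR across
sets is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust

__all__ = ["rank_metric", "make_ranked_list", "load_gmt", "enrichment_score", "gsea_preranked", "GseaResult"]

logger = logging.getLogger(__name__)


def rank_metric(log2fc, p) -> np.ndarray:
    """r = sign(log2FC) * -log10(p); p = 0 is clamped with a warning."""
    lfc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (pv == 0).any():
        warnings.warn("p = 0 clamped to the smallest positive float", stacklevel=2)
        pv = np.clip(pv, np.finfo(float).tiny, None)
    return np.sign(lfc) * -np.log10(pv)


def make_ranked_list(results: pd.DataFrame) -> pd.Series:
    """Ranked metric series from a DE table (columns log2fc, p).

    Sorted by metric descending with ties broken by gene id ascending, so
    the ordering is reproducible.
    """
    r = pd.Series(rank_metric(results["log2fc"], results["p"]), index=results.index, name="rank_metric")
    order = sorted(r.index, key=lambda g: (-r[g], str(g)))
    return r.loc[order]


def load_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    path = Path(path)
    text = path.read_text()
    sets: dict[str, list[str]] = {}
    n_lines = 0
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip():
            continue
        n_lines += 1
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (need name, description, >=1 gene)")
        name = parts[0]
        members = list(dict.fromkeys(g for g in parts[2:] if g))
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = members
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def _es_from_positions(pos: np.ndarray, absr_w: np.ndarray, n: int) -> np.ndarray:
    """ES for hit-position rows (m x k), vectorized over rows.

    Candidate extrema occur immediately before and at each hit; between
    hits the running sum moves monotonically, and after the last hit it
    decays to zero.
    """
    m, k = pos.shape
    pos = np.sort(pos, axis=1)
    v = absr_w[pos]
    tot = v.sum(axis=1, keepdims=True)
    uniform = tot <= 0
    if uniform.any():
        # all-zero metrics in the set: fall back to equal hit increments
        v = np.where(uniform, 1.0 / k, v / np.where(uniform, 1.0, tot))
    else:
        v = v / tot
    cumv = np.cumsum(v, axis=1)
    miss = 1.0 / (n - k)
    j = np.arange(k)
    n_miss_before = pos - j  # misses strictly before hit j
    at_hit = cumv - n_miss_before * miss
    before_hit = np.concatenate([np.zeros((m, 1)), cumv[:, :-1]], axis=1) - n_miss_before * miss
    cand = np.concatenate([at_hit, before_hit], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(m), idx]


def enrichment_score(
    ranked: pd.Series, gene_set: Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """(ES, running sum over the whole list, hit positions) for one set."""
    genes = ranked.index
    n = len(genes)
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), bool, count=n)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if k == n:
        raise ValueError("gene set covers the entire ranked list")
    absr_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    v = absr_w * hit_mask
    tot = v.sum()
    steps = np.where(hit_mask, v / tot if tot > 0 else hit_mask / k, -1.0 / (n - k))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running, np.flatnonzero(hit_mask)


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    size: int
    leading_edge: list[str]
    n_perm: int
    seed: int


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
) -> list[GseaResult]:
    """Permutation GSEA over a mapping of named gene sets."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    absr_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    results: list[GseaResult] = []
    pvals: list[float] = []
    for name, members in gene_sets.items():
        overlap = [g for g in dict.fromkeys(members) if g in ranked.index]
        k = len(overlap)
        if k < min_size or k >= n:
            logger.info("gsea: skipping set %r (overlap %d)", name, k)
            continue
        es, running, hits = enrichment_score(ranked, overlap, weight=weight)
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        perm_es = _es_from_positions(perm_pos, absr_w, n)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0
            nes = 0.0
        else:
            exceed = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
            p = (1 + exceed) / (1 + n_same)
            denom = float(np.abs(perm_es[same_sign]).mean())
            nes = es / denom if denom > 0 else 0.0
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            lead = [ranked.index[i] for i in hits if i <= peak]
        else:
            lead = [ranked.index[i] for i in hits if i >= peak]
        results.append(GseaResult(name, es, nes, p, np.nan, k, lead, n_perm, seed))
        pvals.append(p)
    if results:
        fdrs = bh_adjust(pvals)
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results
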