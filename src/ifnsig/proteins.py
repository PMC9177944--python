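"""Olink-style NPX inflammation-panel analysis.

NPX (normalized protein expression) values are relative log2-scale protein
abundances.  The panel analysis mirrors the transcriptomic stages: Welch
t-tests per protein with Benjamini-Hochberg FDR across the panel, z-score
heatmap matrices with Euclidean complete-linkage clustering, and clinical
comparison of the protein-high sample subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .expression import zscore_rows
from .subgroups import compare_subgroups, hierarchical_cluster

__all__ = [
    "NpxMatrix",
    "load_npx_long",
    "write_npx_long",
    "npx_differential",
    "npx_zscore_heatmap_table",
    "protein_subgroup_clinical",
]

REQUIRED_COLUMNS = ("SampleID", "Assay", "UniProt", "NPX")


@dataclass
class NpxMatrix:
    """Proteins x samples NPX values with group labels and assay metadata."""

    values: pd.DataFrame
    groups: pd.Series | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("NPX values must be finite")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.columns)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()].tolist()
                raise ValueError(f"samples without group label: {missing[:5]}")

    @property
    def protein_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


def load_npx_long(path: str | Path, groups: pd.Series | None = None) -> NpxMatrix:
    """Read an Olink-style long CSV (SampleID, Assay, UniProt, NPX)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"NPX file {path} lacks column(s): {missing}")
    dup = df.duplicated(subset=["SampleID", "Assay"])
    if dup.any():
        pairs = df.loc[dup, ["SampleID", "Assay"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate sample x assay measurement(s): {pairs[:5]}")
    wide = df.pivot(index="Assay", columns="SampleID", values="NPX")
    if wide.isna().any().any():
        raise ValueError("incomplete NPX table: missing sample x assay values")
    meta = df.drop_duplicates("Assay").set_index("Assay")[["UniProt"]].rename(columns={"UniProt": "uniprot"})
    # preserve first-appearance order of assays and samples
    wide = wide.loc[df["Assay"].drop_duplicates(), df["SampleID"].drop_duplicates()]
    wide.index.name = None
    wide.columns.name = None
    meta = meta.loc[wide.index]
    meta.index.name = None
    return NpxMatrix(wide, groups, meta)


def write_npx_long(npx: NpxMatrix, path: str | Path) -> None:
    rows = []
    for prot in npx.protein_ids:
        uni = npx.meta.loc[prot, "uniprot"] if npx.meta is not None else ""
        for sid in npx.sample_ids:
            rows.append({"SampleID": sid, "Assay": prot, "UniProt": uni,
                         "NPX": npx.values.at[prot, sid]})
    pd.DataFrame(rows).to_csv(path, index=False)


def npx_differential(npx: NpxMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein Welch t-test (FM vs CTL) with BH FDR across the panel."""
    if npx.groups is None:
        raise ValueError("NPX matrix needs group labels")
    ctl = npx.groups.index[npx.groups == "CTL"].tolist()
    fm = npx.groups.index[npx.groups == "FM"].tolist()
    if len(ctl) < 2 or len(fm) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = npx.values[ctl].to_numpy(dtype=float)
    b = npx.values[fm].to_numpy(dtype=float)
    mean_ctl = a.mean(axis=1)
    mean_fm = b.mean(axis=1)
    constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} protein(s) constant in both groups; p set to 1",
            stacklevel=2,
        )
        p[constant] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "mean_ctl": mean_ctl,
            "mean_fm": mean_fm,
            "diff": mean_fm - mean_ctl,
            "p": p,
            "fdr": fdr,
        },
        index=npx.values.index,
    )
    out["direction"] = np.where(
        out["fdr"] < alpha, np.where(out["diff"] > 0, "up", "down"), "ns"
    )
    if npx.meta is not None:
        out.insert(0, "uniprot", npx.meta["uniprot"])
    return out


def npx_zscore_heatmap_table(npx: NpxMatrix, protein_subset: Sequence[str] | None = None) -> dict:
    """Per-protein z-score matrix plus row/column dendrogram orderings."""
    values = npx.values if protein_subset is None else npx.values.loc[list(protein_subset)]
    z = zscore_rows(values)
    row_link, row_order = hierarchical_cluster(z, axis="rows")
    col_link, col_order = hierarchical_cluster(z, axis="columns")
    return {
        "zscores": z,
        "protein_order": row_order,
        "sample_order": col_order,
        "protein_linkage": row_link,
        "sample_linkage": col_link,
    }


def protein_subgroup_clinical(
    subset_ids: Sequence[str], clinical: pd.DataFrame
) -> dict:
    """Compare FM-score and FSS total between a protein-high subset of FM
    patients and the remaining FM patients (Welch t-tests)."""
    fm = clinical.index[clinical["group"] == "FM"]
    subset = [s for s in subset_ids if s in fm]
    unresolved = sorted(set(subset_ids) - set(clinical.index))
    if unresolved:
        raise KeyError(f"subset sample(s) not in the clinical table: {unresolved[:5]}")
    rest = [s for s in fm if s not in set(subset)]
    return {
        "FM_score": compare_subgroups(clinical["FM_score"], subset, rest),
        "FSS_total": compare_subgroups(clinical["FSS_total"], subset, rest),
    }
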