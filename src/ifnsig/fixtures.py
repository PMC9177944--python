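"""Packaged reference tables.

``table1``: the 60 differentially expressed genes/transcripts (FM vs CTL)
with base mean, log2 fold change, BH-adjusted p, IFN-regulated flag and the
marker for genes highly expressed in the patient subgroup.  ``table2``: the
19 inflammatory serum proteins elevated in FM with CTL/FM group NPX means
and adjusted p.  ``panel_genes``: the six-gene IFN-score panel.
``ifn_genes``: the packaged interferon-regulated gene list (a synthetic
stand-in assembled from table1's own flags plus the panel genes).
Checksums guard against accidental edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_fixtures", "load_table1", "load_table2", "load_panel_genes", "load_ifn_gene_list", "fixture_path"]

_CHECKSUMS = {
    "table1_degs.tsv": "d32703a50be7116d84143b51970f8161621da73338e51811e11d514b89ebcabf",
    "table2_npx.tsv": "8a4ae944da42f89e225f2d37f887badea8aebf15c943523b8a06f855b73d1621",
    "panel_genes.txt": "835a476026f90bba480c6bdf38b4958621b99ad99e96c361df9117f2548a42fb",
    "ifn_genes.txt": "9fb7b9259ded9b5cf86a728d700b3e9479b46f7c3e693c243e4306014ec8384f",
}


def fixture_path(name: str):
    """Traversable path to a packaged data file, checksum-verified."""
    if name not in _CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}")
    ref = resources.files("ifnsig.data") / name
    digest = hashlib.sha256(ref.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    return ref


def load_table1() -> pd.DataFrame:
    with resources.as_file(fixture_path("table1_degs.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    df["ifn_regulated"] = df["ifn_regulated"].fillna("") == "YES"
    df["subset_high"] = df["subset_high"].fillna("") == "YES"
    return df


def load_table2() -> pd.DataFrame:
    with resources.as_file(fixture_path("table2_npx.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


def load_panel_genes() -> tuple[str, ...]:
    text = fixture_path("panel_genes.txt").read_text()
    return tuple(ln.strip() for ln in text.splitlines() if ln.strip())


def load_ifn_gene_list() -> set[str]:
    text = fixture_path("ifn_genes.txt").read_text()
    return {ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")}


def load_fixtures() -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...]]:
    """(table1, table2, panel_genes)."""
    return load_table1(), load_table2(), load_panel_genes()
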