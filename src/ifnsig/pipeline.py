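"""End-to-end orchestration of the analysis stages.

Stage order: load -> filter -> normalize -> differential expression ->
IFN annotation/enrichment -> IFN score -> preranked GSEA -> PCA/OPLS-DA ->
subgroup discovery and clinical comparison -> NPX panel.  Every output
table carries a provenance header (package version, seed, config hash) and
the JSON report is byte-identical for identical config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import classify_degs, nb_wald_test, volcano_table
from .expression import filter_low_expressed, load_counts, normalize, size_factors, zscore_rows
from .fixtures import load_fixtures
from .gsea import gsea_preranked, load_gmt, make_ranked_list
from .ifn import DEFAULT_PANEL, annotate_ifn, compare_ifn_scores, compute_ifn_score, fisher_ifn_enrichment, load_gene_list
from .multivariate import opls_fit, opls_scores_plot_table, pca
from .proteins import load_npx_long, npx_differential, npx_zscore_heatmap_table, protein_subgroup_clinical
from .subgroups import compare_subgroups, identify_high_subset, validate_clinical

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_fixture_analysis"]


@dataclass
class PipelineConfig:
    counts: str
    clinical: str
    outdir: str
    npx: str | None = None
    ifn_genes: str | None = None
    gmt: str | None = None
    panel_genes: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    counts_format: str = "tsv"
    max_zero_samples: int = 5
    alpha: float = 0.05
    n_perm: int = 1000
    n_ortho: int = 1
    opls_features: str = "degs"  # or "all"
    distinct_threshold: float = 0.75
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def sha256(self) -> str:
        # hash analysis parameters only, not the output location
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _provenance(config: PipelineConfig) -> str:
    return f"# ifnsig {__version__}; seed={config.seed}; config_sha256={config.sha256()}\n"


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the machine-readable report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "config_sha256": config.sha256()}

    clinical = pd.read_csv(config.clinical, index_col=0)
    validate_clinical(clinical)
    groups = clinical["group"]

    counts = load_counts(config.counts, fmt=config.counts_format, groups=groups)
    report["n_genes_loaded"] = counts.shape[0]
    counts = filter_low_expressed(counts, config.max_zero_samples)
    report["n_genes_retained"] = counts.shape[0]
    logger.info("retained %d genes after zero-count filter", counts.shape[0])

    s = size_factors(counts)
    log_norm = normalize(counts, s, scale="log2")
    ctl_ids = counts.samples_in_group("CTL")
    fm_ids = counts.samples_in_group("FM")

    de = nb_wald_test(counts, alpha=config.alpha)
    up, down = classify_degs(de, config.alpha)
    report["de"] = {"n_up": len(up), "n_down": len(down), "n_degs": len(up) + len(down)}
    _write_table(de, outdir / "de_results.tsv", config)
    _write_table(volcano_table(de, config.alpha), outdir / "volcano.tsv", config)

    ifn_set = load_gene_list(config.ifn_genes) if config.ifn_genes else set()
    if ifn_set:
        de_ann = annotate_ifn(de, ifn_set)
        up_ifn = int(de_ann.loc[sorted(up), "ifn_regulated"].sum()) if up else 0
        down_ifn = int(de_ann.loc[sorted(down), "ifn_regulated"].sum()) if down else 0
        if up and down:
            odds, p = fisher_ifn_enrichment(len(up), up_ifn, len(down), down_ifn)
        else:
            odds, p = float("nan"), float("nan")
        report["ifn_enrichment"] = {
            "up_total": len(up), "up_ifn": up_ifn,
            "down_total": len(down), "down_ifn": down_ifn,
            "odds_ratio": odds, "p": p,
        }
        _write_table(de_ann, outdir / "de_annotated.tsv", config)

    panel = [g for g in config.panel_genes if g in log_norm.values.index]
    if len(panel) == len(config.panel_genes):
        score_panel = compute_ifn_score(log_norm.values, ctl_ids, panel)
        t, df, p = compare_ifn_scores(score_panel.ifn_score, fm_ids, ctl_ids)
        report["ifn_score"] = {
            "control_mean": float(score_panel.ifn_score[ctl_ids].mean()),
            "control_sd": float(score_panel.ifn_score[ctl_ids].std(ddof=1)),
            "patient_mean": float(score_panel.ifn_score[fm_ids].mean()),
            "patient_sd": float(score_panel.ifn_score[fm_ids].std(ddof=1)),
            "t": t, "df": df, "p": p,
        }
        _write_table(score_panel.ifn_score.to_frame(), outdir / "ifn_scores.tsv", config)
    else:
        missing = sorted(set(config.panel_genes) - set(panel))
        logger.warning("IFN-score panel gene(s) missing after filtering: %s", missing)
        report["ifn_score"] = {"skipped_missing_genes": missing}
        score_panel = None

    if config.gmt:
        ranked = make_ranked_list(de)
        sets = load_gmt(config.gmt)
        gsea = gsea_preranked(ranked, sets, n_perm=config.n_perm, seed=config.seed)
        report["gsea"] = [
            {"name": r.name, "es": r.es, "nes": r.nes, "p": r.p_perm, "fdr": r.fdr, "size": r.size}
            for r in gsea
        ]

    scores, loadings, evr = pca(log_norm.values.T, n_components=2)
    report["pca"] = {"explained_variance_ratio": [float(v) for v in evr]}
    _write_table(scores, outdir / "pca_scores.tsv", config)

    feature_genes = sorted(up | down) if config.opls_features == "degs" else log_norm.values.index.tolist()
    if len(feature_genes) >= 2:
        X = log_norm.values.loc[feature_genes].T
        model = opls_fit(X, groups.loc[X.index], n_ortho=config.n_ortho, cv_seed=config.seed)
        report["opls"] = {"r2y": model.r2y, "q2": model.q2, "n_ortho": model.n_ortho,
                          "n_features": len(feature_genes)}
        _write_table(opls_scores_plot_table(model), outdir / "opls_scores.tsv", config)

    report["subgroup"] = {"distinct": False}
    if len(up) >= 2:
        z_up = zscore_rows(log_norm.values.loc[sorted(up)])
        assign = identify_high_subset(z_up, fm_ids, distinct_threshold=config.distinct_threshold)
        report["subgroup"] = {
            "distinct": assign.distinct,
            "high_subset": sorted(assign.high_subset),
            "n_subset": len(assign.high_subset),
        }
        if assign.distinct:
            rest = [sid for sid in fm_ids if sid not in assign.high_subset]
            report["subgroup"]["fm_score"] = compare_subgroups(
                clinical["FM_score"], sorted(assign.high_subset), rest)
            report["subgroup"]["fss_total"] = compare_subgroups(
                clinical["FSS_total"], sorted(assign.high_subset), rest)
            if score_panel is not None:
                t, df, p = compare_ifn_scores(score_panel.ifn_score, sorted(assign.high_subset), ctl_ids)
                report["subgroup"]["ifn_score_vs_ctl"] = {
                    "subset_mean": float(score_panel.ifn_score[sorted(assign.high_subset)].mean()),
                    "subset_sd": float(score_panel.ifn_score[sorted(assign.high_subset)].std(ddof=1)),
                    "t": t, "df": df, "p": p,
                }

    if config.npx:
        npx = load_npx_long(config.npx, groups=groups)
        npx_de = npx_differential(npx, alpha=config.alpha)
        sig = npx_de.index[npx_de["direction"] == "up"].tolist()
        report["npx"] = {"n_proteins": npx.values.shape[0], "n_up": len(sig),
                         "n_down": int((npx_de["direction"] == "down").sum())}
        _write_table(npx_de, outdir / "npx_results.tsv", config)
        if len(sig) >= 2:
            heat = npx_zscore_heatmap_table(npx, sig)
            prot_assign = identify_high_subset(
                heat["zscores"], fm_ids, distinct_threshold=config.distinct_threshold)
            report["npx"]["high_subset"] = sorted(prot_assign.high_subset)
            if prot_assign.distinct:
                report["npx"]["clinical"] = protein_subgroup_clinical(
                    sorted(prot_assign.high_subset), clinical)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def run_fixture_analysis() -> dict:
    """Reproduce the in-table summary numbers from the packaged fixtures.

    Uses only the packaged DEG and protein tables: DEG counts by direction,
    the IFN-regulated annotation counts, the two-sided Fisher enrichment of
    IFN membership among up- vs downregulated genes, and the protein count.
    """
    table1, table2, panel = load_fixtures()
    up = table1[table1["log2fc"] > 0]
    down = table1[table1["log2fc"] < 0]
    up_ifn = int(up["ifn_regulated"].sum())
    down_ifn = int(down["ifn_regulated"].sum())
    odds, p = fisher_ifn_enrichment(len(up), up_ifn, len(down), down_ifn)
    return {
        "n_degs": int(len(table1)),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "up_ifn": up_ifn,
        "down_ifn": down_ifn,
        "up_ifn_percent": 100.0 * up_ifn / len(up),
        "fisher_odds_ratio": odds,
        "fisher_p": p,
        "n_proteins_elevated": int(len(table2)),
        "panel_size": len(panel),
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
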