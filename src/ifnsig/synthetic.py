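"""Synthetic cohort generator: counts, clinical table and NPX panel.

The generator emulates the statistical structure of a two-group B-cell
RNA-seq cohort (23 healthy controls vs 25 fibromyalgia patients) together
with a matched Olink-style inflammation panel:

* gene-level baseline means are heavy-tailed (log-normal), counts are
  negative-binomial with a common dispersion (var = mu + phi * mu^2,
  phi = 0.085 by default) and log-normal per-sample library-size factors;
* a planted set of up/down differentially expressed genes (33 up / 27 down
  by default), most upregulated ones labelled interferon-regulated, six of
  them carrying the IFN-score panel symbols;
* a "high inflammatory subset" of FM samples (7 by default) in which the
  planted log2 fold changes are amplified;
* a 92-protein NPX panel with 19 planted positive group shifts, likewise
  amplified in the subset;
* a clinical table (WPI, SSS, nine FSS items) in which subset patients have
  a stochastically higher FM-score.

Every operation is deterministic for a fixed seed and returns the planted
ground truth for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .proteins import NpxMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "simulate_clinical", "simulate_npx", "simulate_cohort"]

PANEL_SYMBOLS = ("IFI27", "IFI44L", "IFIT1", "ISG15", "RSAD2", "SIGLEC1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 23 CTL + 25 FM samples, ~19,000
    genes, NB dispersion 0.085, 33 up- / 27 down-regulated genes with 25/33
    of the upregulated ones interferon-regulated, a 7-patient high
    inflammatory subset, and a 92-protein panel with 19 shifted proteins.
    """

    n_genes: int = 19000
    n_ctl: int = 23
    n_fm: int = 25
    dispersion: float = 0.085
    n_de_up: int = 33
    n_de_down: int = 27
    frac_up_ifn: float = 25 / 33
    lfc_mean: float = 1.0
    lfc_sd: float = 0.5
    subset_size: int = 7
    subset_amplification: float = 2.0
    n_proteins: int = 92
    n_proteins_shifted: int = 19
    npx_shift_mean: float = 0.9
    npx_shift_sd: float = 0.15
    npx_noise_sd: float = 0.5
    # baseline and library-size heterogeneity
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.5
    size_factor_sdlog: float = 0.25
    # correlated over-dispersion of planted up-genes within the subset
    # (log2 units of a shared per-sample latent factor; 0 = independent)
    subset_corr_sd: float = 0.0
    # expected FM-score excess of subset patients over the remaining FM group
    subset_clinical_shift: float = 2.5
    # fraction of non-DE genes additionally labelled IFN-regulated
    ifn_background_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {"n_genes", "n_ctl", "n_fm", "n_proteins"}
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        non_negative = {
            "n_de_up", "n_de_down", "subset_size", "n_proteins_shifted",
            "lfc_sd", "npx_shift_sd", "npx_noise_sd", "subset_corr_sd",
            "ifn_background_frac",
        }
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.frac_up_ifn <= 1:
            raise ValueError("frac_up_ifn must be in [0, 1]")
        if self.subset_size > self.n_fm:
            raise ValueError("subset_size must be <= n_fm")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("n_de_up + n_de_down must be <= n_genes")
        if self.n_proteins_shifted > self.n_proteins:
            raise ValueError("n_proteins_shifted must be <= n_proteins")
        if self.subset_amplification < 1:
            raise ValueError("subset_amplification must be >= 1")


@dataclass
class SimTruth:
    """Planted parameters of a simulated cohort (the recovery targets)."""

    de_genes_up: set[str]
    de_genes_down: set[str]
    planted_lfc: dict[str, float]
    ifn_genes: set[str]
    subset_samples: set[str]
    fm_samples: set[str]
    panel_genes: tuple[str, ...]
    true_size_factors: dict[str, float]
    shifted_proteins: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("a gene cannot be both up- and down-regulated")
        if not self.subset_samples <= self.fm_samples:
            raise ValueError("subset samples must be FM samples")


def _sample_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    ctl = [f"CTL{i + 1:02d}" for i in range(config.n_ctl)]
    fm = [f"FM{i + 1:02d}" for i in range(config.n_fm)]
    return ctl, fm


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw the synthetic count matrix and its ground truth."""
    rng = np.random.default_rng([config.seed, 0])
    ctl_ids, fm_ids = _sample_ids(config)
    sample_ids = ctl_ids + fm_ids
    n_samples = len(sample_ids)

    gene_ids = np.array([f"GENE{i + 1:05d}" for i in range(config.n_genes)], dtype=object)
    de_idx = rng.choice(config.n_genes, size=config.n_de_up + config.n_de_down, replace=False)
    up_idx = de_idx[: config.n_de_up]
    down_idx = de_idx[config.n_de_up:]
    n_up_ifn = int(round(config.frac_up_ifn * config.n_de_up))
    ifn_up_idx = up_idx[:n_up_ifn]
    # the IFN-score panel genes are planted as upregulated IFN-responders
    for j, sym in enumerate(PANEL_SYMBOLS[: min(len(PANEL_SYMBOLS), n_up_ifn)]):
        gene_ids[ifn_up_idx[j]] = sym

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=config.n_genes)
    panel_idx = ifn_up_idx[: min(len(PANEL_SYMBOLS), n_up_ifn)]
    baseline[panel_idx] = np.maximum(baseline[panel_idx], 50.0)

    lfc = np.zeros(config.n_genes)
    lfc[up_idx] = np.clip(rng.normal(config.lfc_mean, config.lfc_sd, size=len(up_idx)), 0.1, None)
    lfc[down_idx] = -np.clip(rng.normal(config.lfc_mean, config.lfc_sd, size=len(down_idx)), 0.1, None)

    subset = set(rng.choice(fm_ids, size=config.subset_size, replace=False).tolist())
    s_true = rng.lognormal(0.0, config.size_factor_sdlog, size=n_samples)

    mu = np.tile(baseline[:, None], (1, n_samples))
    for j, sid in enumerate(sample_ids):
        if sid in fm_ids:
            amp = config.subset_amplification if sid in subset else 1.0
            gene_lfc = lfc * amp
            if sid in subset and config.subset_corr_sd > 0:
                latent = rng.normal(0.0, config.subset_corr_sd)
                gene_lfc = gene_lfc + np.where(lfc > 0, latent, 0.0)
            mu[:, j] = baseline * np.exp2(gene_lfc)
        mu[:, j] *= s_true[j]

    phi = config.dispersion
    r = 1.0 / phi
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    groups = pd.Series(["CTL"] * config.n_ctl + ["FM"] * config.n_fm, index=sample_ids)
    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), groups)

    ifn_set = set(gene_ids[ifn_up_idx].tolist())
    n_background = int(round(config.ifn_background_frac * config.n_genes))
    non_de = np.setdiff1d(np.arange(config.n_genes), de_idx, assume_unique=False)
    if n_background > 0 and len(non_de) > 0:
        bg = rng.choice(non_de, size=min(n_background, len(non_de)), replace=False)
        ifn_set |= set(gene_ids[bg].tolist())

    truth = SimTruth(
        de_genes_up=set(gene_ids[up_idx].tolist()),
        de_genes_down=set(gene_ids[down_idx].tolist()),
        planted_lfc={gene_ids[i]: float(lfc[i]) for i in de_idx},
        ifn_genes=ifn_set,
        subset_samples=subset,
        fm_samples=set(fm_ids),
        panel_genes=tuple(gene_ids[panel_idx].tolist()),
        true_size_factors=dict(zip(sample_ids, s_true.tolist())),
    )
    return matrix, truth


def simulate_clinical(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Synthetic clinical table: WPI, SSS, FM-score and nine FSS items.

    FM patients sit in the diagnostic range (FM-score about 21 +/- 2.5);
    subset patients receive an additive expected FM-score excess of
    ``subset_clinical_shift``, split 60/40 between WPI and SSS.  Controls
    have near-zero pain scores and low fatigue.
    """
    rng = np.random.default_rng([config.seed, 1])
    ctl_ids, fm_ids = _sample_ids(config)
    rows = []
    for sid in ctl_ids + fm_ids:
        if sid in ctl_ids:
            wpi = int(rng.binomial(4, 0.25))
            sss = int(rng.binomial(3, 0.3))
            fss = np.clip(np.round(rng.normal(1.5, 0.7, size=9)), 1, 7).astype(int)
            site = "HC1"
        else:
            shift = config.subset_clinical_shift if sid in truth.subset_samples else 0.0
            wpi = int(np.clip(round(rng.normal(13.3 + 0.6 * shift, 2.0)), 0, 19))
            sss = int(np.clip(round(rng.normal(7.9 + 0.4 * shift, 1.5)), 0, 12))
            fss = np.clip(np.round(rng.normal(5.6, 1.0, size=9)), 1, 7).astype(int)
            site = "PainClinic" if sid in truth.subset_samples else "HC1"
        rows.append(
            {
                "sample_id": sid,
                "group": "CTL" if sid in ctl_ids else "FM",
                "WPI": wpi,
                "SSS": sss,
                "FM_score": wpi + sss,
                **{f"FSS{i + 1}": int(v) for i, v in enumerate(fss)},
                "FSS_total": int(fss.sum()),
                "site": site,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_npx(config: SimConfig, truth: SimTruth) -> NpxMatrix:
    """Synthetic Olink-style NPX panel (log2 scale).

    ``n_proteins_shifted`` proteins get positive FM-group shifts drawn from
    N(npx_shift_mean, npx_shift_sd), amplified by ``subset_amplification``
    in subset samples.  The planted shifts are recorded in
    ``truth.shifted_proteins``.
    """
    rng = np.random.default_rng([config.seed, 2])
    ctl_ids, fm_ids = _sample_ids(config)
    sample_ids = ctl_ids + fm_ids
    prot_ids = [f"PROT{i + 1:03d}" for i in range(config.n_proteins)]

    baseline = rng.normal(5.0, 2.0, size=config.n_proteins)
    shifted_idx = rng.choice(config.n_proteins, size=config.n_proteins_shifted, replace=False)
    shifts = np.zeros(config.n_proteins)
    shifts[shifted_idx] = np.clip(
        rng.normal(config.npx_shift_mean, config.npx_shift_sd, size=config.n_proteins_shifted),
        0.1,
        None,
    )

    values = np.empty((config.n_proteins, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        mean = baseline.copy()
        if sid in fm_ids:
            amp = config.subset_amplification if sid in truth.subset_samples else 1.0
            mean = mean + shifts * amp
        values[:, j] = rng.normal(mean, config.npx_noise_sd)

    truth.shifted_proteins = {prot_ids[i]: float(shifts[i]) for i in shifted_idx}
    groups = pd.Series(["CTL"] * len(ctl_ids) + ["FM"] * len(fm_ids), index=sample_ids)
    meta = pd.DataFrame(
        {"uniprot": [f"U{i + 1:05d}" for i in range(config.n_proteins)]}, index=prot_ids
    )
    return NpxMatrix(pd.DataFrame(values, index=prot_ids, columns=sample_ids), groups, meta)


def simulate_cohort(config: SimConfig) -> dict:
    """Convenience wrapper: counts + truth + clinical + NPX in one call."""
    counts, truth = simulate_counts(config)
    clinical = simulate_clinical(config, truth)
    npx = simulate_npx(config, truth)
    return {"counts": counts, "truth": truth, "clinical": clinical, "npx": npx}


def write_cohort(cohort: dict, outdir) -> dict[str, str]:
    """Write a simulated cohort to disk in the pipeline's input formats.

    counts.tsv (genes x samples), clinical.csv, npx.csv (Olink long
    format), ifn_genes.txt (one symbol per line), gene_sets.gmt (planted
    up/down/IFN sets, usable for enrichment), truth.json.
    """
    import json
    from pathlib import Path

    from .expression import write_matrix
    from .proteins import write_npx_long

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, truth = cohort["counts"], cohort["truth"]
    paths = {
        "counts": str(outdir / "counts.tsv"),
        "clinical": str(outdir / "clinical.csv"),
        "npx": str(outdir / "npx.csv"),
        "ifn_genes": str(outdir / "ifn_genes.txt"),
        "gmt": str(outdir / "gene_sets.gmt"),
        "truth": str(outdir / "truth.json"),
    }
    write_matrix(counts, paths["counts"], fmt="tsv")
    cohort["clinical"].to_csv(paths["clinical"])
    write_npx_long(cohort["npx"], paths["npx"])
    Path(paths["ifn_genes"]).write_text("\n".join(sorted(truth.ifn_genes)) + "\n")
    with open(paths["gmt"], "w") as fh:
        fh.write("PLANTED_UP\tplanted upregulated genes\t" + "\t".join(sorted(truth.de_genes_up)) + "\n")
        fh.write("PLANTED_DOWN\tplanted downregulated genes\t" + "\t".join(sorted(truth.de_genes_down)) + "\n")
        fh.write("PLANTED_IFN\tplanted IFN-regulated genes\t" + "\t".join(sorted(truth.ifn_genes)) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "de_genes_up": sorted(truth.de_genes_up),
                "de_genes_down": sorted(truth.de_genes_down),
                "planted_lfc": truth.planted_lfc,
                "ifn_genes": sorted(truth.ifn_genes),
                "subset_samples": sorted(truth.subset_samples),
                "fm_samples": sorted(truth.fm_samples),
                "panel_genes": list(truth.panel_genes),
                "true_size_factors": truth.true_size_factors,
                "shifted_proteins": truth.shifted_proteins,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
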