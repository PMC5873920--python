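"""End-to-end scan orchestration: inputs -> statistics -> p-values -> tables.

Null distributions are keyed by (statistic, region length, scope) and cached,
so genes of equal length share a null; one batch of replicate simulations at
a given length serves every genic-region statistic, and a second batch at the
flanked window length serves per-population nsl_max.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .category_analysis import pairwise_category_tests
from .genomic_data import (
    POPULATIONS,
    GeneRegion,
    PopulationPanel,
    apply_gene_filters,
    read_gene_table,
    read_panel,
    read_vcf_region,
)
from .neutral_simulator import (
    DemographicModel,
    NullDistribution,
    replicate_seeds,
    simulate_region,
)
from .selection_stats import (
    compute_statistic,
    h12,
    max_abs_nsl,
    nsl_scores,
    nucleotide_diversity,
    tajimas_d,
    wc_fst,
)
from .significance import DEFAULT_TAILS, scan_genes

log = logging.getLogger("sweepscan")

#: measures compared across functional categories
CATEGORY_MEASURES = (
    "pi_per_site",
    "tajimas_d",
    "fst_weighted_global",
    "h12",
    "nsl_max_AFR",
    "nsl_max_EUR",
    "nsl_max_EAS",
)


@dataclass
class RunConfig:
    vcf: Path
    panel: Path
    gene_table: Path
    outdir: Path
    model: DemographicModel = field(default_factory=DemographicModel)
    n_sims: int = 5000
    n_sims_nsl: int = 2500
    flank: int = 100_000
    maf_cutoff: float = 0.01
    nsl_cap: int = 100
    alpha: float = 0.05
    seed: int = 0
    tails: dict = field(default_factory=lambda: dict(DEFAULT_TAILS))
    polarity_mode: str = "strict"

    def __post_init__(self) -> None:
        if self.n_sims < 1 or self.n_sims_nsl < 1:
            raise ValueError("n_sims must be >= 1")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.vcf = Path(self.vcf)
        self.panel = Path(self.panel)
        self.gene_table = Path(self.gene_table)
        self.outdir = Path(self.outdir)


def gene_statistics(
    gene: GeneRegion,
    genic: "HaplotypeMatrix",
    window: "HaplotypeMatrix",
    window_length: int,
    maf_cutoff: float = 0.01,
    nsl_cap: int = 100,
) -> dict:
    """One observed-statistics row for a gene (genic matrix + flanked window)."""
    pi_total, pi_site = nucleotide_diversity(genic)
    fst = wc_fst(genic, mode="pairwise") if genic.n_sites else None
    row = {
        "gene": gene.name,
        "category": gene.category,
        "length": gene.length,
        "window_length": window_length,
        "n_sites": genic.n_sites,
        "pi_per_site": pi_site,
        "tajimas_d": tajimas_d(genic),
        "fst_weighted_global": fst["global"].weighted if fst else math.nan,
        "fst_mean_global": fst["global"].mean if fst else math.nan,
        "h12": h12(genic).h12 if genic.n_sites else math.nan,
    }
    for pa, pb in combinations(POPULATIONS, 2):
        key = f"{pa}-{pb}"
        row[f"fst_weighted_{key}"] = fst[key].weighted if fst and key in fst else math.nan
    for pop in POPULATIONS:
        sub = window.subset_population(pop)
        row[f"nsl_max_{pop}"] = max_abs_nsl(
            nsl_scores(sub, maf_cutoff=maf_cutoff, cap=nsl_cap)
        )
    return row


def _null_batch(
    model: DemographicModel,
    length: int,
    n_sims: int,
    statistics: list[tuple[str, str]],
    sample_sizes: dict[str, int],
    seed: int,
    stream: tuple[int, ...],
    maf_cutoff: float,
    nsl_cap: int,
) -> dict[tuple[str, int, str], NullDistribution]:
    """Simulate one batch of replicates and score several statistics on each."""
    values: dict[tuple[str, str], list[float]] = {key: [] for key in statistics}
    nan_counts: dict[tuple[str, str], int] = {key: 0 for key in statistics}
    for ss in replicate_seeds(seed, n_sims, stream=stream + (length,)):
        mat = simulate_region(model, length, sample_sizes, np.random.default_rng(ss))
        for stat, scope in statistics:
            v = compute_statistic(mat, stat, scope, maf_cutoff=maf_cutoff, nsl_cap=nsl_cap)
            if math.isnan(v):
                nan_counts[(stat, scope)] += 1
            else:
                values[(stat, scope)].append(v)
    out = {}
    for stat, scope in statistics:
        vals = values[(stat, scope)]
        if not vals:
            raise RuntimeError(
                f"statistic {stat!r} ({scope}) undefined under null at length {length}"
            )
        out[(stat, length, scope)] = NullDistribution(
            statistic=stat,
            length_bp=length,
            scope=scope,
            values=np.array(vals),
            n_sims=n_sims,
            n_nan=nan_counts[(stat, scope)],
            seed=seed,
        )
    return out


@dataclass
class ScanBundle:
    stats: pd.DataFrame
    pvalues: pd.DataFrame
    categories: pd.DataFrame
    manifest: dict
    paths: dict[str, Path]


def run_scan(config: RunConfig) -> ScanBundle:
    """Run the full scan and write stats / p-value / category tables.

    Fully deterministic given ``config.seed``.  Outputs are assembled in
    memory and written together at the end, so a failing stage leaves no
    partial output files behind.
    """
    panel = read_panel(config.panel)
    pop_counts = panel.counts()
    log.info("panel: %s (%d samples)", pop_counts, len(panel))

    genes_all = read_gene_table(config.gene_table)
    genes, exclusions = apply_gene_filters(genes_all)
    if exclusions:
        log.info("excluded %d gene(s): %s", len(exclusions), exclusions)
    if not genes:
        raise ValueError("no genes left after filtering")

    warnings_log: list[str] = []
    stat_rows: list[dict] = []
    windows: dict[str, int] = {}
    for gene in genes:
        log.info("statistics: %s", gene.name)
        genic, glog = read_vcf_region(config.vcf, gene, panel, mode=config.polarity_mode)
        wstart, wend = gene.window(config.flank)
        window, _ = read_vcf_region(
            config.vcf, (gene.chrom, wstart, wend), panel, mode=config.polarity_mode
        )
        window_length = wend - wstart + 1
        windows[gene.name] = window_length
        if glog.n_indels or glog.n_multiallelic or glog.n_missing_dropped:
            warnings_log.append(
                f"{gene.name}: dropped {glog.n_indels} indel/non-SNP, "
                f"{glog.n_multiallelic} multiallelic, {glog.n_missing_dropped} missing-call records"
            )
        stat_rows.append(
            gene_statistics(
                gene, genic, window, window_length,
                maf_cutoff=config.maf_cutoff, nsl_cap=config.nsl_cap,
            )
        )

    nulls: dict[tuple[str, int, str], NullDistribution] = {}
    genic_lengths = sorted({row["length"] for row in stat_rows})
    window_lengths = sorted({row["window_length"] for row in stat_rows})
    for length in genic_lengths:
        log.info("null distributions at genic length %d bp", length)
        nulls.update(
            _null_batch(
                config.model, length, config.n_sims,
                [("tajimas_d", "pooled"), ("fst", "global"), ("h12", "pooled")],
                pop_counts, config.seed, (1,), config.maf_cutoff, config.nsl_cap,
            )
        )
    for length in window_lengths:
        log.info("nsl null distributions at window length %d bp", length)
        nulls.update(
            _null_batch(
                config.model, length, config.n_sims_nsl,
                [("nsl_max", pop) for pop in POPULATIONS],
                pop_counts, config.seed, (2,), config.maf_cutoff, config.nsl_cap,
            )
        )

    results = scan_genes(stat_rows, nulls, alpha=config.alpha, tails=config.tails)

    comparisons = []
    for measure in CATEGORY_MEASURES:
        by_cat: dict[str, list[float]] = {}
        for row in stat_rows:
            by_cat.setdefault(row["category"], []).append(row[measure])
        comparisons.extend(pairwise_category_tests(by_cat, measure))

    stats_df = pd.DataFrame(stat_rows)
    pvalues_df = pd.DataFrame(
        {
            "gene": r.gene,
            "category": r.category,
            "statistic": r.statistic,
            "scope": r.scope,
            "observed": r.observed,
            "n_valid_null": r.n_valid_null,
            "p_value": r.p_value,
            "significant": int(r.significant),
        }
        for r in results
    )
    categories_df = pd.DataFrame(
        {
            "statistic": c.statistic,
            "category_a": c.category_a,
            "category_b": c.category_b,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "U": c.u,
            "p_raw": c.p_raw,
            "p_bonferroni": c.p_adjusted,
        }
        for c in comparisons
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_sims": config.n_sims,
        "n_sims_nsl": config.n_sims_nsl,
        "flank": config.flank,
        "maf_cutoff": config.maf_cutoff,
        "alpha": config.alpha,
        "polarity_mode": config.polarity_mode,
        "tails": config.tails,
        "model": config.model.to_dict(),
        "panel_counts": pop_counts,
        "n_genes": len(genes),
        "excluded_genes": [list(e) for e in exclusions],
        "null_nan_counts": {
            f"{k[0]}@{k[1]}:{k[2]}": v.n_nan for k, v in nulls.items()
        },
        "warnings": warnings_log,
    }

    config.outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stats": config.outdir / "statistics.tsv",
        "pvalues": config.outdir / "pvalues.tsv",
        "categories": config.outdir / "categories.tsv",
        "manifest": config.outdir / "manifest.json",
    }
    kwargs = dict(sep="\t", index=False, float_format="%.10g", na_rep="NaN")
    stats_df.to_csv(paths["stats"], **kwargs)
    pvalues_df.to_csv(paths["pvalues"], **kwargs)
    categories_df.to_csv(paths["categories"], **kwargs)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ScanBundle(stats_df, pvalues_df, categories_df, manifest, paths)
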