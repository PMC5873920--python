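"""Self-contained synthetic studies: neutral genes plus planted sweeps.

Sweeps are planted by haplotype copying on neutral simulations: copying one
donor haplotype over a fraction of the sample reproduces the
reduced-diversity / dominant-haplotype signature of a hard sweep, copying
two distinct donors the multi-haplotype signature of a soft sweep.
Planting never touches positions, site count or polarity - only row
contents.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genomic_data import (
    CATEGORIES,
    GeneRegion,
    HaplotypeMatrix,
    PopulationPanel,
    write_gene_table,
    write_panel,
    write_vcf,
)
from .neutral_simulator import DemographicModel, replicate_seeds, simulate_region

SCALED_SAMPLE_SIZES = {"AFR": 66, "EUR": 50, "EAS": 50}  # ~10% of the study


@dataclass(frozen=True)
class SweepConfig:
    mode: str  # neutral | hard | soft
    sweep_frequency: float = 0.9
    population: str = "pooled"  # pooled or a population code
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "hard", "soft"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if not 0.0 < self.sweep_frequency <= 1.0:
            raise ValueError("sweep_frequency must be in (0, 1]")

    @property
    def n_sweep_haplotypes(self) -> int:
        return {"neutral": 0, "hard": 1, "soft": 2}[self.mode]


def _target_rows(h: HaplotypeMatrix, population: str) -> np.ndarray:
    if population == "pooled":
        return np.arange(h.n_haplotypes)
    rows = np.array([i for i, p in enumerate(h.pop_labels) if p == population])
    if len(rows) == 0:
        raise ValueError(f"no haplotypes in target population {population!r}")
    return rows


def _sweep_plan(h: HaplotypeMatrix, cfg: SweepConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Shared donor/recipient draw so that hard and soft plantings with the
    same seed replace exactly the same rows (making matched comparisons of
    the two modes exact)."""
    rng = np.random.default_rng(cfg.seed)
    rows = _target_rows(h, cfg.population)
    k = int(round(cfg.sweep_frequency * len(rows)))
    if k == 0:
        raise ValueError("sweep_frequency rounds to zero copied haplotypes")
    perm = rng.permutation(rows)
    return perm, perm[:k], k


def plant_hard_sweep(h: HaplotypeMatrix, cfg: SweepConfig) -> HaplotypeMatrix:
    """Copy one randomly chosen donor haplotype over a ``sweep_frequency``
    fraction (rounded to nearest) of the target haplotypes."""
    if cfg.mode != "hard":
        raise ValueError("cfg.mode must be 'hard'")
    perm, recipients, k = _sweep_plan(h, cfg)
    donor = h.states[perm[k % len(perm)]].copy()
    out = h.copy()
    out.states[recipients, :] = donor
    return out


def plant_soft_sweep(h: HaplotypeMatrix, cfg: SweepConfig) -> HaplotypeMatrix:
    """Copy two distinct donor haplotypes to ~sweep_frequency/2 each.

    The total number of replaced rows equals the hard-sweep count at the
    same frequency and seed, so the two modes are directly comparable on
    the same base matrix.
    """
    if cfg.mode != "soft":
        raise ValueError("cfg.mode must be 'soft'")
    perm, recipients, k = _sweep_plan(h, cfg)
    donor_a = h.states[perm[k % len(perm)]].copy()
    donor_b = None
    for i in np.roll(perm, -(k % len(perm)) - 1):
        if not np.array_equal(h.states[i], donor_a):
            donor_b = h.states[i].copy()
            break
    if donor_b is None:
        raise ValueError("fewer than 2 distinct donor haplotypes in input")
    k_a = k // 2
    out = h.copy()
    out.states[recipients[:k_a], :] = donor_a
    out.states[recipients[k_a:], :] = donor_b
    return out


def plant_sweep(h: HaplotypeMatrix, cfg: SweepConfig) -> HaplotypeMatrix:
    if cfg.mode == "neutral":
        return h
    if cfg.mode == "hard":
        return plant_hard_sweep(h, cfg)
    return plant_soft_sweep(h, cfg)


@dataclass
class StudyFiles:
    vcf: Path
    panel: Path
    gene_table: Path
    truth_table: Path


def generate_study(
    outdir: str | Path,
    n_neutral: int,
    n_hard: int = 0,
    n_soft: int = 0,
    model: DemographicModel | None = None,
    sample_sizes: dict[str, int] | None = None,
    gene_length: int = 5000,
    flank: int = 2500,
    sweep_frequency: float = 0.9,
    sweep_population: str = "pooled",
    seed: int = 0,
) -> StudyFiles:
    """Write a complete synthetic study: VCF + panel + gene table + truth table.

    Each gene occupies its own contig: the simulated window spans
    [1, gene_length + 2*flank] and the genic interval sits at
    [flank+1, flank+gene_length].  Sweeps are planted over the whole window
    so haplotype statistics on flanked regions see them too.  Categories are
    assigned round-robin.  Deterministic for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = DemographicModel()
    if sample_sizes is None:
        sample_sizes = SCALED_SAMPLE_SIZES
    if n_neutral < 1:
        raise ValueError("need at least one neutral gene")

    modes = ["neutral"] * n_neutral + ["hard"] * n_hard + ["soft"] * n_soft
    window = gene_length + 2 * flank
    matrices: list[HaplotypeMatrix] = []
    regions: list[GeneRegion] = []
    truth_rows: list[tuple] = []
    sim_seeds = replicate_seeds(seed, len(modes), stream=(0xD,))
    for i, (mode, ss) in enumerate(zip(modes, sim_seeds)):
        mat = simulate_region(model, window, sample_sizes, np.random.default_rng(ss))
        cfg = SweepConfig(
            mode=mode,
            sweep_frequency=sweep_frequency,
            population=sweep_population,
            seed=seed + 7919 * (i + 1),
        )
        mat = plant_sweep(mat, cfg)
        mat.chrom = f"chr{i + 1}"
        matrices.append(mat)
        regions.append(
            GeneRegion(
                name=f"GENE{i + 1:03d}",
                chrom=mat.chrom,
                start=flank + 1,
                end=flank + gene_length,
                category=CATEGORIES[i % len(CATEGORIES)],
            )
        )
        truth_rows.append(
            (regions[-1].name, mode, sweep_frequency if mode != "neutral" else 0.0,
             sweep_population if mode != "neutral" else ".", cfg.seed)
        )

    files = StudyFiles(
        vcf=outdir / "study.vcf",
        panel=outdir / "panel.tsv",
        gene_table=outdir / "genes.tsv",
        truth_table=outdir / "truth.tsv",
    )
    write_vcf(files.vcf, matrices)
    panel = PopulationPanel(
        {sid: pop for sid, pop in zip(matrices[0].sample_ids[::2], matrices[0].pop_labels[::2])}
    )
    write_panel(files.panel, panel)
    write_gene_table(files.gene_table, regions)
    with open(files.truth_table, "w") as fh:
        fh.write("gene\tmode\tfrequency\tpopulation\tseed\n")
        for row in truth_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return files
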