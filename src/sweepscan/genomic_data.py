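"""Phased genotype data, population panels, gene tables and the study filters.

All coordinates are 1-based inclusive (Ensembl/VCF convention).  Haplotypes
are stored row-wise, two per diploid sample, with columns ordered by strictly
increasing physical position.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

POPULATIONS = ("AFR", "EUR", "EAS")
CATEGORIES = (
    "biosynthesis",
    "activation_transport_transfer",
    "recognition",
    "recycling_degradation",
)

_BASES = frozenset("ACGT")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _is_x_chromosome(chrom: str) -> bool:
    c = chrom.lower()
    if c.startswith("chr"):
        c = c[3:]
    return c == "x"


# ---------------------------------------------------------------------------
# Population panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationPanel:
    """Mapping of sample id to population code (AFR / EUR / EAS)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {p for p in self.mapping.values() if p not in POPULATIONS}
        if bad:
            raise DataError(f"unknown population code(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def samples(self) -> list[str]:
        return list(self.mapping)

    def population_of(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def counts(self) -> dict[str, int]:
        out = {p: 0 for p in POPULATIONS}
        for p in self.mapping.values():
            out[p] += 1
        return out


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a two-column TSV (sample_id, population).

    Duplicate sample ids and unknown population codes are hard errors; an
    empty file is rejected ("no samples").
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected two columns, got {line!r}")
            sample, pop = parts[0], parts[1]
            if sample in mapping:
                raise DataError(f"{path}:{lineno}: duplicate sample_id {sample!r}")
            if pop not in POPULATIONS:
                raise DataError(
                    f"{path}:{lineno}: unknown population code {pop!r} for sample {sample!r}"
                )
            mapping[sample] = pop
    if not mapping:
        raise DataError(f"{path}: no samples")
    return PopulationPanel(mapping)


def write_panel(path: str | Path, panel: PopulationPanel) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.mapping.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRegion:
    """Named genomic interval (1-based inclusive) with a functional category."""

    name: str
    chrom: str
    start: int
    end: int
    category: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"{self.name}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise DataError(f"{self.name}: 1-based start must be >= 1")
        if self.category not in CATEGORIES:
            raise DataError(f"{self.name}: unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def window(self, flank: int) -> tuple[int, int]:
        """Interval extended by ``flank`` bp on both sides, clipped at 1."""
        return max(1, self.start - flank), self.end + flank


@dataclass(frozen=True)
class CandidateGene:
    """Pre-filter candidate: gene symbol with chromosome and pseudogene flag.

    Unlike :class:`GeneRegion` the category is unrestricted, so categories
    that are dropped wholesale by the filters (e.g. a pseudogene-only one)
    can still be represented at the candidate stage.
    """

    name: str
    chrom: str
    category: str
    pseudogene: bool = False


def read_gene_table(path: str | Path) -> list[GeneRegion]:
    """Read a gene-coordinate TSV: name, chrom, start, end, category.

    Coordinates are 1-based inclusive.  Unknown categories (including the
    pseudogene-only 'modification' class, which is excluded from analysis)
    are hard errors, as is start > end.
    """
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "name":  # optional header
                continue
            if len(parts) < 5:
                raise DataError(f"{path}:{lineno}: expected 5 columns, got {line!r}")
            name, chrom, start, end, category = parts[:5]
            try:
                region = GeneRegion(name, chrom, int(start), int(end), category)
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
            regions.append(region)
    return regions


def write_gene_table(path: str | Path, regions: list[GeneRegion]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\tcategory\n")
        for r in regions:
            fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.category}\n")


def read_candidate_table(path: str | Path) -> list[CandidateGene]:
    """Read a candidate-gene TSV: name, chrom, category, pseudogene (0/1)."""
    out: list[CandidateGene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "name":
                continue
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: expected 4 columns, got {line!r}")
            out.append(
                CandidateGene(parts[0], parts[1], parts[2], parts[3] not in ("0", "false", "False"))
            )
    return out


def bundled_candidate_genes() -> list[CandidateGene]:
    """The packaged 58-gene sialic-acid-biology candidate list."""
    ref = resources.files("sweepscan").joinpath("data/candidate_genes.tsv")
    with resources.as_file(ref) as path:
        return read_candidate_table(path)


def apply_gene_filters(
    candidates: list[CandidateGene] | list[GeneRegion],
) -> tuple[list, list[tuple[str, str]]]:
    """Remove X-linked genes and pseudogenes from a candidate list.

    Returns ``(retained, exclusion_log)`` where the log holds
    ``(gene_name, reason)`` pairs.  An empty result is allowed.
    """
    retained = []
    log: list[tuple[str, str]] = []
    for gene in candidates:
        if _is_x_chromosome(gene.chrom):
            log.append((gene.name, "X-linked"))
        elif getattr(gene, "pseudogene", False):
            log.append((gene.name, "pseudogene"))
        else:
            retained.append(gene)
    return retained, log


def write_exclusion_log(path: str | Path, log: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("name\treason\n")
        for name, reason in log:
            fh.write(f"{name}\t{reason}\n")


# ---------------------------------------------------------------------------
# Haplotype matrices
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotype-by-site matrix.

    ``states`` has one row per haplotype (two consecutive rows per diploid
    sample) and one column per segregating site.  ``polarity[j]`` is True when
    state 1 at column j is the derived allele, False when polarity is unknown.
    ``region_start``/``region_end`` record the extracted interval so per-bp
    quantities can be normalised by physical length.
    """

    states: np.ndarray
    positions: np.ndarray
    chrom: str
    polarity: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]
    region_start: int = 1
    region_end: int | None = None

    def __post_init__(self) -> None:
        self.states = np.ascontiguousarray(self.states, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.polarity = np.asarray(self.polarity, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n, s = self.states.shape
        if n % 2 != 0:
            raise DataError("haplotype row count must be even (2 per diploid sample)")
        if len(self.sample_ids) != n or len(self.pop_labels) != n:
            raise DataError("sample_ids/pop_labels length must match haplotype count")
        if self.positions.shape != (s,) or self.polarity.shape != (s,):
            raise DataError("positions/polarity length must match site count")
        if s and not np.all(np.diff(self.positions) > 0):
            raise DataError("positions must be strictly increasing")
        if s and not np.all((self.states == 0) | (self.states == 1)):
            raise DataError("states must be in {0,1} with no missing values")
        for i in range(0, n, 2):
            if self.sample_ids[i] != self.sample_ids[i + 1]:
                raise DataError("haplotype rows must come in sample pairs")

    @property
    def n_haplotypes(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    @property
    def n_samples(self) -> int:
        return self.n_haplotypes // 2

    @property
    def region_length(self) -> int:
        if self.region_end is None:
            if self.n_sites == 0:
                return 1
            return int(self.positions[-1] - self.positions[0] + 1)
        return int(self.region_end - self.region_start + 1)

    def subset_population(self, population: str) -> "HaplotypeMatrix":
        rows = [i for i, p in enumerate(self.pop_labels) if p == population]
        return self.take_haplotypes(rows)

    def take_haplotypes(self, rows: list[int]) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            states=self.states[rows, :],
            positions=self.positions.copy(),
            chrom=self.chrom,
            polarity=self.polarity.copy(),
            sample_ids=[self.sample_ids[i] for i in rows],
            pop_labels=[self.pop_labels[i] for i in rows],
            region_start=self.region_start,
            region_end=self.region_end,
        )

    def take_sites(self, keep: np.ndarray) -> "HaplotypeMatrix":
        keep = np.asarray(keep)
        return HaplotypeMatrix(
            states=self.states[:, keep],
            positions=self.positions[keep],
            chrom=self.chrom,
            polarity=self.polarity[keep],
            sample_ids=list(self.sample_ids),
            pop_labels=list(self.pop_labels),
            region_start=self.region_start,
            region_end=self.region_end,
        )

    def copy(self) -> "HaplotypeMatrix":
        return replace(
            self,
            states=self.states.copy(),
            positions=self.positions.copy(),
            polarity=self.polarity.copy(),
            sample_ids=list(self.sample_ids),
            pop_labels=list(self.pop_labels),
        )

    def derived_counts(self) -> np.ndarray:
        """Per-site count of allele 1 (derived where polarity is known)."""
        return self.states.sum(axis=0).astype(np.int64)


@dataclass
class VcfFilterLog:
    """Counts of records dropped while reading a VCF interval."""

    n_kept: int = 0
    n_indels: int = 0
    n_multiallelic: int = 0
    n_missing_dropped: int = 0
    dropped_sites: list[int] = field(default_factory=list)


def _parse_aa(info_aa, ref: str, alt: str) -> str | None:
    """Normalise an ancestral-allele INFO value; None when unusable."""
    if info_aa is None:
        return None
    aa = str(info_aa).split("|")[0].strip().upper()
    if aa not in _BASES:
        return None
    if aa not in (ref.upper(), alt.upper()):
        return None
    return aa


def read_vcf_region(
    path: str | Path,
    region: GeneRegion | tuple[str, int, int],
    panel: PopulationPanel,
    mode: str = "strict",
) -> tuple[HaplotypeMatrix, VcfFilterLog]:
    """Extract a phased biallelic-SNP haplotype matrix for one interval.

    Indels and multiallelic records are dropped (and counted); polarity is
    set from the AA INFO tag where it matches REF or ALT case-insensitively.
    In strict mode (default) an unphased or missing genotype in a surviving
    record is a hard error; lenient mode drops the site and treats REF as
    ancestral at sites lacking a usable AA tag.
    """
    from cyvcf2 import VCF

    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(region, GeneRegion):
        chrom, start, end = region.chrom, region.start, region.end
    else:
        chrom, start, end = region

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in panel.mapping]
    if missing:
        raise DataError(f"samples present in VCF but absent from panel: {missing}")

    log = VcfFilterLog()
    positions: list[int] = []
    polarity: list[bool] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if variant.CHROM != chrom or not (start <= variant.POS <= end):
            continue
        if len(variant.ALT) != 1:
            log.n_multiallelic += 1
            continue
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            log.n_indels += 1
            continue
        genotypes = variant.genotypes  # [allele_a, allele_b, phased]
        col = np.empty(2 * len(samples), dtype=np.int16)
        bad = False
        for i, gt in enumerate(genotypes):
            a, b = gt[0], gt[1]
            phased = bool(gt[2])
            if a < 0 or b < 0:
                if mode == "strict":
                    raise DataError(
                        f"missing genotype at {chrom}:{variant.POS} (sample {samples[i]})"
                    )
                bad = True
                break
            if not phased and (mode == "strict" or a != b):
                raise DataError(
                    f"unphased genotype at {chrom}:{variant.POS} (sample {samples[i]})"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        if bad:
            log.n_missing_dropped += 1
            log.dropped_sites.append(variant.POS)
            continue
        aa = _parse_aa(variant.INFO.get("AA"), ref, alt)
        if aa is None:
            if mode == "lenient":
                polar = True  # REF treated as ancestral
            else:
                polar = False  # kept, but flagged polarity-unknown
        elif aa == alt:
            col = 1 - col  # recode so that 1 = derived
            polar = True
        else:
            polar = True
        positions.append(variant.POS)
        polarity.append(polar)
        columns.append(col.astype(np.uint8))
        log.n_kept += 1

    n_haps = 2 * len(samples)
    states = (
        np.column_stack(columns) if columns else np.zeros((n_haps, 0), dtype=np.uint8)
    )
    sample_ids = [s for s in samples for _ in range(2)]
    pop_labels = [panel.mapping[s] for s in sample_ids]
    matrix = HaplotypeMatrix(
        states=states,
        positions=np.array(positions, dtype=np.int64),
        chrom=chrom,
        polarity=np.array(polarity, dtype=bool),
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        region_start=start,
        region_end=end,
    )
    if matrix.n_sites == 0:
        warnings.warn(
            f"interval {chrom}:{start}-{end} contains no retained SNPs", stacklevel=2
        )
    return matrix, log


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=sweepscan
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path: str | Path, matrices: "HaplotypeMatrix | list[HaplotypeMatrix]") -> None:
    """Write one or more haplotype matrices as a plain-text VCF 4.2 file.

    Site columns are emitted with REF=A / ALT=G; the AA tag is written only
    for polarity-known sites (state 1 = derived => AA is the REF base), so a
    round trip through :func:`read_vcf_region` reproduces states, positions
    and polarity exactly.  All matrices must share the same sample list.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = [matrices]
    samples = matrices[0].sample_ids[::2]
    for m in matrices:
        if m.sample_ids[::2] != samples:
            raise DataError("all matrices in one VCF must share the same samples")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for m in matrices:
            length = m.region_end or (int(m.positions[-1]) if m.n_sites else 1)
            fh.write(f"##contig=<ID={m.chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for m in matrices:
            for j in range(m.n_sites):
                info = "AA=A" if m.polarity[j] else "."
                gts = "\t".join(
                    f"{m.states[2 * i, j]}|{m.states[2 * i + 1, j]}"
                    for i in range(m.n_samples)
                )
                fh.write(
                    f"{m.chrom}\t{m.positions[j]}\t.\tA\tG\t.\tPASS\t{info}\tGT\t{gts}\n"
                )
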