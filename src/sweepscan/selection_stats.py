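"""Summary statistics of diversity, differentiation and haplotype structure.

Implements, directly from their definitions: pairwise nucleotide diversity,
Tajima's D, the Weir & Cockerham (1984) variance-components FST (weighted and
per-site mean), the unstandardized nSL haplotype score, and the H1/H12
haplotype-frequency-spectrum statistics.
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genomic_data import POPULATIONS, DataError, HaplotypeMatrix

DEFAULT_MAF_CUTOFF = 0.01
DEFAULT_NSL_CAP = 100  # max tract extension (segregating sites) per side


# ---------------------------------------------------------------------------
# Site-frequency-spectrum statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteFrequencySummary:
    n: int
    S: int
    pi_total: float
    theta_w: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of the D variance formula for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _pi_total(states: np.ndarray) -> float:
    n = states.shape[0]
    if n < 2:
        return math.nan
    d = states.sum(axis=0, dtype=np.int64)
    pairs = n * (n - 1) // 2
    return float(np.sum(d * (n - d)) / pairs)


def sfs_summary(h: HaplotypeMatrix) -> SiteFrequencySummary:
    n = h.n_haplotypes
    consts = tajima_constants(n)
    d = h.derived_counts()
    seg = (d > 0) & (d < n)
    S = int(np.count_nonzero(seg))
    pi = _pi_total(h.states)
    theta_w = S / consts["a1"]
    return SiteFrequencySummary(n=n, S=S, pi_total=pi, theta_w=theta_w, **consts)


def nucleotide_diversity(h: HaplotypeMatrix) -> tuple[float, float]:
    """Return (total pi, per-site pi).

    Total pi is the mean Hamming distance over all unordered haplotype
    pairs; per-site pi divides by the region length in bp.
    """
    if h.n_haplotypes < 2:
        warnings.warn("pi undefined for fewer than 2 haplotypes", stacklevel=2)
        return math.nan, math.nan
    if h.n_sites == 0:
        return 0.0, 0.0
    total = _pi_total(h.states)
    return total, total / h.region_length


def tajimas_d(h: HaplotypeMatrix) -> float:
    """Tajima's D on the full (pooled) haplotype sample; NaN when monomorphic."""
    if h.n_haplotypes < 4:
        warnings.warn("Tajima's D needs at least 4 haplotypes", stacklevel=2)
        return math.nan
    s = sfs_summary(h)
    if s.S == 0:
        return math.nan  # monomorphic region
    var = s.e1 * s.S + s.e2 * s.S * (s.S - 1)
    return (s.pi_total - s.S / s.a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstComponents:
    """Per-site a/b/c variance components and the derived FST estimates."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    weighted: float
    mean: float


def _wc_site_components(
    p: np.ndarray, het: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) a/b/c for k populations of diploids.

    ``p``/``het`` are (k, S) allele-frequency and observed-heterozygosity
    arrays, ``sizes`` the per-population individual counts.
    """
    r = len(sizes)
    n = sizes.astype(float)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    w = n[:, None]
    pbar = np.sum(w * p, axis=0) / (r * nbar)
    s2 = np.sum(w * (p - pbar) ** 2, axis=0) / ((r - 1) * nbar)
    hbar = np.sum(w * het, axis=0) / (r * nbar)
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def _pop_arrays(h: HaplotypeMatrix, pops: list[str]):
    """Per-population allele frequencies and heterozygosities per site."""
    n_ind = h.n_samples
    g0 = h.states[0::2, :].astype(np.int64)
    g1 = h.states[1::2, :].astype(np.int64)
    ind_pops = np.array(h.pop_labels[0::2])
    freqs, hets, sizes = [], [], []
    for pop in pops:
        mask = ind_pops == pop
        k = int(mask.sum())
        if 2 * k < 2:
            raise DataError(f"population {pop} has fewer than 2 haplotypes")
        freqs.append((g0[mask].sum(axis=0) + g1[mask].sum(axis=0)) / (2.0 * k))
        hets.append((g0[mask] != g1[mask]).mean(axis=0))
        sizes.append(k)
    return np.array(freqs), np.array(hets), np.array(sizes)


def wc_fst(h: HaplotypeMatrix, mode: str = "global") -> dict:
    """Weighted and mean Weir & Cockerham FST over the matrix's sites.

    ``mode='global'`` returns the k-population estimate for every population
    present; ``mode='pairwise'`` additionally returns all population pairs.
    Sites monomorphic overall contribute zero components and are excluded
    from the per-site mean; an all-monomorphic region yields NaN.
    """
    pops = [p for p in POPULATIONS if p in h.pop_labels]
    if not pops:  # fall back to whatever labels are present
        pops = sorted(set(h.pop_labels))
    if len(pops) < 2:
        raise DataError("FST needs at least 2 populations")

    def estimate(subset: list[str]) -> FstComponents:
        if h.n_sites == 0:
            z = np.zeros(0)
            return FstComponents(z, z, z, math.nan, math.nan)
        p, het, sizes = _pop_arrays(h, subset)
        a, b, c = _wc_site_components(p, het, sizes)
        denom = a + b + c
        poly = denom != 0.0
        weighted = float(a[poly].sum() / denom[poly].sum()) if poly.any() else math.nan
        mean = float(np.mean(a[poly] / denom[poly])) if poly.any() else math.nan
        return FstComponents(a, b, c, weighted, mean)

    out = {"global": estimate(pops), "populations": pops}
    if mode == "pairwise":
        for pa, pb in combinations(pops, 2):
            out[f"{pa}-{pb}"] = estimate([pa, pb])
    elif mode != "global":
        raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NslSiteScore:
    position: int
    derived_freq: float
    sl_ancestral: float
    sl_derived: float
    nsl: float


def _class_mean_tract(states: np.ndarray, rows: np.ndarray, focal: int, cap: int) -> float:
    """Mean pairwise shared-tract length (in sites, counting the focal site)
    among ``rows``, extending left/right until first mismatch, truncated at
    the matrix edges and capped at ``cap`` sites per side.

    Uses progressive group refinement: after extending k sites in one
    direction, the pairs still sharing a tract are exactly the pairs still in
    the same identity group.
    """
    m = len(rows)
    npairs = m * (m - 1) // 2
    total = npairs  # the focal site itself
    n_sites = states.shape[1]
    for step_dir in (1, -1):
        ids = np.zeros(m, dtype=np.int64)  # identity-group label per haplotype
        for k in range(1, cap + 1):
            col = focal + step_dir * k
            if col < 0 or col >= n_sites:
                break
            _, ids, counts = np.unique(
                ids * 2 + states[rows, col], return_inverse=True, return_counts=True
            )
            pairs = int(np.sum(counts * (counts - 1)) // 2)
            if pairs == 0:
                break
            total += pairs
    return total / npairs


def _pairwise_tracts(states: np.ndarray, cap: int) -> np.ndarray:
    """Shared-tract length (sites, incl. focal) for every haplotype pair at
    every focal site, as an (n, n, S) tensor.

    For a pair, the tract at focal s runs from the previous to the next
    mismatching site (exclusive), truncated at the matrix edges and capped
    at ``cap`` sites per side.
    """
    n, S = states.shape
    mism = states[:, None, :] != states[None, :, :]
    idx = np.arange(S, dtype=np.int32)
    prev = np.maximum.accumulate(np.where(mism, idx, np.int32(-1)), axis=2)
    prev = np.concatenate(
        [np.full((n, n, 1), -1, dtype=np.int32), prev[:, :, :-1]], axis=2
    )
    nxt = np.minimum.accumulate(
        np.where(mism, idx, np.int32(S))[:, :, ::-1], axis=2
    )[:, :, ::-1]
    nxt = np.concatenate(
        [nxt[:, :, 1:], np.full((n, n, 1), S, dtype=np.int32)], axis=2
    )
    left = np.minimum(idx - prev - 1, cap)
    right = np.minimum(nxt - idx - 1, cap)
    return (1 + left + right).astype(np.int64)


_TRACT_TENSOR_LIMIT = 150_000_000  # entries; beyond this use the slow path


def nsl_scores(
    h: HaplotypeMatrix,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    cap: int = DEFAULT_NSL_CAP,
) -> list[NslSiteScore]:
    """Unstandardized nSL at every polarity-known site with MAF >= cutoff.

    The matrix should already be restricted to a single population.  Sites
    with unknown polarity are removed from the computation entirely (they
    neither serve as focal sites nor count towards tract lengths); sites
    where either allele class has fewer than 2 haplotypes are skipped.
    """
    known = np.flatnonzero(h.polarity)
    if len(known) < 2:
        return []
    states = h.states[:, known]
    positions = h.positions[known]
    n, S = states.shape
    all_rows = np.arange(n)
    use_tensor = n * n * S <= _TRACT_TENSOR_LIMIT
    tracts = _pairwise_tracts(states, cap) if use_tensor else None
    scores: list[NslSiteScore] = []
    for j in range(S):
        d = int(states[:, j].sum())
        if min(d, n - d) / n < maf_cutoff:
            continue
        if d < 2 or n - d < 2:
            continue
        derived = states[:, j] == 1
        if use_tensor:
            t_j = tracts[:, :, j]
            diag = t_j.diagonal()
            sums = []
            for mask in (~derived, derived):
                m = int(mask.sum())
                pair_sum = (t_j[np.ix_(mask, mask)].sum() - diag[mask].sum()) / 2.0
                sums.append(pair_sum / (m * (m - 1) / 2.0))
            sl_a, sl_d = sums
        else:
            sl_d = _class_mean_tract(states, all_rows[derived], j, cap)
            sl_a = _class_mean_tract(states, all_rows[~derived], j, cap)
        scores.append(
            NslSiteScore(
                position=int(positions[j]),
                derived_freq=d / n,
                sl_ancestral=sl_a,
                sl_derived=sl_d,
                nsl=math.log(sl_a / sl_d),
            )
        )
    return scores


def max_abs_nsl(scores: list[NslSiteScore]) -> float:
    """Maximum |nSL| over a window's site scores; NaN when empty."""
    if not scores:
        return math.nan
    return max(abs(s.nsl) for s in scores)


# ---------------------------------------------------------------------------
# H12
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeSpectrum:
    frequencies: tuple[float, ...]  # sorted descending, sums to 1
    h1: float
    h12: float


def h12(h: HaplotypeMatrix) -> HaplotypeSpectrum:
    """Haplotype-frequency spectrum with H1 and H12 over the region's sites.

    Haplotypes are grouped by exact identity over all retained sites; H12
    merges the two most frequent classes.  A 0-site region degenerates to a
    single haplotype class (H12 = 1) with a warning.
    """
    n = h.n_haplotypes
    if n == 0:
        raise DataError("H12 needs at least one haplotype")
    if h.n_sites == 0:
        warnings.warn("H12 on a region with no sites is trivially 1", stacklevel=2)
        return HaplotypeSpectrum((1.0,), 1.0, 1.0)
    counts = Counter(h.states[i].tobytes() for i in range(n))
    freqs = sorted((c / n for c in counts.values()), reverse=True)
    h1 = sum(f * f for f in freqs)
    if len(freqs) >= 2:
        h12_val = (freqs[0] + freqs[1]) ** 2 + sum(f * f for f in freqs[2:])
    else:
        h12_val = h1
    return HaplotypeSpectrum(tuple(freqs), h1, h12_val)


# ---------------------------------------------------------------------------
# Shared statistic dispatch (used on both observed data and null replicates)
# ---------------------------------------------------------------------------

STATISTICS = ("pi", "tajimas_d", "fst", "h12", "nsl_max")


def compute_statistic(
    h: HaplotypeMatrix,
    statistic: str,
    scope: str = "pooled",
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    nsl_cap: int = DEFAULT_NSL_CAP,
) -> float:
    """One scalar statistic value on a haplotype matrix.

    ``scope`` is a population code for nsl_max, ignored otherwise (pi, D and
    H12 are pooled; fst is the global weighted estimate).
    """
    if statistic == "pi":
        return nucleotide_diversity(h)[1]
    if statistic == "tajimas_d":
        return tajimas_d(h)
    if statistic == "fst":
        return wc_fst(h)["global"].weighted
    if statistic == "h12":
        return h12(h).h12
    if statistic == "nsl_max":
        sub = h.subset_population(scope) if scope in set(h.pop_labels) else h
        return max_abs_nsl(nsl_scores(sub, maf_cutoff=maf_cutoff, cap=nsl_cap))
    raise ValueError(f"unknown statistic {statistic!r}")
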