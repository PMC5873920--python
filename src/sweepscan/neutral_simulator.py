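"""Neutral coalescent simulation under a three-population human demography.

A Hudson-style backwards-in-time coalescent with recombination, written
directly against the standard event rates: within-population coalescence at
k(k-1)/2 / (2N(t)) per generation, recombination at r x (ancestral span) per
lineage, infinite-sites mutation at mu per bp per generation.  Exponential
epochs are handled exactly by inverting the integrated hazard, so no time
discretisation or thinning is involved.

All times are expressed backwards from the present in generations; input
model times are given in years and converted via ``gen_time``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic_data import POPULATIONS, HaplotypeMatrix

#: Study sample sizes (diploid individuals per population).
DEFAULT_SAMPLE_SIZES = {"AFR": 661, "EUR": 503, "EAS": 504}


@dataclass
class DemographicModel:
    """Piecewise three-population history (sizes in diploids, times in years).

    ``n_ooa`` (out-of-Africa bottleneck size) and ``n_eas0`` (East Asian
    founding size) are not part of the primary parameter set; their defaults
    come from the underlying published demographic model and can be
    overridden.
    """

    n_anc: float = 7310.0
    n_afr: float = 14474.0
    t_expand_years: float = 148_000.0
    t_ooa_years: float = 51_000.0
    t_split_years: float = 23_000.0
    n_eur0: float = 1032.0
    n_eas0: float = 554.0
    n_ooa: float = 1861.0
    r_eur: float = 0.0038
    r_eas: float = 0.0048
    mu: float = 2.36e-8
    rec: float = 1.0e-8
    gen_time: float = 25.0
    migration: np.ndarray | None = None  # backwards rates, (3,3), diagonal ignored

    def __post_init__(self) -> None:
        for name in ("n_anc", "n_afr", "n_eur0", "n_eas0", "n_ooa"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not (self.t_expand_years > self.t_ooa_years > self.t_split_years > 0):
            raise ValueError("need t_expand > t_ooa > t_split > 0")
        if self.r_eur < 0 or self.r_eas < 0:
            raise ValueError("growth rates must be >= 0")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("mu and rec must be >= 0")
        if self.gen_time <= 0:
            raise ValueError("gen_time must be positive")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_anc n_afr t_expand_years t_ooa_years t_split_years "
                "n_eur0 n_eas0 n_ooa r_eur r_eas mu rec gen_time".split()
            )
        }
        if self.migration is not None:
            d["migration"] = np.asarray(self.migration).tolist()
        return d


@dataclass
class Demography:
    """Engine-level description: initial populations plus timed events.

    ``events`` entries are ``(time_generations, kind, *args)`` with kind
    'resize' (pop, new_size, new_growth) or 'merge' (source_pop, dest_pop);
    they are processed in time order going backwards from the present.
    """

    names: list[str]
    initial_sizes: list[float]
    growth_rates: list[float]
    events: list[tuple]
    migration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e[0])
        if any(e[0] < 0 for e in self.events):
            raise ValueError("event times must be non-negative")


def build_demography(model: DemographicModel) -> Demography:
    """Convert the year-based model into a backwards-in-time epoch schedule."""
    g_split = model.t_split_years / model.gen_time
    g_ooa = model.t_ooa_years / model.gen_time
    g_expand = model.t_expand_years / model.gen_time
    eur_present = model.n_eur0 * math.exp(model.r_eur * g_split)
    eas_present = model.n_eas0 * math.exp(model.r_eas * g_split)
    events = [
        (g_split, "merge", 2, 1),  # EAS lineages join the out-of-Africa branch
        (g_split, "resize", 1, model.n_ooa, 0.0),
        (g_ooa, "merge", 1, 0),  # out-of-Africa branch joins the African one
        (g_expand, "resize", 0, model.n_anc, 0.0),
    ]
    return Demography(
        names=list(POPULATIONS),
        initial_sizes=[model.n_afr, eur_present, eas_present],
        growth_rates=[0.0, model.r_eur, model.r_eas],
        events=events,
        migration=None if model.migration is None else np.asarray(model.migration, float),
    )


def single_population_demography(n_diploid: float) -> Demography:
    """A constant-size single population (used for calibration checks)."""
    return Demography(["POP"], [float(n_diploid)], [0.0], [])


# ---------------------------------------------------------------------------
# Coalescent engine
# ---------------------------------------------------------------------------

_MAX_ITER = 50_000_000


def _merge_segment_lists(a: list, b: list, full_mask: int) -> list:
    """Union of two disjoint-interval lists; overlapping masks are OR'd and
    fully-coalesced (mask == full) material is discarded."""
    bounds = sorted({x for sl, sr, _ in a + b for x in (sl, sr)})
    out: list = []
    for left, right in zip(bounds, bounds[1:]):
        m = 0
        for segs in (a, b):
            for sl, sr, sm in segs:
                if sl <= left and sr >= right:
                    m |= sm
                    break
        if m and m != full_mask:
            if out and out[-1][1] == left and out[-1][2] == m:
                out[-1] = [out[-1][0], right, m]
            else:
                out.append([left, right, m])
    return out


def _growth_waiting_time(rate_now: float, growth: float, unit_exp: float) -> float:
    """Waiting time for an event whose rate is rate_now * exp(growth * dt)."""
    if growth == 0.0:
        return unit_exp / rate_now
    return math.log1p(growth * unit_exp / rate_now) / growth


def simulate_haplotypes(
    demography: Demography,
    sample_haplotypes: dict[str, int],
    length_bp: int,
    mu: float,
    rec: float,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Simulate one phased, ancestrally polarised haplotype sample.

    Mutations follow the infinite-sites convention on integer positions in
    [1, length_bp]; a discretisation collision triggers a redraw within the
    carrying segment.  Returned rows are grouped by population in the order
    of ``demography.names``, two rows per synthetic diploid sample.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    names = demography.names
    pop_index = {name: i for i, name in enumerate(names)}
    counts = [sample_haplotypes.get(name, 0) for name in names]
    n_total = sum(counts)
    if n_total < 2:
        raise ValueError("need at least 2 sampled haplotypes")
    if any(c % 2 for c in counts):
        raise ValueError("per-population haplotype counts must be even (diploids)")

    full_mask = (1 << n_total) - 1
    L = float(length_bp)
    lineages: list[list] = []  # [pop, segments]
    bit = 0
    for p, c in enumerate(counts):
        for _ in range(c):
            lineages.append([p, [[0.0, L, 1 << bit]]])
            bit += 1

    n_pops = len(names)
    # mutable population state: [size_at_since, backward_decline_rate, since]
    pops = [
        [demography.initial_sizes[p], demography.growth_rates[p], 0.0]
        for p in range(n_pops)
    ]
    mig = demography.migration
    events = list(demography.events)
    ev_i = 0
    t = 0.0
    taken: set[int] = set()
    muts: list[tuple[int, int]] = []  # (position, carrier mask)

    def accrue_mutations(dt: float) -> None:
        if dt <= 0.0 or mu == 0.0 or not lineages:
            return
        seg_lens = []
        seg_refs = []
        for ln in lineages:
            for seg in ln[1]:
                seg_lens.append(seg[1] - seg[0])
                seg_refs.append(seg)
        total = sum(seg_lens)
        if total <= 0.0:
            return
        n_mut = rng.poisson(mu * total * dt)
        if n_mut == 0:
            return
        cum = np.cumsum(seg_lens)
        for u in rng.uniform(0.0, total, size=n_mut):
            k = int(np.searchsorted(cum, u, side="right"))
            sl, sr, sm = seg_refs[min(k, len(seg_refs) - 1)]
            lo = max(1, int(math.floor(sl)) + 1)
            hi = min(length_bp, int(math.ceil(sr)))
            if hi < lo:
                continue
            for _ in range(80):
                pos = int(rng.integers(lo, hi + 1))
                if pos not in taken:
                    taken.add(pos)
                    muts.append((pos, sm))
                    break
            # segment saturated with sites: mutation silently dropped

    for _ in range(_MAX_ITER):
        if not lineages:
            break
        t_bound = events[ev_i][0] if ev_i < len(events) else math.inf

        pop_counts = [0] * n_pops
        for ln in lineages:
            pop_counts[ln[0]] += 1

        best_t = math.inf
        best_ev: tuple | None = None
        for p in range(n_pops):
            k = pop_counts[p]
            if k < 2:
                continue
            size0, decline, since = pops[p]
            n_now = size0 * math.exp(-decline * (t - since))
            rate_now = k * (k - 1) / 2.0 / (2.0 * n_now)
            dt = _growth_waiting_time(rate_now, decline, rng.exponential())
            if t + dt < best_t:
                best_t = t + dt
                best_ev = ("coal", p)
        spans = None
        if rec > 0.0:
            spans = [max(0.0, ln[1][-1][1] - ln[1][0][0]) for ln in lineages]
            total_span = sum(spans)
            if total_span > 0.0:
                dt = rng.exponential() / (rec * total_span)
                if t + dt < best_t:
                    best_t = t + dt
                    best_ev = ("rec",)
        if mig is not None:
            for p in range(n_pops):
                if pop_counts[p] == 0:
                    continue
                for q in range(n_pops):
                    if p == q or mig[p, q] <= 0.0:
                        continue
                    dt = rng.exponential() / (pop_counts[p] * mig[p, q])
                    if t + dt < best_t:
                        best_t = t + dt
                        best_ev = ("mig", p, q)

        if best_t >= t_bound:
            accrue_mutations(t_bound - t)
            t = t_bound
            while ev_i < len(events) and events[ev_i][0] <= t:
                ev = events[ev_i]
                if ev[1] == "resize":
                    _, _, p, new_size, new_growth = ev
                    pops[p] = [float(new_size), float(new_growth), t]
                elif ev[1] == "merge":
                    _, _, src, dst = ev
                    for ln in lineages:
                        if ln[0] == src:
                            ln[0] = dst
                else:  # pragma: no cover - guarded by Demography construction
                    raise ValueError(f"unknown event kind {ev[1]!r}")
                ev_i += 1
            continue

        accrue_mutations(best_t - t)
        t = best_t
        kind = best_ev[0]
        if kind == "coal":
            p = best_ev[1]
            idx = [i for i, ln in enumerate(lineages) if ln[0] == p]
            i1, i2 = rng.choice(len(idx), size=2, replace=False)
            a, b = lineages[idx[i1]], lineages[idx[i2]]
            merged = _merge_segment_lists(a[1], b[1], full_mask)
            for i in sorted((idx[i1], idx[i2]), reverse=True):
                lineages.pop(i)
            if merged:
                lineages.append([p, merged])
        elif kind == "rec":
            cum = np.cumsum(spans)
            i = int(np.searchsorted(cum, rng.uniform(0.0, cum[-1]), side="right"))
            i = min(i, len(lineages) - 1)
            ln = lineages[i]
            segs = ln[1]
            x = rng.uniform(segs[0][0], segs[-1][1])
            left, right = [], []
            for sl, sr, sm in segs:
                if sr <= x:
                    left.append([sl, sr, sm])
                elif sl >= x:
                    right.append([sl, sr, sm])
                else:
                    left.append([sl, x, sm])
                    right.append([x, sr, sm])
            if left and right:
                lineages[i] = [ln[0], left]
                lineages.append([ln[0], right])
        else:  # migration: lineage in p traces back to q
            p, q = best_ev[1], best_ev[2]
            idx = [i for i, ln in enumerate(lineages) if ln[0] == p]
            lineages[idx[int(rng.integers(len(idx)))]][0] = q
    else:  # pragma: no cover
        raise RuntimeError("coalescent did not terminate (iteration guard hit)")

    muts.sort()
    S = len(muts)
    states = np.zeros((n_total, S), dtype=np.uint8)
    positions = np.empty(S, dtype=np.int64)
    for j, (pos, mask) in enumerate(muts):
        positions[j] = pos
        m = mask
        while m:
            low = m & -m
            states[low.bit_length() - 1, j] = 1
            m ^= low
    sample_ids = []
    pop_labels = []
    for name in names:
        for i in range(sample_haplotypes.get(name, 0) // 2):
            sid = f"{name}_{i:05d}"
            sample_ids += [sid, sid]
            pop_labels += [name, name]
    return HaplotypeMatrix(
        states=states,
        positions=positions,
        chrom="sim",
        polarity=np.ones(S, dtype=bool),
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        region_start=1,
        region_end=length_bp,
    )


def simulate_region(
    model: DemographicModel,
    length_bp: int,
    sample_sizes: dict[str, int] | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> HaplotypeMatrix:
    """Simulate one neutral region under the three-population model.

    ``sample_sizes`` counts diploid individuals per population (defaults to
    the full study sizes).  Deterministic for a fixed seed.
    """
    if sample_sizes is None:
        sample_sizes = DEFAULT_SAMPLE_SIZES
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    demog = build_demography(model)
    haps = {pop: 2 * n for pop, n in sample_sizes.items()}
    return simulate_haplotypes(demog, haps, length_bp, model.mu, model.rec, rng)


def simulate_single_population(
    n_haplotypes: int,
    n_diploid: float,
    length_bp: int,
    mu: float,
    rec: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> HaplotypeMatrix:
    """Constant-size single-population sample (calibration helper)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_haplotypes + (n_haplotypes % 2)  # engine works in diploid pairs
    mat = simulate_haplotypes(
        single_population_demography(n_diploid), {"POP": n}, length_bp, mu, rec, rng
    )
    if n != n_haplotypes:
        mat = mat.take_haplotypes(list(range(n_haplotypes)))
    return mat


# ---------------------------------------------------------------------------
# Null distributions
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Simulated neutral values of one statistic for one region length."""

    statistic: str
    length_bp: int
    scope: str
    values: np.ndarray
    n_sims: int
    n_nan: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_sims <= 0:
            raise ValueError("n_sims must be positive")
        if len(self.values) + self.n_nan != self.n_sims:
            raise ValueError("values + NaN replicates must account for every sim")

    @property
    def n_valid(self) -> int:
        return len(self.values)

    def save(self, path: str | Path) -> None:
        header = {
            "statistic": self.statistic,
            "length_bp": self.length_bp,
            "scope": self.scope,
            "n_sims": self.n_sims,
            "n_nan": self.n_nan,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            for v in self.values:
                fh.write(f"{float(v)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "NullDistribution":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            values = np.array([float(line) for line in fh if line.strip()])
        return cls(values=values, **header)


def replicate_seeds(seed: int, n: int, stream: tuple[int, ...] = ()) -> list[np.random.SeedSequence]:
    """Counter-derived per-replicate seed sequences (deterministic in seed)."""
    return [np.random.SeedSequence(entropy=seed, spawn_key=stream + (i,)) for i in range(n)]


def null_distribution(
    model: DemographicModel,
    length_bp: int,
    n_sims: int,
    statistic: str,
    scope: str = "pooled",
    seed: int = 0,
    sample_sizes: dict[str, int] | None = None,
    maf_cutoff: float = 0.01,
    nsl_cap: int = 100,
) -> NullDistribution:
    """Simulate ``n_sims`` neutral replicates and score one statistic on each.

    Uses the same statistic code paths as observed data.  NaN replicates
    (e.g. monomorphic regions for Tajima's D) are excluded from ``values``
    and counted in ``n_nan``; an all-NaN null is an error.
    """
    from .selection_stats import compute_statistic

    values = []
    n_nan = 0
    for ss in replicate_seeds(seed, n_sims):
        mat = simulate_region(model, length_bp, sample_sizes, np.random.default_rng(ss))
        v = compute_statistic(mat, statistic, scope, maf_cutoff=maf_cutoff, nsl_cap=nsl_cap)
        if math.isnan(v):
            n_nan += 1
        else:
            values.append(v)
    if not values:
        raise RuntimeError(f"statistic {statistic!r} undefined under null (all replicates NaN)")
    return NullDistribution(
        statistic=statistic,
        length_bp=length_bp,
        scope=scope,
        values=np.array(values),
        n_sims=n_sims,
        n_nan=n_nan,
        seed=seed,
    )
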