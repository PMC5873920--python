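"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from first principles
(explicit pair enumeration, series sums, per-site loops) and stays
deliberately separate from the package's vectorised code paths.
"""
from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np


def pi_oracle(states: np.ndarray) -> float:
    """Mean pairwise Hamming distance by explicit pair enumeration."""
    n = states.shape[0]
    dists = [
        int(np.sum(states[i] != states[j])) for i, j in combinations(range(n), 2)
    ]
    return sum(dists) / len(dists)


def tajimas_d_oracle(states: np.ndarray) -> float:
    """Tajima's D with constants evaluated from their series definitions."""
    n, _ = states.shape
    d = states.sum(axis=0)
    seg = int(np.sum((d > 0) & (d < n)))
    if seg == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = pi_oracle(states)
    return (pi - seg / a1) / math.sqrt(e1 * seg + e2 * seg * (seg - 1))


def wc_fst_oracle(states: np.ndarray, pop_of_ind: list[str]) -> tuple[float, float]:
    """Weir & Cockerham (1984) weighted and mean FST by per-site loops.

    ``states`` rows are haplotypes, two consecutive rows per individual;
    ``pop_of_ind`` labels each individual.
    """
    pops = sorted(set(pop_of_ind))
    r = len(pops)
    sum_a = sum_abc = 0.0
    ratios = []
    for site in range(states.shape[1]):
        n_i, p_i, h_i = [], [], []
        for pop in pops:
            inds = [k for k, p in enumerate(pop_of_ind) if p == pop]
            genos = [(states[2 * k, site], states[2 * k + 1, site]) for k in inds]
            n_i.append(len(genos))
            p_i.append(sum(g0 + g1 for g0, g1 in genos) / (2 * len(genos)))
            h_i.append(sum(1 for g0, g1 in genos if g0 != g1) / len(genos))
        nbar = sum(n_i) / r
        nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c != 0.0:
            sum_a += a
            sum_abc += a + b + c
            ratios.append(a / (a + b + c))
    if not ratios:
        return math.nan, math.nan
    return sum_a / sum_abc, sum(ratios) / len(ratios)


def nsl_pair_tract_oracle(
    states: np.ndarray, i: int, j: int, focal: int, cap: int
) -> int:
    """Shared tract length for one haplotype pair by explicit extension."""
    length = 1  # focal site
    col = focal - 1
    while col >= 0 and focal - col <= cap and states[i, col] == states[j, col]:
        length += 1
        col -= 1
    col = focal + 1
    S = states.shape[1]
    while col < S and col - focal <= cap and states[i, col] == states[j, col]:
        length += 1
        col += 1
    return length


def nsl_site_oracle(
    states: np.ndarray, focal: int, cap: int
) -> tuple[float, float] | None:
    """(SL_ancestral, SL_derived) at one focal site, or None if undefined."""
    derived = [i for i in range(states.shape[0]) if states[i, focal] == 1]
    ancestral = [i for i in range(states.shape[0]) if states[i, focal] == 0]
    if len(derived) < 2 or len(ancestral) < 2:
        return None
    sls = []
    for group in (ancestral, derived):
        tracts = [
            nsl_pair_tract_oracle(states, i, j, focal, cap)
            for i, j in combinations(group, 2)
        ]
        sls.append(sum(tracts) / len(tracts))
    return sls[0], sls[1]


def h12_oracle(states: np.ndarray) -> tuple[float, float]:
    """(H1, H12) from the sorted haplotype frequency spectrum."""
    n = states.shape[0]
    counts = sorted(Counter(tuple(row) for row in states).values(), reverse=True)
    freqs = [c / n for c in counts]
    h1 = sum(f * f for f in freqs)
    if len(freqs) < 2:
        return h1, h1
    h12 = (freqs[0] + freqs[1]) ** 2 + sum(f * f for f in freqs[2:])
    return h1, h12


def mwu_enum_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided MWU by enumerating all C(n1+n2, n1) assignments."""
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_of(group):
        rest = list(pooled)
        chosen = []
        for v in group:
            chosen.append(v)
            rest.remove(v)
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in chosen for b in rest
        )

    u_obs = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = u_of([pooled[i] for i in idx])
        total += 1
        if abs(u - center) >= dev - 1e-12:
            count += 1
    return u_obs, count / total
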