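"""Empirical p-values against simulated neutral nulls and the scan table."""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genomic_data import POPULATIONS
from .neutral_simulator import NullDistribution

#: Per-statistic tail conventions: only elevation of FST / H12 / max|nSL|
#: signals selection, while Tajima's D is extreme in either direction.
DEFAULT_TAILS = {
    "tajimas_d": "two_sided_abs",
    "fst": "upper",
    "h12": "upper",
    "nsl_max": "upper",
}

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ScanResult:
    """Per-gene, per-statistic observed value and empirical p-value."""

    gene: str
    category: str
    statistic: str
    scope: str
    observed: float
    n_valid_null: int
    p_value: float
    significant: bool

    def p_display(self) -> str:
        """Human-readable p; resolution-limited zeros shown as '< 1/n'."""
        if math.isnan(self.p_value):
            return "NaN"
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_valid_null:.3g}"
        return f"{self.p_value:.4g}"


def empirical_pvalue(observed: float, null: NullDistribution | np.ndarray, tail: str) -> float:
    """Proportion of null values equal to or more extreme than ``observed``.

    ``tail`` is 'upper' (count >= observed), 'lower' (count <= observed) or
    'two_sided_abs' (absolute deviation from the null median).  A NaN
    observation yields a NaN p-value.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, float)
    if len(values) == 0:
        raise ValueError("null distribution has no valid values")
    if math.isnan(observed):
        return math.nan
    if tail == "upper":
        count = int(np.count_nonzero(values >= observed))
    elif tail == "lower":
        count = int(np.count_nonzero(values <= observed))
    elif tail == "two_sided_abs":
        m = float(np.median(values))
        count = int(np.count_nonzero(np.abs(values - m) >= abs(observed - m)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return count / len(values)


def scan_genes(
    gene_stats: list[dict],
    nulls: dict[tuple[str, int, str], NullDistribution],
    alpha: float = ALPHA_DEFAULT,
    tails: dict[str, str] | None = None,
) -> list[ScanResult]:
    """Assemble the scan result table from observed statistics and nulls.

    ``gene_stats`` rows come from :func:`sweepscan.pipeline.gene_statistics`;
    ``nulls`` is keyed by (statistic, region length, scope).  Pi is
    descriptive and gets no p-value.  Tajima's D / FST / H12 use the pooled
    (respectively global) values at the genic length; nsl_max is tested per
    population at the flanked window length.
    """
    tails = dict(DEFAULT_TAILS, **(tails or {}))
    results: list[ScanResult] = []
    for row in gene_stats:
        gene, category = row["gene"], row["category"]
        tested = [
            ("tajimas_d", "pooled", row["length"], row["tajimas_d"]),
            ("fst", "global", row["length"], row["fst_weighted_global"]),
            ("h12", "pooled", row["length"], row["h12"]),
        ]
        for pop in POPULATIONS:
            tested.append(("nsl_max", pop, row["window_length"], row[f"nsl_max_{pop}"]))
        for statistic, scope, length, observed in tested:
            key = (statistic, length, scope)
            if key not in nulls:
                raise KeyError(
                    f"missing null distribution {key} for gene {gene}"
                )
            null = nulls[key]
            p = empirical_pvalue(observed, null, tails[statistic])
            results.append(
                ScanResult(
                    gene=gene,
                    category=category,
                    statistic=statistic,
                    scope=scope,
                    observed=observed,
                    n_valid_null=null.n_valid,
                    p_value=p,
                    significant=(not math.isnan(p)) and p < alpha,
                )
            )
    return results
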