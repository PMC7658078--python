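"""Population-level MI statistics.

Implements the average inverted-allele count per individual

    C_bar_p = (sum_i C_i) / N_p

where C_i is the count of inverted alleles in individual i and N_p the
number of individuals in population (or super-population) p, plus the
per-population summary table (sample count, MIR count, inverted-allele
count, multi-supported MIRs and the derived ratios), the unmapped-read
fraction, and the Pearson correlation of per-chromosome counts against
chromosome length.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

from .detect import MICall
from .regions import MIR, merge_mis_to_mirs


def average_inverted_alleles(
    counts: Sequence[int], exclude_zero_individuals: bool = False
) -> float | None:
    """Arithmetic mean of per-individual inverted-allele counts.

    With ``exclude_zero_individuals`` set, individuals with zero alleles are
    dropped from both numerator and denominator (the convention used when
    reporting diversity among carriers only).  Returns ``None`` (undefined,
    distinct from 0) when no individuals remain.
    """
    for c in counts:
        if c < 0 or int(c) != c:
            raise ValueError(f"negative or non-integer count: {c}")
    included = [c for c in counts if c > 0] if exclude_zero_individuals else list(counts)
    if not included:
        return None
    return sum(included) / len(included)


def _round2(x: float | None) -> float | None:
    return None if x is None else round(x, 2)


def mi_per_sample(n_mi: int, n_samples: int) -> float | None:
    """MI-num/Sam-num: average inverted alleles per individual from the row's
    integer cells (equals C_bar_p since only the sum enters), 2 d.p."""
    if n_samples == 0:
        return None
    return _round2(n_mi / n_samples)


def multi_support_percent(mul_sup: int, n_mir: int) -> float | None:
    """Mul-sup/MIR-num: percentage of MIRs supported by >= 2 MIs, 2 d.p."""
    if n_mir == 0:
        return None
    return _round2(100.0 * mul_sup / n_mir)


def population_summary(
    calls: Sequence[MICall],
    mirs: Sequence[MIR],
    population_map: Mapping[str, tuple[str, str]],
    tolerance: int = 4,
) -> pd.DataFrame:
    """Per-population / per-super-population / pooled summary table.

    One row per population, per super-population, and a pooled Total row.
    ``n_mir`` and ``mul_sup`` (MIRs supported by at least two MIs) are
    recomputed from each row's own calls, except in the Total row where the
    pooled ``mirs`` are used.  ``mi_per_sample`` is C_bar_p rounded to 2
    decimals and ``mul_sup_pct`` the percentage of multi-supported MIRs
    rounded to 2 decimals; both are ``None`` when undefined.
    """
    for c in calls:
        if c.individual not in population_map:
            raise ValueError(f"individual {c.individual} missing from population map")

    pops: dict[str, list[str]] = {}
    supers: dict[str, list[str]] = {}
    for ind, (pop, sup) in population_map.items():
        pops.setdefault(pop, []).append(ind)
        supers.setdefault(sup, []).append(ind)

    calls_by_pop: dict[str, list[MICall]] = {p: [] for p in pops}
    calls_by_sup: dict[str, list[MICall]] = {s: [] for s in supers}
    for c in calls:
        pop, sup = population_map[c.individual]
        calls_by_pop[pop].append(c)
        calls_by_sup[sup].append(c)

    def row(level: str, name: str, members: list[str], row_calls: list[MICall], row_mirs=None):
        if row_mirs is None:
            row_mirs = merge_mis_to_mirs(row_calls, tolerance=tolerance)
        n_samples = len(members)
        n_mi = len(row_calls)
        n_mir = len(row_mirs)
        mul_sup = sum(1 for m in row_mirs if m.hits >= 2)
        return {
            "level": level,
            "name": name,
            "n_samples": n_samples,
            "n_mir": n_mir,
            "n_mi": n_mi,
            "mul_sup": mul_sup,
            "mi_per_sample": mi_per_sample(n_mi, n_samples),
            "mul_sup_pct": multi_support_percent(mul_sup, n_mir),
        }

    rows = [row("population", p, pops[p], calls_by_pop[p]) for p in sorted(pops)]
    rows += [row("super_population", s, supers[s], calls_by_sup[s]) for s in sorted(supers)]
    rows.append(row("total", "Total", list(population_map), list(calls), row_mirs=mirs))
    return pd.DataFrame(rows)


def read_mapping_summary(mapped: int, unmapped: int) -> float:
    """Unmapped-read fraction as a percentage, rounded to one decimal."""
    if mapped < 0 or unmapped < 0:
        raise ValueError("read counts must be non-negative")
    total = mapped + unmapped
    if total == 0:
        raise ValueError("mapped + unmapped must be positive")
    return round(100.0 * unmapped / total, 1)


def correlate_counts_vs_length(
    per_chromosome_counts: Sequence[float], lengths: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (two-sided p) between per-chromosome counts and lengths."""
    if len(per_chromosome_counts) != len(lengths):
        raise ValueError("counts and lengths must align")
    if len(lengths) < 3:
        raise ValueError("at least 3 chromosomes required")
    if len(set(per_chromosome_counts)) == 1 or len(set(lengths)) == 1:
        raise ValueError("constant vector: Pearson correlation undefined")
    r, p = _scipy_stats.pearsonr(per_chromosome_counts, lengths)
    return float(r), float(p)
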