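"""Per-locus, per-population diversity summaries.

Expected heterozygosity is Nei's unbiased estimator
``H_E = 2n/(2n-1) * (1 - sum p_i^2)``; allelic richness is
hypergeometric rarefaction to a fixed number of gene copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from consgen.types import GenotypeTable


@dataclass
class LocusSummary:
    population: str
    locus: str
    n: int          # diploid individuals with a call
    A: int          # allele count
    A_R: float      # rarefied allelic richness
    H_O: float
    H_E: float
    F_IS: "float | None"   # None when H_E == 0 (monomorphic)

    def __post_init__(self) -> None:
        if not (0.0 <= self.H_O <= 1.0 and 0.0 <= self.H_E <= 1.0):
            raise ValueError("heterozygosities must lie in [0, 1]")
        if self.A < 1 or self.A_R > self.A + 1e-9:
            raise ValueError("require 1 <= A_R <= A")


def unbiased_expected_het(counts: "dict[int, int]") -> float:
    """Nei's unbiased H_E from gene-copy counts of each allele."""
    n2 = sum(counts.values())
    if n2 < 2:
        raise ValueError("need at least 2 gene copies")
    sum_p2 = sum((c / n2) ** 2 for c in counts.values())
    return n2 / (n2 - 1) * (1.0 - sum_p2)


def rarefied_richness(counts: "dict[int, int]", g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies."""
    n2 = sum(counts.values())
    if g > n2:
        raise ValueError(f"rarefaction size g={g} exceeds gene copies {n2}")
    if g < 1:
        raise ValueError("g must be >= 1")
    denom = math.comb(n2, g)
    return sum(1.0 - math.comb(n2 - c, g) / denom if n2 - c >= g else 1.0
               for c in counts.values())


def default_rarefaction_g(table: GenotypeTable) -> int:
    """Smallest per-population, per-locus non-missing gene-copy count."""
    g = None
    for pop in table.populations:
        for l in range(len(table.loci)):
            n2 = sum(1 for row in table.calls[pop] if row[l] is not None) * 2
            if n2 > 0:
                g = n2 if g is None else min(g, n2)
    if g is None:
        raise ValueError("table has no non-missing calls")
    return g


def locus_summaries(
    table: GenotypeTable,
    rarefaction_g: "int | None" = None,
) -> "list[LocusSummary]":
    """Diversity summary for every locus x population combination.

    ``rarefaction_g`` defaults to the smallest per-population gene-copy
    count across the dataset (Fstat convention).
    """
    if rarefaction_g is None:
        rarefaction_g = default_rarefaction_g(table)
    out = []
    for pop in table.populations:
        for l, locus in enumerate(table.loci):
            calls = [row[l] for row in table.calls[pop] if row[l] is not None]
            if not calls:
                continue
            counts: dict[int, int] = {}
            het = 0
            for a, b in calls:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
                het += a != b
            n = len(calls)
            h_o = het / n
            h_e = unbiased_expected_het(counts)
            a_r = rarefied_richness(counts, rarefaction_g)
            f_is = None if h_e == 0 else 1.0 - h_o / h_e
            out.append(
                LocusSummary(pop, locus.name, n, len(counts), a_r, h_o, h_e, f_is)
            )
    return out


def summaries_frame(summaries: "list[LocusSummary]") -> pd.DataFrame:
    """Long-format DataFrame of :func:`locus_summaries` output."""
    return pd.DataFrame(
        [
            {
                "population": s.population,
                "locus": s.locus,
                "n": s.n,
                "A": s.A,
                "A_R": s.A_R,
                "H_O": s.H_O,
                "H_E": s.H_E,
                "F_IS": s.F_IS,
            }
            for s in summaries
        ]
    )
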