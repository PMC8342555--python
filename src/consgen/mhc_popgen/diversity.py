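"""Haplotype (allelic) and nucleotide diversity for MHC catalogs."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from consgen.types import AlleleCatalog


@dataclass
class MhcPopSummary:
    population: str
    locus: str
    n_alleles: int          # distinct alleles observed (A_M)
    haplotype_diversity: float   # A_d
    nucleotide_diversity: float  # pi per site

    def __post_init__(self) -> None:
        if not (0.0 <= self.haplotype_diversity <= 1.0):
            raise ValueError("haplotype diversity must lie in [0, 1]")
        if self.nucleotide_diversity < 0:
            raise ValueError("pi must be >= 0")
        if (self.n_alleles == 1) != (self.haplotype_diversity == 0.0):
            raise ValueError("A_d must be 0 iff a single allele is present")


def haplotype_diversity(allele_counts: "dict | Counter") -> float:
    """Unbiased gene diversity over gene copies:
    A_d = n/(n-1) (1 - sum p_i^2)."""
    counts = {a: c for a, c in allele_counts.items() if c > 0}
    n = sum(counts.values())
    if n < 2:
        return 0.0
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1.0 - sum_p2)


def pairwise_differences(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    return sum(x != y for x, y in zip(a, b))


def nucleotide_diversity(seq_counts: "dict[str, int]") -> float:
    """Mean per-site difference over ordered pairs of gene copies,
    with the n/(n-1) small-sample weighting."""
    seqs = [(s, c) for s, c in seq_counts.items() if c > 0]
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0][0])
    n = sum(c for _, c in seqs)
    if n < 2:
        return 0.0
    total = 0.0
    for i, (si, ci) in enumerate(seqs):
        for sj, cj in seqs[i + 1:]:
            total += ci * cj * pairwise_differences(si, sj)
    # ordered pairs: each unordered cross-pair counts twice
    return 2.0 * total / (n * (n - 1)) / length


def population_summaries(
    catalog: AlleleCatalog,
    single_allele: str = "homozygote",
) -> "list[MhcPopSummary]":
    """A_M, A_d and pi per population from a validated catalog."""
    out = []
    for pop in catalog.populations():
        counts: Counter = Counter()
        for ind, geno in catalog.genotypes.items():
            if catalog.population_of[ind] != pop:
                continue
            if len(geno) == 1 and single_allele == "homozygote":
                counts[geno[0]] += 2
            else:
                for a in geno:
                    counts[a] += 1
        if not counts:
            continue
        seq_counts = {catalog.alleles[a]: c for a, c in counts.items()}
        out.append(
            MhcPopSummary(
                pop,
                catalog.locus,
                len(counts),
                haplotype_diversity(counts),
                nucleotide_diversity(seq_counts),
            )
        )
    return out
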