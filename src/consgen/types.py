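"""Shared domain types used across subpackages."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: name plus repeat-motif length in bp."""

    name: str
    motif_length: int = 2

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")


# A diploid call is an unordered pair of allele sizes (bp) or None (missing).
Call = "tuple[int, int] | None"


@dataclass
class GenotypeTable:
    """Diploid multilocus microsatellite genotypes grouped by population.

    ``calls[pop][i][l]`` is the call of individual ``i`` of population
    ``pop`` at locus index ``l``: either a sorted pair of positive
    integer allele sizes (bp) or ``None`` for missing data.
    """

    populations: list[str]
    individuals: dict[str, list[str]]
    loci: list[Locus]
    calls: dict[str, list[list["tuple[int, int] | None"]]]

    def __post_init__(self) -> None:
        for pop in self.populations:
            if pop not in self.calls:
                raise ValueError(f"population {pop!r} has no calls")
            if len(self.calls[pop]) != len(self.individuals[pop]):
                raise ValueError(f"individual/call count mismatch in {pop!r}")
            for row in self.calls[pop]:
                if len(row) != len(self.loci):
                    raise ValueError(
                        f"expected {len(self.loci)} loci per individual in {pop!r},"
                        f" got {len(row)}"
                    )
                for call in row:
                    if call is None:
                        continue
                    a, b = call
                    if a <= 0 or b <= 0:
                        raise ValueError(f"allele sizes must be positive: {call}")

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def n_individuals(self, pop: str | None = None) -> int:
        if pop is not None:
            return len(self.individuals[pop])
        return sum(len(v) for v in self.individuals.values())

    def locus_index(self, locus: str) -> int:
        return self.locus_names.index(locus)

    def allele_counts(self, pop: str, locus: str | int) -> Counter:
        """Counts of allele sizes (gene copies) at one locus in one population."""
        l = locus if isinstance(locus, int) else self.locus_index(locus)
        counts: Counter = Counter()
        for row in self.calls[pop]:
            call = row[l]
            if call is not None:
                counts[call[0]] += 1
                counts[call[1]] += 1
        return counts

    def genotype_counts(self, pop: str, locus: str | int) -> Counter:
        """Counts of unordered genotypes at one locus in one population."""
        l = locus if isinstance(locus, int) else self.locus_index(locus)
        counts: Counter = Counter()
        for row in self.calls[pop]:
            call = row[l]
            if call is not None:
                counts[tuple(sorted(call))] += 1
        return counts

    def subset(self, pops: list[str]) -> "GenotypeTable":
        unknown = [p for p in pops if p not in self.populations]
        if unknown:
            raise KeyError(f"unknown population(s): {unknown}")
        return GenotypeTable(
            populations=list(pops),
            individuals={p: list(self.individuals[p]) for p in pops},
            loci=list(self.loci),
            calls={p: [list(r) for r in self.calls[p]] for p in pops},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        norm = lambda c: {
            p: [[None if x is None else tuple(sorted(x)) for x in row] for row in c[p]]
            for p in c
        }
        return (
            self.populations == other.populations
            and self.individuals == other.individuals
            and self.loci == other.loci
            and norm(self.calls) == norm(other.calls)
        )


@dataclass
class AmpliconReadSet:
    """Unique trimmed variants with read counts for one individual at one locus."""

    individual: str
    locus: str
    variants: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq, n in self.variants.items():
            if n < 1:
                raise ValueError(f"variant {seq[:20]}... has count {n} < 1")

    @property
    def total_reads(self) -> int:
        return sum(self.variants.values())

    def frequencies(self) -> dict[str, float]:
        tot = self.total_reads
        return {s: n / tot for s, n in self.variants.items()}


@dataclass
class AlleleCatalog:
    """Validated alleles for one locus, with per-individual genotypes.

    ``genotypes`` maps individual -> tuple of 1-2 allele names;
    ``population_of`` maps individual -> population id.
    """

    locus: str
    alleles: dict[str, str]
    genotypes: dict[str, tuple]
    population_of: dict[str, str]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.population_of.values():
            if p not in seen:
                seen.append(p)
        return seen

    def allele_frequencies(
        self, single_allele: str = "homozygote"
    ) -> "dict[str, dict[str, float]]":
        """Per-population allele frequencies.

        Individuals carrying one validated allele contribute two copies
        under ``single_allele='homozygote'`` or one under ``'haploid'``.
        """
        if single_allele not in ("homozygote", "haploid"):
            raise ValueError("single_allele must be 'homozygote' or 'haploid'")
        out: dict[str, dict[str, float]] = {}
        for pop in self.populations():
            counts: Counter = Counter()
            for ind, geno in self.genotypes.items():
                if self.population_of[ind] != pop:
                    continue
                if len(geno) == 1 and single_allele == "homozygote":
                    counts[geno[0]] += 2
                else:
                    for a in geno:
                        counts[a] += 1
            tot = sum(counts.values())
            out[pop] = {a: c / tot for a, c in counts.items()} if tot else {}
        return out
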