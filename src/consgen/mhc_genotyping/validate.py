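"""Two-rule validation of amplicon variants into alleles.

Rule 1 (within individual): a variant is retained when it is supported
by more than ``min_reads`` reads or exceeds within-amplicon frequency
``min_freq`` (OR-combined as published; an AND mode is available for
sensitivity analysis).

Rule 2 (across the population): a retained variant is an allele when it
appears in at least two individuals, or in exactly one individual that
also carries another retained variant (the heterozygote exception).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from consgen.types import AlleleCatalog, AmpliconReadSet

logger = logging.getLogger("consgen.mhc_genotyping")


@dataclass
class ReadAccounting:
    """Mean +/- sd and range of per-amplicon read totals."""

    n_amplicons: int
    mean: float
    sd: float
    min: int
    max: int

    def __str__(self) -> str:
        return (f"{self.mean:.0f} ± {self.sd:.0f}, "
                f"ranging from {self.min} to {self.max}")


def read_accounting(readsets: "list[AmpliconReadSet]") -> ReadAccounting:
    totals = [rs.total_reads for rs in readsets]
    if not totals:
        raise ValueError("no read sets")
    arr = np.array(totals, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return ReadAccounting(len(arr), float(arr.mean()), sd,
                          int(arr.min()), int(arr.max()))


def _rule1(rs: AmpliconReadSet, min_reads: int, min_freq: float,
           combine: str) -> "dict[str, int]":
    total = rs.total_reads
    kept = {}
    for seq, count in rs.variants.items():
        by_reads = count > min_reads
        by_freq = count / total > min_freq
        ok = (by_reads or by_freq) if combine == "or" else (by_reads and by_freq)
        if ok:
            kept[seq] = count
    return kept


def validate_alleles(
    readsets_by_pop: "dict[str, list]",
    locus: str = "locus",
    min_reads: int = 1000,
    min_freq: float = 0.1,
    rule_combine: str = "or",
    allele_prefix: "str | None" = None,
) -> AlleleCatalog:
    """Validate variants across populations into an allele catalog.

    ``readsets_by_pop`` maps population -> list of
    :class:`AmpliconReadSet` for one locus. Rule 2 is applied within
    each population; the catalog unions alleles over populations.
    Per-individual genotypes keep the up-to-2 highest-count retained
    alleles (more than 2 is flagged and truncated).
    """
    if rule_combine not in ("or", "and"):
        raise ValueError("rule_combine must be 'or' or 'and'")
    prefix = allele_prefix or locus

    validated_seqs: dict[str, None] = {}
    genotypes: dict[str, tuple] = {}
    population_of: dict[str, str] = {}

    for pop, readsets in readsets_by_pop.items():
        retained = {
            rs.individual: _rule1(rs, min_reads, min_freq, rule_combine)
            for rs in readsets
        }
        carriers: dict[str, list] = {}
        for ind, kept in retained.items():
            for seq in kept:
                carriers.setdefault(seq, []).append(ind)
        alleles_here = set()
        for seq, inds in carriers.items():
            if len(inds) >= 2:
                alleles_here.add(seq)
            elif len(retained[inds[0]]) >= 2:
                # heterozygote exception: sole carrier bears another
                # retained variant
                alleles_here.add(seq)
        for rs in readsets:
            ind = rs.individual
            kept = {s: c for s, c in retained[ind].items() if s in alleles_here}
            if not kept:
                continue
            ranked = sorted(kept, key=lambda s: (-kept[s], s))
            if len(ranked) > 2:
                logger.warning(
                    "%s %s: %d validated variants, keeping top 2 "
                    "(putative contamination or paralog)",
                    locus, ind, len(ranked),
                )
                ranked = ranked[:2]
            genotypes[ind] = tuple(ranked)
            population_of[ind] = pop
            for seq in ranked:
                validated_seqs.setdefault(seq, None)

    names = {
        seq: f"{prefix}*{i + 1:02d}"
        for i, seq in enumerate(validated_seqs)
    }
    return AlleleCatalog(
        locus=locus,
        alleles={name: seq for seq, name in names.items()},
        genotypes={
            ind: tuple(names[s] for s in geno)
            for ind, geno in genotypes.items()
        },
        population_of=population_of,
    )
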