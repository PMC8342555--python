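"""Ratio of allele number to allele-size range (M), a signature of
historical population decline when below the conventional 0.68
threshold."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from consgen.types import GenotypeTable

M_THRESHOLD = 0.68


@dataclass
class MRatioResult:
    population: str
    per_locus: dict            # locus name -> M
    mean_m: float
    decline_flag: bool         # mean below the 0.68 threshold

    def __post_init__(self) -> None:
        for name, m in self.per_locus.items():
            if not (0.0 < m <= 1.0 + 1e-9):
                raise ValueError(f"M out of range at {name}: {m}")


def m_ratio_locus(sizes, motif_length: int) -> float:
    """M = k / (r + 1) with r the size range in repeat units."""
    sizes = sorted(set(sizes))
    if not sizes:
        raise ValueError("no alleles")
    k = len(sizes)
    r = (sizes[-1] - sizes[0]) / motif_length
    return k / (r + 1.0)


def m_ratio(
    table: GenotypeTable,
    pop: "str | None" = None,
    threshold: float = M_THRESHOLD,
) -> "list[MRatioResult]":
    """Per-locus M and its across-locus mean for each population."""
    pops = [pop] if pop is not None else table.populations
    out = []
    for p in pops:
        per_locus = {}
        for l, locus in enumerate(table.loci):
            counts = table.allele_counts(p, l)
            if not counts:
                continue
            per_locus[locus.name] = m_ratio_locus(list(counts), locus.motif_length)
        if not per_locus:
            raise ValueError(f"population {p!r} has no scored loci")
        mean_m = float(np.mean(list(per_locus.values())))
        out.append(MRatioResult(p, per_locus, mean_m, mean_m < threshold))
    return out
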