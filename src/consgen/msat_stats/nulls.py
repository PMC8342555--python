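"""Null-allele screening from heterozygote deficits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from consgen.msat_stats.summaries import unbiased_expected_het
from consgen.types import GenotypeTable


@dataclass
class NullAlleleReport:
    population: str
    locus: str
    null_frequency: float      # Brookfield (1996) estimator 1
    homozygote_excess: bool    # observed homozygotes above 95th pct under HWE
    excess_p: float            # upper-tail simulated p of the homozygote count


def brookfield1(h_e: float, h_o: float) -> float:
    """Brookfield estimator 1 of null-allele frequency, r = (He-Ho)/(1+He)."""
    if not (0 <= h_e <= 1 and 0 <= h_o <= 1):
        raise ValueError("heterozygosities must lie in [0, 1]")
    return (h_e - h_o) / (1.0 + h_e)


def null_allele_screen(
    table: GenotypeTable,
    locus: str,
    sims: int = 2000,
    seed: "int | None" = None,
) -> "list[NullAlleleReport]":
    """Screen each population for a null-allele signature at one locus.

    The homozygote-excess flag is raised when the observed homozygote
    count exceeds the 95th percentile of counts simulated under HWE with
    the observed allele frequencies.
    """
    rng = np.random.default_rng(seed)
    l = table.locus_index(locus)
    reports = []
    for pop in table.populations:
        calls = [row[l] for row in table.calls[pop] if row[l] is not None]
        if len(calls) < 2:
            continue
        counts = table.allele_counts(pop, l)
        alleles = sorted(counts)
        if len(alleles) < 2:
            reports.append(NullAlleleReport(pop, locus, 0.0, False, 1.0))
            continue
        n = len(calls)
        h_o = sum(a != b for a, b in calls) / n
        h_e = unbiased_expected_het(dict(counts))
        r = max(brookfield1(h_e, h_o), 0.0)

        p = np.array([counts[a] for a in alleles], dtype=float)
        p /= p.sum()
        hom_prob = float((p**2).sum())
        obs_hom = sum(a == b for a, b in calls)
        sim_hom = rng.binomial(n, hom_prob, size=sims)
        excess_p = float((sim_hom >= obs_hom).mean())
        threshold = np.quantile(sim_hom, 0.95)
        reports.append(
            NullAlleleReport(pop, locus, r, bool(obs_hom > threshold), excess_p)
        )
    return reports
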