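"""Presence/absence encodings of MHC genotypes for clustering input."""

from __future__ import annotations

import pandas as pd

from consgen.supertyping.dapc import SupertypeAssignment
from consgen.types import AlleleCatalog


def encode_for_structure(
    catalog: AlleleCatalog,
    mode: str = "allele",
    assignment: "SupertypeAssignment | None" = None,
    individuals: "list | None" = None,
    populations: "dict | None" = None,
) -> pd.DataFrame:
    """Binary matrix: individuals x alleles (or supertypes).

    Entries are 1 (carries), 0 (does not) or -1 across the whole locus
    for individuals without a validated genotype. ``individuals`` may
    extend beyond the catalog's genotyped set (e.g. failed
    amplifications), in which case ``populations`` supplies their
    population ids.
    """
    if mode not in ("allele", "supertype"):
        raise ValueError("mode must be 'allele' or 'supertype'")
    if mode == "supertype" and assignment is None:
        raise ValueError("supertype mode requires an assignment")

    if mode == "allele":
        columns = sorted(catalog.alleles)
        carried = {ind: set(geno) for ind, geno in catalog.genotypes.items()}
    else:
        columns = sorted(
            {f"ST{st}" for st in assignment.assignments.values()}
        )
        carried = {
            ind: {f"ST{assignment.assignments[a]}" for a in geno}
            for ind, geno in catalog.genotypes.items()
        }

    inds = individuals if individuals is not None else sorted(catalog.genotypes)
    rows = []
    pop_col = []
    for ind in inds:
        if ind in carried:
            rows.append([1 if c in carried[ind] else 0 for c in columns])
        else:
            rows.append([-1] * len(columns))
        if ind in catalog.population_of:
            pop_col.append(catalog.population_of[ind])
        elif populations is not None and ind in populations:
            pop_col.append(populations[ind])
        else:
            pop_col.append("NA")
    df = pd.DataFrame(rows, index=inds, columns=columns)
    df.insert(0, "population", pop_col)
    return df
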