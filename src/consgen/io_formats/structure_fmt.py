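"""Structure-format input matrices.

Two encodings are written:

* diploid genotype data — two rows per individual, one integer allele
  code per locus, missing = ``-9``;
* binary presence/absence data (e.g. MHC alleles or supertypes) — one
  row per individual of 1 (present), 0 (absent) or -1 (missing).

Each row starts with the individual id and an integer population index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from consgen.types import GenotypeTable

MISSING_GENOTYPE = -9


def write_structure(data, path: str | Path) -> None:
    """Write a Structure input file.

    ``data`` is either a :class:`GenotypeTable` (diploid: two rows per
    individual) or a :class:`pandas.DataFrame` of integers in
    ``{1, 0, -1}`` indexed by individual id with an optional
    ``population`` column placed first.
    """
    lines: list[str] = []
    if isinstance(data, GenotypeTable):
        for pidx, pop in enumerate(data.populations, start=1):
            for ind, row in zip(data.individuals[pop], data.calls[pop]):
                alleles_a, alleles_b = [], []
                for call in row:
                    if call is None:
                        alleles_a.append(MISSING_GENOTYPE)
                        alleles_b.append(MISSING_GENOTYPE)
                    else:
                        alleles_a.append(call[0])
                        alleles_b.append(call[1])
                for alleles in (alleles_a, alleles_b):
                    lines.append(f"{ind} {pidx} " + " ".join(map(str, alleles)))
    elif isinstance(data, pd.DataFrame):
        df = data.copy()
        if "population" in df.columns:
            pops = df.pop("population")
            pop_index = {p: i + 1 for i, p in enumerate(dict.fromkeys(pops))}
            pop_codes = [pop_index[p] for p in pops]
        else:
            pop_codes = [1] * len(df)
        values = df.to_numpy()
        if not np.isin(values, (-1, 0, 1)).all():
            raise ValueError("binary matrix entries must be in {1, 0, -1}")
        for ind, pidx, row in zip(df.index, pop_codes, values):
            lines.append(f"{ind} {pidx} " + " ".join(str(int(v)) for v in row))
    else:
        raise TypeError(f"cannot write {type(data).__name__} as Structure input")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure_matrix(path: str | Path) -> pd.DataFrame:
    """Read a Structure matrix back into a DataFrame (one row per line).

    Returns integer columns ``c0..cL-1`` plus a ``population`` column;
    the index holds individual ids (repeated for diploid files).
    """
    rows, ids, pops = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        ids.append(parts[0])
        pops.append(int(parts[1]))
        rows.append([int(x) for x in parts[2:]])
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"ragged Structure matrix: row widths {sorted(widths)}")
    df = pd.DataFrame(rows, index=ids, columns=[f"c{i}" for i in range(widths.pop())])
    df.insert(0, "population", pops)
    return df
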