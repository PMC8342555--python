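"""CSV writers for statistic tables.

``write_pairwise_csv`` supports the two-statistic layout used for
publication tables: one statistic above the diagonal, another below.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from consgen.msat_stats.pairwise import PairwiseStatMatrix


def write_pairwise_csv(
    upper: PairwiseStatMatrix,
    path: str | Path,
    lower: "PairwiseStatMatrix | None" = None,
    digits: int = 3,
) -> None:
    """Write one matrix (full symmetric) or two (upper/lower split) as CSV."""
    labels = upper.labels
    if lower is not None and lower.labels != labels:
        raise ValueError("upper and lower matrices must share labels")
    k = len(labels)
    cells = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            if i == j:
                cells[i, j] = ""
            elif i < j or lower is None:
                cells[i, j] = f"{upper.values[i, j]:.{digits}f}"
            else:
                cells[i, j] = f"{lower.values[i, j]:.{digits}f}"
    pd.DataFrame(cells, index=labels, columns=labels).to_csv(path)


def read_pairwise_csv(
    path: str | Path,
    upper_name: str = "upper",
    lower_name: str = "lower",
) -> "tuple[PairwiseStatMatrix, PairwiseStatMatrix]":
    """Read a split upper/lower CSV back into two symmetric matrices."""
    df = pd.read_csv(path, index_col=0)
    labels = list(df.index)
    vals = df.to_numpy(dtype=float)
    k = len(labels)
    up = np.zeros((k, k))
    lo = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    up[iu] = vals[iu]
    up += up.T
    il = np.tril_indices(k, -1)
    lo[il] = vals[il]
    lo += lo.T
    return (
        PairwiseStatMatrix(labels, up, upper_name),
        PairwiseStatMatrix(labels, lo, lower_name),
    )
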