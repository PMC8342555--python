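"""Symmetric pairwise statistic matrices with summary utilities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PairwiseStatMatrix:
    """A named symmetric matrix of pairwise population statistics.

    The diagonal is fixed at zero; ``p_values`` (if given) has the same
    shape. Off-diagonal entries must be finite.
    """

    labels: list
    values: np.ndarray
    name: str = "stat"
    p_values: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError(f"matrix shape {self.values.shape} != ({k}, {k})")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        off = self.values[~np.eye(k, dtype=bool)]
        if not np.isfinite(off).all():
            raise ValueError("non-finite off-diagonal entries")
        np.fill_diagonal(self.values, 0.0)
        if self.p_values is not None:
            self.p_values = np.asarray(self.p_values, dtype=float)
            if self.p_values.shape != (k, k):
                raise ValueError("p-value matrix shape mismatch")

    def __getitem__(self, pair) -> float:
        i, j = (self.labels.index(x) for x in pair)
        return float(self.values[i, j])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def mean(self) -> float:
        """Arithmetic mean of the pairwise (off-diagonal) entries."""
        return float(self.offdiag().mean())

    def max(self) -> float:
        return float(self.offdiag().max())

    def min(self) -> float:
        return float(self.offdiag().min())

    def submatrix(self, labels: list) -> "PairwiseStatMatrix":
        idx = [self.labels.index(x) for x in labels]
        pv = self.p_values[np.ix_(idx, idx)] if self.p_values is not None else None
        return PairwiseStatMatrix(
            list(labels), self.values[np.ix_(idx, idx)].copy(), self.name, pv
        )
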