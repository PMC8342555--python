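"""Classical metric multidimensional scaling (principal coordinates)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from consgen.msat_stats.pairwise import PairwiseStatMatrix


@dataclass
class PcoaResult:
    labels: list
    coordinates: np.ndarray       # n x n_axes, sorted by eigenvalue
    eigenvalues: np.ndarray       # positive eigenvalues, descending
    explained_fraction: np.ndarray

    def reconstructed_distances(self) -> np.ndarray:
        d = np.sqrt(
            ((self.coordinates[:, None, :] - self.coordinates[None, :, :]) ** 2)
            .sum(axis=2)
        )
        return d


def pcoa_from_fst(matrix: PairwiseStatMatrix) -> PcoaResult:
    """Principal-coordinates analysis of a pairwise statistic matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and keeps axes with
    positive eigenvalues (sorted descending). Explained fractions are
    relative to the sum of positive eigenvalues.
    """
    d = matrix.values
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 populations")
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > max(1e-10, 1e-8 * abs(eigvals[0]))
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    total = eigvals.sum()
    return PcoaResult(
        list(matrix.labels), coords, eigvals,
        eigvals / total if total > 0 else eigvals,
    )
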