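"""Isolation by distance: Mantel test and regression of genetic on
geographic pairwise distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from consgen.msat_stats.pairwise import PairwiseStatMatrix


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r: float
    mantel_p: float
    permutations: int


def ibd_test(
    genetic: PairwiseStatMatrix,
    distance_km: PairwiseStatMatrix,
    permutations: int = 9999,
    seed: "int | None" = None,
    log_distance: bool = False,
    log_genetic: bool = False,
) -> IbdResult:
    """Simple Mantel test of genetic vs geographic distance.

    The regression (slope, intercept, Pearson r) is fit on the pairwise
    entries; significance comes from permuting population labels of the
    genetic matrix, one-tailed for positive association.
    """
    if genetic.labels != distance_km.labels:
        raise ValueError("matrices must share population labels and order")
    k = len(genetic.labels)
    if k < 3:
        raise ValueError("need at least 3 populations for a Mantel test")
    iu = np.triu_indices(k, 1)
    y = genetic.values[iu].astype(float)
    x = distance_km.values[iu].astype(float)
    if log_distance:
        x = np.log(x)
    if log_genetic:
        y = np.log(y)

    slope, intercept = np.polyfit(x, y, 1)
    r_obs = _pearson(x, y)

    rng = np.random.default_rng(seed)
    hits = 0
    g = genetic.values
    for _ in range(permutations):
        perm = rng.permutation(k)
        y_perm = g[np.ix_(perm, perm)][iu]
        if log_genetic:
            y_perm = np.log(y_perm)
        if _pearson(x, y_perm) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return IbdResult(float(slope), float(intercept), float(r_obs), p, permutations)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd**2).sum() * (yd**2).sum())
    if den == 0:
        return 0.0
    return float((xd * yd).sum() / den)
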