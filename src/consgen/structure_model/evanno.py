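"""Second-order rate-of-change criterion for choosing the cluster
number K from replicate clustering runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DeltaKResult:
    delta_k: dict       # interior K -> delta-K value
    best_k: int

    def __post_init__(self) -> None:
        if not self.delta_k:
            raise ValueError("no interior K values")


def evanno_delta_k(l_table: "dict[int, list]") -> DeltaKResult:
    """delta-K per interior K from a runs-by-K table of mean log-likelihoods.

    ``l_table`` maps K -> list of L(K) values over independent runs
    (>= 3 runs per K, >= 3 consecutive K). delta-K(K) =
    |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)); endpoints are
    undefined.
    """
    ks = sorted(l_table)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values must be consecutive, got {ks}")
    for k in ks:
        if len(l_table[k]) < 3:
            raise ValueError(f"need >= 3 runs per K, got {len(l_table[k])} at K={k}")
    means = {k: float(np.mean(l_table[k])) for k in ks}
    sds = {k: float(np.std(l_table[k], ddof=1)) for k in ks}
    delta = {}
    for k in ks[1:-1]:
        if sds[k] == 0:
            raise ZeroDivisionError(
                f"sd of L(K) is zero at K={k}; add jitter by using more "
                f"independent runs"
            )
        delta[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
    best = max(delta, key=delta.get)
    return DeltaKResult(delta, best)
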