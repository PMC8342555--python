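"""Pairwise phi_ST from sequence distances (two-level variance
decomposition) with permutation significance."""

from __future__ import annotations

import numpy as np

from consgen.mhc_popgen.diversity import pairwise_differences
from consgen.msat_stats.pairwise import PairwiseStatMatrix


def _phi_st_two_groups(d: np.ndarray, sizes: "tuple[int, int]") -> float:
    """phi_ST from a full copy-by-copy distance matrix split into two
    consecutive groups of the given sizes."""
    n1, n2 = sizes
    n = n1 + n2
    iu = np.triu_indices(n, 1)
    ssd_total = d[iu].sum() / n
    within = 0.0
    for start, size in ((0, n1), (n1, n2)):
        if size > 1:
            block = d[start:start + size, start:start + size]
            within += block[np.triu_indices(size, 1)].sum() / size
    df_within = n - 2
    if df_within <= 0:
        return 0.0
    sigma_w = within / df_within
    msd_among = (ssd_total - within) / 1.0
    n_prime = (n - (n1**2 + n2**2) / n) / 1.0
    sigma_a = (msd_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(
    pop_sequences: "dict[str, list]",
    permutations: int = 1000,
    seed: "int | None" = None,
) -> PairwiseStatMatrix:
    """Pairwise phi_ST among populations of aligned sequence copies.

    ``pop_sequences`` maps population -> list of sequences (one entry
    per gene copy). Distances are raw pairwise differences (squared
    Euclidean in the variance decomposition sense). p-values are
    one-tailed from permuting copies among the two populations.
    """
    pops = list(pop_sequences)
    if any(len(s) == 0 for s in pop_sequences.values()):
        raise ValueError("every population needs at least one copy")
    rng = np.random.default_rng(seed)
    k = len(pops)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            seqs = list(pop_sequences[pops[i]]) + list(pop_sequences[pops[j]])
            n1 = len(pop_sequences[pops[i]])
            n = len(seqs)
            d = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    d[a, b] = d[b, a] = pairwise_differences(seqs[a], seqs[b])
            obs = _phi_st_two_groups(d, (n1, n - n1))
            values[i, j] = values[j, i] = obs
            hits = 0
            for _ in range(permutations):
                perm = rng.permutation(n)
                dp = d[np.ix_(perm, perm)]
                if _phi_st_two_groups(dp, (n1, n - n1)) >= obs - 1e-12:
                    hits += 1
            pvals[i, j] = pvals[j, i] = (hits + 1) / (permutations + 1)
    return PairwiseStatMatrix(pops, values, "phi_ST", pvals)
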