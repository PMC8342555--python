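"""Markov-chain exact test of Hardy-Weinberg proportions.

The chain walks over genotype tables with fixed allele counts by
shuffling gene copies between individuals (a random-transposition walk
over pairings, which leaves the conditional exact-test distribution
invariant), and estimates the probability-ordering exact p-value:
the probability mass of tables no more likely than the observed one.
The standard error comes from the between-batch variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class HweResult:
    p_value: float
    se: float
    n_batches: int


def _table_logprob(counts: "dict[tuple, int]") -> float:
    """log of the HWE-conditional table probability, up to a constant.

    P(table) proportional to 2^H / prod(n_ij!) with H the number of
    heterozygous individuals.
    """
    lp = 0.0
    for (a, b), n in counts.items():
        if a != b:
            lp += n * math.log(2.0)
        lp -= math.lgamma(n + 1)
    return lp


def hwe_exact_test(
    genotype_counts: "dict[tuple, int]",
    batches: int = 1000,
    iters_per_batch: int = 10000,
    burn_in: int = 10000,
    seed: "int | None" = None,
) -> HweResult:
    """Exact HWE test p-value by Markov-chain Monte Carlo.

    Parameters
    ----------
    genotype_counts
        Unordered genotype -> count, e.g. ``{(1, 1): 25, (1, 2): 50}``.
    """
    rng = np.random.default_rng(seed)
    genos = {tuple(sorted(g)): n for g, n in genotype_counts.items() if n > 0}
    if not genos:
        raise ValueError("empty genotype table")
    alleles = sorted({a for g in genos for a in g})
    if len(alleles) == 1 or len(genos) == 1:
        return HweResult(1.0, 0.0, 0)

    # flat array of gene copies; positions (2i, 2i+1) form individual i
    copies: list = []
    for (a, b), n in genos.items():
        copies.extend([a, b] * n)
    copies_arr = np.array(copies)
    n_ind = len(copies_arr) // 2

    counts: dict[tuple, int] = dict(genos)
    lp = _table_logprob(counts)
    lp_obs = lp + 1e-9  # tolerance for float ties

    def geno_at(i: int) -> tuple:
        a, b = copies_arr[2 * i], copies_arr[2 * i + 1]
        return (a, b) if a <= b else (b, a)

    total_steps = burn_in + batches * iters_per_batch
    pos1 = rng.integers(0, 2 * n_ind, size=total_steps)
    pos2 = rng.integers(0, 2 * n_ind, size=total_steps)

    batch_hits = np.zeros(batches)
    step = 0
    for b in range(-1, batches):  # b == -1 is burn-in
        n_iters = burn_in if b < 0 else iters_per_batch
        hits = 0
        for _ in range(n_iters):
            i, j = pos1[step], pos2[step]
            step += 1
            ind_i, ind_j = i // 2, j // 2
            if ind_i != ind_j:
                g_i, g_j = geno_at(ind_i), geno_at(ind_j)
                copies_arr[i], copies_arr[j] = copies_arr[j], copies_arr[i]
                g_i2, g_j2 = geno_at(ind_i), geno_at(ind_j)
                if (g_i, g_j) != (g_i2, g_j2):
                    # update counts and log-prob incrementally
                    for g in (g_i, g_j):
                        c = counts[g]
                        lp += math.lgamma(c + 1) - math.lgamma(c)
                        if g[0] != g[1]:
                            lp -= math.log(2.0)
                        counts[g] = c - 1
                        if counts[g] == 0:
                            del counts[g]
                    for g in (g_i2, g_j2):
                        c = counts.get(g, 0)
                        lp -= math.lgamma(c + 2) - math.lgamma(c + 1)
                        if g[0] != g[1]:
                            lp += math.log(2.0)
                        counts[g] = c + 1
            if b >= 0 and lp <= lp_obs:
                hits += 1
        if b >= 0:
            batch_hits[b] = hits / n_iters

    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return HweResult(max(p, 1.0 / (batches * iters_per_batch)), se, batches)
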