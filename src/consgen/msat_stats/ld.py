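"""Markov-chain exact test of genotypic linkage disequilibrium.

The null hypothesis is independence of the genotypes at two loci. The
chain shuffles the second locus' genotypes across individuals (a random
transposition walk, uniform over permutations), which induces the
margin-conditioned hypergeometric distribution on the genotype x
genotype contingency table. The p-value is probability-ordered, as in
the exact test of independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from consgen.types import GenotypeTable


@dataclass
class LdResult:
    p_value: float
    se: float


def _contingency_logprob(table: np.ndarray) -> float:
    # hypergeometric probability of the table given margins, up to a constant
    return -sum(math.lgamma(int(n) + 1) for n in table.ravel())


def ld_exact_test(
    table: GenotypeTable,
    locus_pair: "tuple[str, str]",
    batches: int = 1000,
    iters_per_batch: int = 10000,
    burn_in: int = 10000,
    seed: "int | None" = None,
    pops: "list[str] | None" = None,
) -> LdResult:
    """Exact test of genotypic independence between two loci.

    Individuals are pooled within populations (the statistic is computed
    per population and hits are pooled across populations, as Genepop
    does for its across-population test when a single population is
    given the result is the plain within-population test).
    """
    la, lb = (table.locus_index(l) for l in locus_pair)
    pops = pops or table.populations
    rng = np.random.default_rng(seed)

    per_pop_p = []
    weights = []
    for pop in pops:
        rows = [
            (tuple(sorted(r[la])), tuple(sorted(r[lb])))
            for r in table.calls[pop]
            if r[la] is not None and r[lb] is not None
        ]
        if len(rows) < 2:
            continue
        ga = sorted({g for g, _ in rows})
        gb = sorted({g for _, g in rows})
        if len(ga) == 1 or len(gb) == 1:
            per_pop_p.append((1.0, 0.0))
            weights.append(len(rows))
            continue
        a_idx = np.array([ga.index(g) for g, _ in rows])
        b_idx = np.array([gb.index(g) for _, g in rows])
        p, se = _mc_independence(a_idx, b_idx, len(ga), len(gb),
                                 batches, iters_per_batch, burn_in, rng)
        per_pop_p.append((p, se))
        weights.append(len(rows))

    if not per_pop_p:
        return LdResult(1.0, 0.0)
    if len(per_pop_p) == 1:
        return LdResult(*per_pop_p[0])
    # Fisher's combination across populations
    chi2 = -2.0 * sum(math.log(max(p, 1e-12)) for p, _ in per_pop_p)
    from scipy.stats import chi2 as chi2_dist

    p_comb = float(chi2_dist.sf(chi2, df=2 * len(per_pop_p)))
    se = math.sqrt(sum(se**2 for _, se in per_pop_p))
    return LdResult(p_comb, se)


def _mc_independence(a_idx, b_idx, ka, kb, batches, iters, burn_in, rng):
    n = len(a_idx)
    cont = np.zeros((ka, kb), dtype=int)
    for a, b in zip(a_idx, b_idx):
        cont[a, b] += 1
    lp = _contingency_logprob(cont)
    lp_obs = lp + 1e-9

    b_perm = b_idx.copy()
    total = burn_in + batches * iters
    pick1 = rng.integers(0, n, size=total)
    pick2 = rng.integers(0, n, size=total)
    batch_hits = np.zeros(batches)
    step = 0
    log = math.log
    for b in range(-1, batches):
        n_iters = burn_in if b < 0 else iters
        hits = 0
        for _ in range(n_iters):
            i, j = pick1[step], pick2[step]
            step += 1
            ai, aj = a_idx[i], a_idx[j]
            bi, bj = b_perm[i], b_perm[j]
            if bi != bj and ai != aj:
                # swap b values of individuals i and j
                for (r, c, d) in ((ai, bi, -1), (aj, bj, -1),
                                  (ai, bj, 1), (aj, bi, 1)):
                    old = cont[r, c]
                    cont[r, c] = old + d
                    lp += math.lgamma(old + 1) - math.lgamma(old + d + 1)
                b_perm[i], b_perm[j] = bj, bi
            if b >= 0 and lp <= lp_obs:
                hits += 1
        if b >= 0:
            batch_hits[b] = hits / n_iters
    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return max(p, 1.0 / (batches * iters)), se
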