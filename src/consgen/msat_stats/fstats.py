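"""Among-population differentiation statistics.

* ``fst_weir_cockerham`` — Weir & Cockerham (1984) variance-components
  theta, loci combined by summing components, with permutation tests.
* ``rst_slatkin`` — the analogous variance-component ratio computed on
  allele sizes expressed in repeat units.
* ``gst_nei`` — Nei's G_ST from heterozygosity partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from consgen.msat_stats.pairwise import PairwiseStatMatrix
from consgen.types import GenotypeTable

# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _wc_locus_components(pop_calls: "list[list[tuple]]") -> "tuple[float, float]":
    """Sum of (a) and (a+b+c) components over alleles for one locus.

    ``pop_calls[i]`` is the list of non-missing (a, b) calls of
    population i at the locus.
    """
    pop_calls = [c for c in pop_calls if c]
    r = len(pop_calls)
    if r < 2:
        return 0.0, 0.0
    n = np.array([len(c) for c in pop_calls], dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({a for calls in pop_calls for ab in calls for a in ab})
    if len(alleles) < 2:
        return 0.0, 0.0

    sum_a = sum_abc = 0.0
    for allele in alleles:
        # int() guards against numpy bool scalars, whose + is logical-or
        p = np.array(
            [sum(int(a == allele) + int(b == allele) for a, b in calls)
             / (2 * len(calls))
             for calls in pop_calls]
        )
        h = np.array(
            [sum((a == allele) != (b == allele) for a, b in calls) / len(calls)
             for calls in pop_calls]
        )
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def _calls_by_pop(table: GenotypeTable, pops: "list[str]", locus: int):
    return [
        [row[locus] for row in table.calls[p] if row[locus] is not None]
        for p in pops
    ]


def weir_cockerham_theta(table: GenotypeTable, pops: "list[str] | None" = None) -> float:
    """Multilocus Weir-Cockerham theta over the given populations."""
    pops = pops or table.populations
    num = den = 0.0
    for l in range(len(table.loci)):
        a, abc = _wc_locus_components(_calls_by_pop(table, pops, l))
        num += a
        den += abc
    if den == 0:
        raise ValueError("theta undefined: no polymorphic loci")
    return num / den


@dataclass
class FstResult:
    global_theta: float
    pairwise: PairwiseStatMatrix


def _pairwise_matrix(table, pops, stat_fn, name, permutations, seed):
    k = len(pops)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            pair = [pops[i], pops[j]]
            obs = stat_fn(table, pair)
            values[i, j] = values[j, i] = obs
            if permutations:
                pvals[i, j] = pvals[j, i] = _permutation_p(
                    table, pair, stat_fn, obs, permutations, rng
                )
    return PairwiseStatMatrix(list(pops), values, name, pvals)


def _permutation_p(table, pair, stat_fn, obs, permutations, rng):
    """One-tailed p for stat > 0 by permuting individuals among the pair."""
    pooled_inds = []
    for p in pair:
        pooled_inds.extend((p, idx) for idx in range(len(table.calls[p])))
    n_first = len(table.calls[pair[0]])
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(pooled_inds))
        shuffled = GenotypeTable(
            populations=list(pair),
            individuals={
                pair[0]: [f"i{t}" for t in range(n_first)],
                pair[1]: [f"i{t}" for t in range(len(pooled_inds) - n_first)],
            },
            loci=table.loci,
            calls={
                pair[0]: [
                    table.calls[pooled_inds[t][0]][pooled_inds[t][1]]
                    for t in perm[:n_first]
                ],
                pair[1]: [
                    table.calls[pooled_inds[t][0]][pooled_inds[t][1]]
                    for t in perm[n_first:]
                ],
            },
        )
        try:
            stat = stat_fn(shuffled, pair)
        except ValueError:
            stat = 0.0  # degenerate shuffle (no polymorphism left)
        if stat >= obs:
            hits += 1
    return (hits + 1) / (permutations + 1)


def fst_weir_cockerham(
    table: GenotypeTable,
    pops: "list[str] | None" = None,
    permutations: int = 10000,
    seed: "int | None" = None,
) -> FstResult:
    """Global theta and the pairwise theta matrix with permutation p-values."""
    pops = pops or table.populations
    global_theta = weir_cockerham_theta(table, pops)
    pairwise = _pairwise_matrix(
        table, pops, _theta_or_zero, "F_ST", permutations, seed
    )
    return FstResult(global_theta, pairwise)


def _theta_or_zero(table, pair):
    try:
        return weir_cockerham_theta(table, pair)
    except ValueError:
        return 0.0


# ---------------------------------------------------------------------------
# R_ST (variance components on allele sizes in repeat units)


def _rst_locus_components(sizes_by_pop: "list[np.ndarray]") -> "tuple[float, float]":
    groups = [np.asarray(x, dtype=float) for x in sizes_by_pop if len(x) > 0]
    k = len(groups)
    if k < 2:
        return 0.0, 0.0
    n = np.array([len(g) for g in groups], dtype=float)
    total_n = n.sum()
    if total_n <= k:
        return 0.0, 0.0
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (total_n - k)
    n0 = (total_n - (n**2).sum() / total_n) / (k - 1)
    sigma_b = (msb - msw) / n0
    return sigma_b, msw


def rst_value(table: GenotypeTable, pops: "list[str] | None" = None) -> float:
    """Multilocus R_ST over the given populations."""
    pops = pops or table.populations
    s_among = s_within = 0.0
    for l, locus in enumerate(table.loci):
        sizes = [
            np.array(
                [a / locus.motif_length
                 for row in table.calls[p] if row[l] is not None
                 for a in row[l]]
            )
            for p in pops
        ]
        sb, sw = _rst_locus_components(sizes)
        s_among += sb
        s_within += sw
    den = s_among + s_within
    if den == 0:
        raise ValueError("R_ST undefined: no size variance")
    return s_among / den


@dataclass
class RstResult:
    global_rst: float
    pairwise: PairwiseStatMatrix


def rst_slatkin(
    table: GenotypeTable,
    pops: "list[str] | None" = None,
    permutations: int = 10000,
    seed: "int | None" = None,
) -> RstResult:
    pops = pops or table.populations
    global_rst = rst_value(table, pops)
    pairwise = _pairwise_matrix(
        table, pops, _rst_or_zero, "R_ST", permutations, seed
    )
    return RstResult(global_rst, pairwise)


def _rst_or_zero(table, pair):
    try:
        return rst_value(table, pair)
    except ValueError:
        return 0.0


# ---------------------------------------------------------------------------
# Nei's G_ST


def gst_value(table: GenotypeTable, pops: "list[str] | None" = None) -> float:
    """Nei's multilocus G_ST: H_S and H_T averaged over loci, then ratio."""
    pops = pops or table.populations
    h_s_list, h_t_list = [], []
    for l in range(len(table.loci)):
        freqs = []
        for p in pops:
            counts = table.allele_counts(p, l)
            tot = sum(counts.values())
            if tot == 0:
                continue
            freqs.append({a: c / tot for a, c in counts.items()})
        if len(freqs) < 2:
            continue
        h_s = np.mean([1.0 - sum(v**2 for v in f.values()) for f in freqs])
        alleles = {a for f in freqs for a in f}
        mean_p = {a: np.mean([f.get(a, 0.0) for f in freqs]) for a in alleles}
        h_t = 1.0 - sum(v**2 for v in mean_p.values())
        h_s_list.append(h_s)
        h_t_list.append(h_t)
    if not h_t_list or np.mean(h_t_list) == 0:
        raise ValueError("G_ST undefined: no diversity")
    return float((np.mean(h_t_list) - np.mean(h_s_list)) / np.mean(h_t_list))


def gst_nei(table: GenotypeTable, pops: "list[str] | None" = None) -> PairwiseStatMatrix:
    """Pairwise Nei G_ST matrix (no permutation test)."""
    pops = pops or table.populations
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                g = gst_value(table, [pops[i], pops[j]])
            except ValueError:
                g = 0.0
            values[i, j] = values[j, i] = g
    return PairwiseStatMatrix(list(pops), values, "G_ST")
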