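"""Admixture-model Bayesian clustering by Gibbs sampling.

The model is the standard admixture model: cluster allele frequencies
P ~ Dirichlet(lambda), per-individual ancestry Q ~ Dirichlet(alpha),
and a latent cluster of origin for every gene copy. alpha is updated by
a Metropolis step with a uniform prior on (0, 10]. Data may be diploid
allele-coded genotypes or haploid binary (presence/absence) rows;
missing copies (-1) are skipped in all updates.

L(K) is the posterior mean of ln P(data | P, Q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from consgen.types import GenotypeTable

ALPHA_MAX = 10.0


@dataclass
class StructureData:
    """Integer-coded genotype matrix: (N individuals, L loci, ploidy).

    Entries are allele indices within each locus, or -1 for missing.
    """

    individuals: list
    x: np.ndarray
    n_alleles: list
    populations: "list | None" = None

    @classmethod
    def from_genotype_table(cls, table: GenotypeTable) -> "StructureData":
        inds, pops, rows = [], [], []
        for pop in table.populations:
            for ind, row in zip(table.individuals[pop], table.calls[pop]):
                inds.append(ind)
                pops.append(pop)
                rows.append(row)
        L = len(table.loci)
        allele_maps = []
        for l in range(L):
            alleles = sorted({a for row in rows if row[l] is not None
                              for a in row[l]})
            allele_maps.append({a: i for i, a in enumerate(alleles)})
        x = np.full((len(rows), L, 2), -1, dtype=np.int64)
        for i, row in enumerate(rows):
            for l in range(L):
                if row[l] is not None:
                    x[i, l, 0] = allele_maps[l][row[l][0]]
                    x[i, l, 1] = allele_maps[l][row[l][1]]
        return cls(inds, x, [max(len(m), 1) for m in allele_maps], pops)

    @classmethod
    def from_binary_matrix(cls, matrix: pd.DataFrame) -> "StructureData":
        """Presence/absence columns (1/0/-1) as haploid two-state loci."""
        df = matrix.drop(columns=["population"], errors="ignore")
        pops = (list(matrix["population"])
                if "population" in matrix.columns else None)
        vals = df.to_numpy(dtype=np.int64)
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("binary matrix entries must be in {1, 0, -1}")
        return cls(list(df.index), vals[:, :, None], [2] * vals.shape[1], pops)


@dataclass
class StructureRun:
    K: int
    Q: np.ndarray              # posterior-mean ancestry, rows sum to 1
    P: list                    # per locus (K, n_alleles) posterior means
    mean_lnl: float
    run_index: int = 0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        for l, p in enumerate(self.P):
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"P rows must sum to 1 at locus {l}")

    def hard_assignments(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


def admixture_gibbs(
    data: "StructureData | GenotypeTable | pd.DataFrame",
    K: int,
    burnin: int = 100000,
    generations: int = 400000,
    seed: "int | None" = None,
    lambda_prior: float = 1.0,
    run_index: int = 0,
) -> StructureRun:
    """Run the admixture Gibbs sampler and return posterior means."""
    if isinstance(data, GenotypeTable):
        data = StructureData.from_genotype_table(data)
    elif isinstance(data, pd.DataFrame):
        data = StructureData.from_binary_matrix(data)
    N, L, ploidy = data.x.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K={K} exceeds number of individuals {N}")
    rng = np.random.default_rng(seed)

    # flatten observed gene copies
    obs = np.nonzero(data.x.reshape(N, -1) >= 0)
    ind_idx = obs[0]
    flat_pos = obs[1]
    loc_idx = flat_pos // ploidy
    allele = data.x.reshape(N, -1)[obs]
    M = len(ind_idx)
    a_max = max(data.n_alleles)

    z = rng.integers(0, K, size=M)
    alpha = 1.0
    q = np.full((N, K), 1.0 / K)
    p_mat = np.zeros((L, K, a_max))

    # padding mask so unused allele slots never receive mass
    allele_ok = np.zeros((L, a_max), dtype=bool)
    for l, na in enumerate(data.n_alleles):
        allele_ok[l, :na] = True

    q_sum = np.zeros((N, K))
    p_sum = np.zeros((L, K, a_max))
    lnl_sum = 0.0
    alpha_sum = 0.0
    kept = 0

    total_sweeps = burnin + generations
    for sweep in range(total_sweeps):
        # --- P | Z: Dirichlet(lambda + counts)
        counts_p = np.zeros((L, K, a_max))
        np.add.at(counts_p, (loc_idx, z, allele), 1.0)
        g = rng.gamma(counts_p + lambda_prior)
        g[:, :, :] *= allele_ok[:, None, :]
        p_mat = g / g.sum(axis=2, keepdims=True)

        # --- Q | Z: Dirichlet(alpha + counts)
        counts_q = np.zeros((N, K))
        np.add.at(counts_q, (ind_idx, z), 1.0)
        gq = rng.gamma(counts_q + alpha)
        q = gq / gq.sum(axis=1, keepdims=True)

        # --- Z | P, Q: categorical per gene copy
        prob = q[ind_idx] * p_mat[loc_idx, :, allele]
        cum = prob.cumsum(axis=1)
        r = rng.random(M) * cum[:, -1]
        z = (cum < r[:, None]).sum(axis=1)

        # --- alpha: Metropolis with uniform (0, ALPHA_MAX] prior
        if K > 1:
            prop = alpha + rng.normal(0.0, 0.25)
            if 0 < prop <= ALPHA_MAX:
                log_q = np.log(np.clip(q, 1e-300, None)).sum()
                def dir_loglik(a):
                    return N * (math.lgamma(K * a) - K * math.lgamma(a)) \
                        + (a - 1.0) * log_q
                if math.log(rng.random() + 1e-300) < dir_loglik(prop) - dir_loglik(alpha):
                    alpha = prop

        if sweep >= burnin:
            kept += 1
            q_sum += q
            p_sum += p_mat
            alpha_sum += alpha
            mix = (q[ind_idx] * p_mat[loc_idx, :, allele]).sum(axis=1)
            lnl_sum += float(np.log(np.clip(mix, 1e-300, None)).sum())

    q_mean = q_sum / kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    p_mean = []
    for l, na in enumerate(data.n_alleles):
        pm = p_sum[l, :, :na] / kept
        p_mean.append(pm / pm.sum(axis=1, keepdims=True))
    return StructureRun(
        K, q_mean, p_mean, lnl_sum / kept, run_index, alpha_sum / kept
    )


def match_labels(reference: StructureRun, run: StructureRun) -> np.ndarray:
    """Greedy cluster-label permutation aligning ``run`` to ``reference``.

    Returns the permutation ``perm`` with ``run.Q[:, perm]`` best
    matching ``reference.Q`` column by column (greedy on correlation of
    ancestry columns)."""
    if reference.K != run.K:
        raise ValueError("runs must share K")
    K = run.K
    sim = reference.Q.T @ run.Q
    perm = np.full(K, -1)
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        perm[i] = j
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return perm
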