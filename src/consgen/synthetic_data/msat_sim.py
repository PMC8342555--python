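"""Forward Wright-Fisher simulator for multi-population microsatellites.

Populations exchange migrants according to a row-stochastic rate
matrix; each locus mutates independently under a pluggable model.
Allele states are repeat counts, converted to bp via the locus motif
length when the sample is packaged as a :class:`GenotypeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from consgen.synthetic_data.mutation import SMM, MutationModel
from consgen.types import GenotypeTable, Locus


@dataclass
class SimPopModel:
    """Demographic model for :func:`simulate_msat`.

    ``migration[i, j]`` is the probability that a gamete in population i
    originates from population j (off-diagonal entries; rows may sum to
    less than 1, the remainder is philopatry). ``bottleneck`` is an
    optional ``(start_generation, duration, reduced_Ne)`` triple applied
    to every population.
    """

    n_populations: int
    ne: "list[int] | int"
    migration: "np.ndarray | None" = None
    mu: float = 5e-4
    model: MutationModel = field(default_factory=SMM)
    generations: int = 100
    bottleneck: "tuple[int, int, int] | None" = None

    def __post_init__(self) -> None:
        if isinstance(self.ne, int):
            self.ne = [self.ne] * self.n_populations
        if len(self.ne) != self.n_populations:
            raise ValueError("ne must have one entry per population")
        if any(n < 1 for n in self.ne):
            raise ValueError("effective sizes must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mutation rate must lie in [0, 1]")
        if self.migration is None:
            self.migration = np.zeros((self.n_populations, self.n_populations))
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (self.n_populations, self.n_populations):
            raise ValueError("migration matrix shape mismatch")
        np.fill_diagonal(self.migration, 0.0)
        if (self.migration < 0).any() or (self.migration.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("migration rows must be non-negative and sum to <= 1")

    def ne_at(self, generation: int) -> "list[int]":
        if self.bottleneck is None:
            return list(self.ne)
        start, duration, reduced = self.bottleneck
        if reduced == 0:
            raise ValueError("bottleneck Ne must be >= 1")
        if start <= generation < start + duration:
            return [reduced] * self.n_populations
        return list(self.ne)


def island_model(
    n_populations: int, ne: int, m: float, mu: float = 5e-4,
    generations: int = 100, model: "MutationModel | None" = None,
) -> SimPopModel:
    """Symmetric island model: total emigration rate ``m`` split evenly."""
    mig = np.full((n_populations, n_populations), m / (n_populations - 1))
    np.fill_diagonal(mig, 0.0)
    return SimPopModel(
        n_populations, ne, mig, mu=mu,
        model=model or SMM(), generations=generations,
    )


def simulate_msat(
    model: SimPopModel,
    n_loci: int,
    sample_sizes: "list[int] | int",
    seed: "int | None" = None,
    motif_length: int = 2,
    init_repeats: int = 30,
    pop_names: "list[str] | None" = None,
) -> GenotypeTable:
    """Simulate diploid samples from a forward Wright-Fisher model.

    Every population starts monomorphic at ``init_repeats`` repeats and
    evolves for ``model.generations`` generations; ``sample_sizes``
    diploids per population are then drawn without replacement.
    """
    rng = np.random.default_rng(seed)
    P = model.n_populations
    if isinstance(sample_sizes, int):
        sample_sizes = [sample_sizes] * P
    if len(sample_sizes) != P:
        raise ValueError("one sample size per population required")

    # state: per population, array (2*Ne, L) of repeat counts (gene copies)
    pops = [np.full((2 * model.ne[p], n_loci), init_repeats, dtype=np.int64)
            for p in range(P)]

    for gen in range(model.generations):
        ne_now = model.ne_at(gen)
        new_pops = []
        for p in range(P):
            n_gametes = 2 * ne_now[p]
            # source population of each gamete
            probs = model.migration[p].copy()
            stay = 1.0 - probs.sum()
            probs[p] += stay
            sources = rng.choice(P, size=n_gametes, p=probs)
            child = np.empty((n_gametes, n_loci), dtype=np.int64)
            for q in range(P):
                mask = sources == q
                k = int(mask.sum())
                if k == 0:
                    continue
                donor = pops[q]
                # free recombination between loci: sample each locus copy
                # independently from the donor gamete pool
                idx = rng.integers(0, donor.shape[0], size=(k, n_loci))
                child[mask] = donor[idx, np.arange(n_loci)]
            new_pops.append(child)
        # mutation
        for p in range(P):
            muts = np.nonzero(rng.random(new_pops[p].shape) < model.mu)
            for i, l in zip(*muts):
                new_pops[p][i, l] = model.model.mutate(int(new_pops[p][i, l]), rng)
        pops = new_pops

    names = pop_names or [f"P{p + 1}" for p in range(P)]
    loci = [Locus(f"L{l + 1}", motif_length) for l in range(n_loci)]
    individuals: dict = {}
    calls: dict = {}
    for p, name in enumerate(names):
        n = sample_sizes[p]
        if 2 * n > pops[p].shape[0]:
            raise ValueError(
                f"sample of {n} diploids exceeds population {name} size"
            )
        picked = rng.choice(pops[p].shape[0], size=2 * n, replace=False)
        gametes = pops[p][picked]
        individuals[name] = [f"{name}_{i + 1:03d}" for i in range(n)]
        calls[name] = []
        for i in range(n):
            row = []
            for l in range(n_loci):
                a = int(gametes[2 * i, l]) * motif_length
                b = int(gametes[2 * i + 1, l]) * motif_length
                row.append((a, b) if a <= b else (b, a))
            calls[name].append(row)
    return GenotypeTable(names, individuals, loci, calls)
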