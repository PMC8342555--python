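"""Shared fixtures and synthetic-table builders."""

from __future__ import annotations

import numpy as np
import pytest

from consgen.demography.bottleneck import coalescent_sample
from consgen.synthetic_data import SMM
from consgen.types import GenotypeTable, Locus


def make_table(pop_calls: dict, motif: int = 2) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [[call, ...], ...]} rows."""
    pops = list(pop_calls)
    n_loci = len(next(iter(pop_calls.values()))[0])
    return GenotypeTable(
        populations=pops,
        individuals={p: [f"{p}_{i + 1:02d}" for i in range(len(rows))]
                     for p, rows in pop_calls.items()},
        loci=[Locus(f"L{l + 1}", motif) for l in range(n_loci)],
        calls={p: [list(r) for r in rows] for p, rows in pop_calls.items()},
    )


def coalescent_table(n_loci: int, n_ind: int, theta: float, seed: int,
                     pop: str = "A") -> GenotypeTable:
    """Single-population table drawn from the neutral SMM coalescent."""
    rng = np.random.default_rng(seed)
    model = SMM()
    calls = [[None] * n_loci for _ in range(n_ind)]
    for l in range(n_loci):
        states = coalescent_sample(2 * n_ind, theta, model, rng)
        rng.shuffle(states)
        for i in range(n_ind):
            a, b = int(states[2 * i]) * 2, int(states[2 * i + 1]) * 2
            calls[i][l] = (min(a, b), max(a, b))
    return GenotypeTable(
        [pop], {pop: [f"{pop}{i}" for i in range(n_ind)]},
        [Locus(f"L{l + 1}", 2) for l in range(n_loci)], {pop: calls},
    )


@pytest.fixture
def two_pop_table() -> GenotypeTable:
    """2 pops x 2 loci toy table with one missing call."""
    return make_table({
        "A": [
            [(100, 102), (150, 150)],
            [(100, 100), (150, 152)],
            [(102, 102), None],
        ],
        "B": [
            [(104, 106), (154, 154)],
            [(104, 104), (154, 156)],
        ],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
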