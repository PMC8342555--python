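"""Codon-alignment simulator with per-codon selection intensity.

Sequences evolve along a rooted tree under a continuous-time codon
process: single-nucleotide changes only, transitions weighted ``kappa``,
nonsynonymous changes weighted by the codon's omega, changes to stop
codons forbidden. Branch lengths are expressed in expected substitutions
per codon for a neutral (omega = 1) codon, via a global rate
normalization computed from the stationary root composition.
"""

from __future__ import annotations

import io

import numpy as np
from Bio import Phylo

from consgen.selection.alignment import CODON_TO_AA, STOP_CODONS, CodonAlignment

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
SENSE_CODONS = sorted(CODON_TO_AA)


def _neighbor_rates(codon: str, omega: float, kappa: float):
    """(target codon, rate) for every allowed single-nt change."""
    out = []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            rate = kappa if (codon[pos], base) in _TRANSITIONS else 1.0
            if CODON_TO_AA[alt] != aa:
                rate *= omega
            out.append((alt, rate))
    return out


def _neutral_mean_rate(kappa: float) -> float:
    total = 0.0
    for codon in SENSE_CODONS:
        total += sum(r for _, r in _neighbor_rates(codon, 1.0, kappa))
    return total / len(SENSE_CODONS)


def _evolve_codon(codon: str, t: float, omega: float, kappa: float,
                  scale: float, rng: np.random.Generator) -> str:
    """Gillespie simulation of one codon over scaled time t."""
    remaining = t
    while True:
        neighbors = _neighbor_rates(codon, omega, kappa)
        total = sum(r for _, r in neighbors) / scale
        if total <= 0:
            return codon
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return codon
        remaining -= wait
        rates = np.array([r for _, r in neighbors])
        pick = rng.choice(len(neighbors), p=rates / rates.sum())
        codon = neighbors[pick][0]


def star_tree(n_tips: int, depth: float, prefix: str = "seq") -> str:
    """Newick for a star tree: n tips at equal distance from the root."""
    tips = ",".join(f"{prefix}{i + 1}:{depth}" for i in range(n_tips))
    return f"({tips});"


def simulate_codon_alignment(
    tree: str,
    omega_map,
    kappa: float = 2.0,
    n_codons: "int | None" = None,
    seed: "int | None" = None,
    first_codon: int = 9,
) -> CodonAlignment:
    """Evolve an in-frame alignment along a newick tree.

    Parameters
    ----------
    tree
        Newick string (branch lengths in expected substitutions per
        codon at omega = 1).
    omega_map
        Sequence of per-codon omega values (length = number of codons),
        or a scalar applied to every codon. Codons with omega > 1 are
        recorded in the returned alignment's ``pbr_mask``.
    """
    if np.isscalar(omega_map):
        if n_codons is None:
            raise ValueError("n_codons required when omega_map is scalar")
        omegas = np.full(n_codons, float(omega_map))
    else:
        omegas = np.asarray(omega_map, dtype=float)
        if n_codons is not None and len(omegas) != n_codons:
            raise ValueError("omega_map length != n_codons")
    if (omegas < 0).any():
        raise ValueError("omega values must be >= 0")

    rng = np.random.default_rng(seed)
    phylo = Phylo.read(io.StringIO(tree), "newick")
    scale = _neutral_mean_rate(kappa)

    root_seq = [SENSE_CODONS[i]
                for i in rng.integers(0, len(SENSE_CODONS), size=len(omegas))]

    names: list = []
    seqs: list = []

    def descend(clade, codons):
        branch = clade.branch_length or 0.0
        if branch > 0:
            codons = [
                _evolve_codon(c, branch, float(w), kappa, scale, rng)
                for c, w in zip(codons, omegas)
            ]
        if clade.is_terminal():
            names.append(clade.name or f"tip{len(names) + 1}")
            seqs.append("".join(codons))
        else:
            for child in clade.clades:
                descend(child, codons)

    descend(phylo.root, root_seq)
    mask = frozenset(
        first_codon + i for i, w in enumerate(omegas) if w > 1.0
    )
    return CodonAlignment(names, seqs, first_codon=first_codon, pbr_mask=mask)
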