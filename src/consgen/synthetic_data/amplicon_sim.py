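"""Amplicon read-set simulator for MHC genotyping tests.

Generates per-individual variant counts from known allele pairs, with
per-base substitution error, single-crossover chimeras between an
individual's own two alleles, and Poisson depth variation. A raw-read
emitter adds dual indices and primers so the demultiplexer can be
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from consgen.io_formats.seqio import FastqRead
from consgen.types import AmpliconReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class AmpliconSimModel:
    """Truth model for :func:`simulate_amplicon_reads`.

    ``genotypes`` maps individual id -> tuple of 1-2 allele names from
    ``catalog`` (name -> sequence). Depth is Poisson(``mean_depth``)
    unless ``fixed_depth`` is set.
    """

    locus: str
    catalog: dict
    genotypes: dict
    mean_depth: float = 2000.0
    fixed_depth: "int | None" = None
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    index_hop_rate: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.chimera_rate, self.index_hop_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("depth must be >= 0")
        for ind, geno in self.genotypes.items():
            if not 1 <= len(geno) <= 2:
                raise ValueError(f"{ind}: genotypes carry 1-2 alleles")
            for a in geno:
                if a not in self.catalog:
                    raise KeyError(f"{ind}: allele {a!r} not in catalog")


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _chimera(a: str, b: str, rng: np.random.Generator) -> str:
    """Single-crossover recombinant of two alleles."""
    point = int(rng.integers(1, min(len(a), len(b))))
    return a[:point] + b[point:]


def simulate_amplicon_reads(
    model: AmpliconSimModel,
    seed: "int | None" = None,
) -> "dict[str, AmpliconReadSet]":
    """Simulate per-individual variant read counts.

    Returns individual id -> :class:`AmpliconReadSet`.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, AmpliconReadSet] = {}
    for ind in sorted(model.genotypes):
        geno = model.genotypes[ind]
        depth = (model.fixed_depth if model.fixed_depth is not None
                 else int(rng.poisson(model.mean_depth)))
        variants: dict[str, int] = {}
        seqs = [model.catalog[a] for a in geno]
        for _ in range(depth):
            if len(seqs) == 2 and rng.random() < model.chimera_rate:
                a, b = (seqs[0], seqs[1]) if rng.random() < 0.5 else (seqs[1], seqs[0])
                read = _chimera(a, b, rng)
            else:
                read = seqs[int(rng.integers(0, len(seqs)))]
            if model.error_rate > 0:
                read = _mutate(read, model.error_rate, rng)
            variants[read] = variants.get(read, 0) + 1
        if variants:
            out[ind] = AmpliconReadSet(ind, model.locus, variants)
    return out


def emit_raw_reads(
    model: AmpliconSimModel,
    index_table: "dict[str, tuple]",
    primers: "tuple[str, str]",
    seed: "int | None" = None,
    quality: int = 38,
) -> "list[FastqRead]":
    """Serialize simulated read sets as raw FASTQ-style reads.

    Read layout: ``index1 + forward primer + insert + reverse primer
    (reverse-complemented) + index2``. With probability
    ``model.index_hop_rate`` a read receives the index pair of a
    different random individual (index hopping).
    """
    rng = np.random.default_rng(seed)
    readsets = simulate_amplicon_reads(model, seed=seed)
    fwd, rev = primers
    # degenerate primer positions are sequenced as a concrete compatible base
    fwd = _resolve_iupac(fwd, rng)
    rev_rc = _resolve_iupac(_revcomp(rev), rng)
    inds = sorted(index_table)
    reads: list[FastqRead] = []
    counter = 0
    for ind, rs in sorted(readsets.items()):
        for seq, count in sorted(rs.variants.items()):
            for _ in range(count):
                i1, i2 = index_table[ind]
                if model.index_hop_rate > 0 and rng.random() < model.index_hop_rate:
                    other = inds[int(rng.integers(0, len(inds)))]
                    i1, i2 = index_table[other]
                full = i1 + fwd + seq + rev_rc + i2
                counter += 1
                reads.append(
                    FastqRead(f"read{counter}", full, [quality] * len(full))
                )
    return reads


_COMP = str.maketrans("ACGTRYSWKMN", "TGCAYRSWMKN")

_IUPAC = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else _IUPAC[c][int(rng.integers(0, len(_IUPAC[c])))]
        for c in seq
    )
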