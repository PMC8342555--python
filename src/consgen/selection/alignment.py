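"""In-frame codon alignments with a binding-site position mask.

Codon numbering is 1-based inclusive with a configurable offset (the
first codon of these amplicon alignments is numbered 9 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)

# Default binding-site codon numbers shared by the two DAB amplicons.
DEFAULT_PBR_POSITIONS = (
    9, 25, 27, 34, 35, 44, 53, 57, 58, 62, 65, 67, 68, 71, 75, 78, 79,
)


@dataclass
class CodonAlignment:
    """Equal-length, in-frame nucleotide sequences.

    ``first_codon`` gives the codon number of the first codon;
    ``pbr_mask`` holds codon numbers (in that numbering) flagged as
    peptide-binding positions.
    """

    names: list
    sequences: list
    first_codon: int = 9
    pbr_mask: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        length = lengths.pop()
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for name, seq in zip(self.names, self.sequences):
            for i in range(0, length, 3):
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(
                        f"sequence {name!r} has internal stop at codon "
                        f"{self.first_codon + i // 3}"
                    )
        self.pbr_mask = frozenset(int(p) for p in self.pbr_mask)
        out_of_range = self.pbr_mask - set(self.codon_numbers)
        if out_of_range:
            raise ValueError(f"mask positions outside codon range: {sorted(out_of_range)}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    @property
    def codon_numbers(self) -> list:
        return list(range(self.first_codon, self.first_codon + self.n_codons))

    def codons(self, seq_index: int) -> list:
        s = self.sequences[seq_index]
        return [s[i:i + 3] for i in range(0, len(s), 3)]

    def translate(self, seq_index: int) -> str:
        return "".join(CODON_TO_AA[c] for c in self.codons(seq_index))


def partition_alignment(
    aln: CodonAlignment,
    pbr_positions: "tuple | frozenset | None" = None,
) -> "tuple[CodonAlignment | None, CodonAlignment | None]":
    """Split into (binding-site, remainder) sub-alignments by codon number.

    Either element is ``None`` when its partition is empty. The
    sub-alignments keep contiguous renumbering from ``first_codon`` of
    the parent (positions lose their meaning after subsetting; the
    original numbers are recorded in each partition's ``pbr_mask`` for
    the binding-site piece only).
    """
    positions = frozenset(
        int(p) for p in (pbr_positions if pbr_positions is not None else aln.pbr_mask)
    )
    out_of_range = positions - set(aln.codon_numbers)
    if out_of_range:
        raise ValueError(f"mask positions outside codon range: {sorted(out_of_range)}")

    def build(keep_numbers):
        if not keep_numbers:
            return None
        idx = [n - aln.first_codon for n in sorted(keep_numbers)]
        seqs = [
            "".join(s[3 * i:3 * i + 3] for i in idx) for s in aln.sequences
        ]
        return CodonAlignment(list(aln.names), seqs, first_codon=1)

    pbr = build(positions)
    non_pbr = build(set(aln.codon_numbers) - positions)
    return pbr, non_pbr
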