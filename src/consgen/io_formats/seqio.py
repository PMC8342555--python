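"""FASTA and FASTQ (Sanger offset-33) sequence IO built on Biopython."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass
class FastqRead:
    """A single read with Sanger-encoded Phred qualities."""

    name: str
    seq: str
    quals: list  # Phred scores, one per base

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.name}: sequence/quality length mismatch")

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


def _check_alphabet(name: str, seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {name!r} contains non-ACGTN characters: {sorted(bad)}"
        )


def read_fasta(path: str | Path) -> "list[tuple[str, str]]":
    """Read FASTA into a list of ``(name, uppercase sequence)`` pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _check_alphabet(rec.id, seq)
        out.append((rec.id, seq))
    return out


def write_fasta(records: "list[tuple[str, str]]", path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> "list[FastqRead]":
    """Read Sanger FASTQ into :class:`FastqRead` objects (Phred = ord - 33)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        _check_alphabet(rec.id, seq)
        out.append(FastqRead(rec.id, seq, list(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(reads: "list[FastqRead]", path: str | Path) -> None:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.name, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")
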