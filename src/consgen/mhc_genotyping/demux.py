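"""Dual-index demultiplexing and primer trimming.

Reads are expected in the layout produced by the two-step tailed PCR:
``index1 (8 bp) + forward primer + insert + reverse-complemented
reverse primer + index2 (8 bp)``. Index matching is exact; primer
matching allows one mismatch and understands IUPAC degenerate bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from consgen.io_formats.seqio import FastqRead
from consgen.types import AmpliconReadSet

logger = logging.getLogger("consgen.mhc_genotyping")

INDEX_LENGTH = 8

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def primer_mismatches(primer: str, segment: str) -> int:
    """Mismatch count of a (possibly degenerate) primer vs a segment."""
    if len(primer) != len(segment):
        return max(len(primer), len(segment))
    return sum(s not in _IUPAC_SETS[p] for p, s in zip(primer, segment))


@dataclass
class DemuxReport:
    assigned: int = 0
    unknown_index: int = 0
    bad_primer: int = 0
    counts: dict = field(default_factory=dict)  # individual -> reads


def demultiplex_and_trim(
    reads: "list[FastqRead]",
    index_table: "dict[str, tuple]",
    primers: "tuple[str, str]",
    locus: str = "locus",
    max_primer_mismatch: int = 1,
) -> "tuple[dict[str, AmpliconReadSet], DemuxReport]":
    """Split reads by exact dual index, verify and trim primers.

    ``index_table`` maps individual id -> (index1, index2); ``primers``
    is (forward, reverse) in 5'->3' orientation on their own strands.
    Returns (individual -> read set, accounting report).
    """
    for ind, (i1, i2) in index_table.items():
        if len(i1) != INDEX_LENGTH or len(i2) != INDEX_LENGTH:
            raise ValueError(f"{ind}: indices must be {INDEX_LENGTH} bp")
    lookup = {pair: ind for ind, pair in index_table.items()}
    if len(lookup) != len(index_table):
        raise ValueError("index pairs are not unique")
    fwd, rev = primers
    rev_rc = reverse_complement(rev)

    variants: dict[str, dict] = {}
    report = DemuxReport()
    for read in reads:
        i1 = read.seq[:INDEX_LENGTH]
        i2 = read.seq[-INDEX_LENGTH:]
        ind = lookup.get((i1, i2))
        if ind is None:
            report.unknown_index += 1
            continue
        body = read.seq[INDEX_LENGTH:-INDEX_LENGTH]
        if len(body) < len(fwd) + len(rev_rc):
            report.bad_primer += 1
            continue
        if (primer_mismatches(fwd, body[:len(fwd)]) > max_primer_mismatch
                or primer_mismatches(
                    rev_rc, body[-len(rev_rc):]) > max_primer_mismatch):
            report.bad_primer += 1
            continue
        insert = body[len(fwd):-len(rev_rc)]
        variants.setdefault(ind, {})
        variants[ind][insert] = variants[ind].get(insert, 0) + 1
        report.assigned += 1
        report.counts[ind] = report.counts.get(ind, 0) + 1
    dropped = report.unknown_index + report.bad_primer
    if dropped:
        logger.info(
            "demultiplex %s: %d assigned, %d unknown index, %d bad primer",
            locus, report.assigned, report.unknown_index, report.bad_primer,
        )
    readsets = {
        ind: AmpliconReadSet(ind, locus, var) for ind, var in variants.items()
    }
    return readsets, report


def merge_paired_reads(fwd: FastqRead, rev: FastqRead, min_overlap: int = 10
                       ) -> "FastqRead | None":
    """Exact-overlap merge of a read pair (utility; vendor pipelines do
    the real merging upstream). The reverse read is given as sequenced;
    it is reverse-complemented here."""
    rc = reverse_complement(rev.seq)
    rc_quals = rev.quals[::-1]
    for overlap in range(min(len(fwd.seq), len(rc)), min_overlap - 1, -1):
        if fwd.seq[-overlap:] == rc[:overlap]:
            seq = fwd.seq + rc[overlap:]
            quals = fwd.quals + rc_quals[overlap:]
            return FastqRead(fwd.name, seq, quals)
    return None
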