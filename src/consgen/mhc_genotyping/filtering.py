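"""Read quality filtering and draft-reference locus assignment."""

from __future__ import annotations

from consgen.io_formats.seqio import FastqRead


def quality_filter(
    reads: "list[FastqRead]",
    expected_len: int,
    q_threshold: float = 30.0,
    len_tol: int = 5,
    quality_mode: str = "mean",
) -> "list[FastqRead]":
    """Drop reads with low quality, ambiguous bases or deviant length.

    A read is removed when its quality is below ``q_threshold`` (mean
    read quality by default, minimum base quality with
    ``quality_mode='min'``), when it contains any N, or when its length
    differs from ``expected_len`` by more than ``len_tol`` bp.
    """
    if quality_mode not in ("mean", "min"):
        raise ValueError("quality_mode must be 'mean' or 'min'")
    kept = []
    for read in reads:
        if abs(len(read.seq) - expected_len) > len_tol:
            continue
        if "N" in read.seq:
            continue
        q = read.mean_quality if quality_mode == "mean" else min(read.quals, default=0)
        if q < q_threshold:
            continue
        kept.append(read)
    return kept


def _identity(a: str, b: str) -> float:
    """Best gapless identity of two sequences over all end offsets."""
    if len(a) == len(b):
        if not a:
            return 0.0
        return sum(x == y for x, y in zip(a, b)) / len(a)
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        best = max(
            best,
            sum(x == y for x, y in zip(short, long_[off:off + len(short)])),
        )
    return best / len(long_)


def map_to_draft(
    reads: "list[FastqRead]",
    draft_refs: "dict[str, list]",
    min_identity: float = 0.85,
) -> "dict[str, list]":
    """Assign each read to the locus of its best-matching draft sequence.

    ``draft_refs`` maps locus name -> list of draft sequences. Reads
    whose best identity falls below ``min_identity`` are discarded.
    Returns locus -> list of reads.
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must lie in (0, 1]")
    out: dict[str, list] = {locus: [] for locus in draft_refs}
    for read in reads:
        best_locus, best_id = None, 0.0
        for locus, refs in draft_refs.items():
            for ref in refs:
                ident = _identity(read.seq, ref)
                if ident > best_id:
                    best_locus, best_id = locus, ident
        if best_locus is not None and best_id >= min_identity:
            out[best_locus].append(read)
    return out
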