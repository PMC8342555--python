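"""Sequence exports for external codon-model software."""

from __future__ import annotations

from pathlib import Path

from consgen.selection.alignment import CodonAlignment


def write_phylip(aln: CodonAlignment, path: str | Path, block: int = 60) -> None:
    """Write a PHYLIP-interleaved alignment usable as codeml input."""
    n = len(aln.sequences)
    length = len(aln.sequences[0])
    lines = [f" {n} {length}"]
    names = [name[:10].ljust(10) for name in aln.names]
    for start in range(0, length, block):
        for i in range(n):
            prefix = names[i] if start == 0 else " " * 10
            lines.append(prefix + aln.sequences[i][start:start + block])
        lines.append("")
    Path(path).write_text("\n".join(lines).rstrip() + "\n")
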