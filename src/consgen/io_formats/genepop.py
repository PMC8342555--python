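"""Genepop (.gen) genotype-table reader and writer.

Supports the diploid 2-digit (4 characters per genotype) and 3-digit
(6 characters) allele-code dialects. Missing data is an all-zero code.
Locus names may be listed one per line or comma-separated; populations
are separated by lines reading ``Pop`` (case-insensitive).
"""

from __future__ import annotations

from pathlib import Path

from consgen.types import GenotypeTable, Locus


class GenepopParseError(ValueError):
    """Raised on malformed Genepop input, naming the offending line."""


def _parse_genotype(token: str, width: int, line_no: int) -> "tuple[int, int] | None":
    if len(token) != 2 * width or not token.isdigit():
        raise GenepopParseError(
            f"line {line_no}: genotype code {token!r} does not match "
            f"{width}-digit dialect"
        )
    a, b = int(token[:width]), int(token[width:])
    if a == 0 and b == 0:
        return None
    if a == 0 or b == 0:
        # partially-missing call: treat as missing, as Genepop does for
        # haploid-coded diploid data
        return None
    return (a, b) if a <= b else (b, a)


def read_genepop(
    path: str | Path,
    motif_lengths: "dict[str, int] | None" = None,
) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        Genepop file. Allele-code width (2 vs 3 digits) is auto-detected
        from the first genotype token.
    motif_lengths
        Optional map locus name -> repeat motif length in bp (Genepop
        itself does not carry motif metadata); defaults to 2 for all loci.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be Genepop")

    # header line 1 is a free-text title; locus names follow until "Pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' separator found")
    if not locus_names:
        raise GenepopParseError("no locus names before first 'Pop'")

    motif_lengths = motif_lengths or {}
    loci = [Locus(n, motif_lengths.get(n, 2)) for n in locus_names]

    populations: list[str] = []
    individuals: dict[str, list[str]] = {}
    calls: dict[str, list] = {}
    width: int | None = None
    pop_idx = 0
    current: str | None = None

    for line_no in range(i, len(lines)):
        raw = lines[line_no]
        if not raw.strip():
            continue
        if raw.strip().lower() == "pop":
            pop_idx += 1
            current = f"pop{pop_idx}"
            populations.append(current)
            individuals[current] = []
            calls[current] = []
            continue
        if current is None:
            raise GenepopParseError(f"line {line_no + 1}: genotype row before 'Pop'")
        if "," not in raw:
            raise GenepopParseError(
                f"line {line_no + 1}: expected 'name , genotypes' row"
            )
        name, _, rest = raw.partition(",")
        tokens = rest.split()
        if width is None:
            if tokens and len(tokens[0]) in (4, 6):
                width = len(tokens[0]) // 2
            else:
                raise GenepopParseError(
                    f"line {line_no + 1}: cannot determine allele-code width from "
                    f"{tokens[0] if tokens else '<empty>'!r}"
                )
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {line_no + 1}: expected {len(loci)} genotypes, "
                f"got {len(tokens)}"
            )
        individuals[current].append(name.strip())
        calls[current].append(
            [_parse_genotype(t, width, line_no + 1) for t in tokens]
        )

    if not populations:
        raise GenepopParseError("no populations found")
    # prefer individual-name prefixes as population labels when consistent
    _relabel_from_individuals(populations, individuals, calls)
    return GenotypeTable(populations, individuals, loci, calls)


def _relabel_from_individuals(populations, individuals, calls) -> None:
    """Rename pop1..popN to the shared 'label_NNN' prefix of member ids."""
    new_names = []
    for pop in populations:
        names = individuals[pop]
        prefixes = {n.rsplit("_", 1)[0] for n in names if "_" in n}
        ok = len(prefixes) == 1 and all("_" in n for n in names) and "" not in prefixes
        new_names.append(prefixes.pop() if ok else pop)
    if len(set(new_names)) != len(new_names):
        return
    for old, new in zip(list(populations), new_names):
        if old == new:
            continue
        individuals[new] = individuals.pop(old)
        calls[new] = calls.pop(old)
        populations[populations.index(old)] = new


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    digits: int = 3,
    title: str = "consgen export",
) -> None:
    """Write a :class:`GenotypeTable` in Genepop format.

    ``digits`` selects the 2- or 3-digit allele-code dialect; allele
    sizes must fit the chosen width.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits - 1
    out = [title]
    out.extend(table.locus_names)
    for pop in table.populations:
        out.append("Pop")
        for ind, row in zip(table.individuals[pop], table.calls[pop]):
            codes = []
            for call in row:
                if call is None:
                    codes.append("0" * (2 * digits))
                else:
                    a, b = call
                    if a > limit or b > limit:
                        raise ValueError(
                            f"allele size {max(a, b)} does not fit {digits}-digit code"
                        )
                    codes.append(f"{a:0{digits}d}{b:0{digits}d}")
            out.append(f"{ind} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")
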