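"""Physicochemical z-descriptor matrices for binding-site residues.

Each allele row is the concatenation of the five z-scale values for the
amino acid at every binding-site position, in position order.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from consgen.selection.alignment import CODON_TO_AA, STOP_CODONS
from consgen.types import AlleleCatalog

Z_COLUMNS = ("z1", "z2", "z3", "z4", "z5")


def load_z_table() -> pd.DataFrame:
    """The packaged 20 x 5 z-scale table, indexed by amino acid."""
    with resources.files("consgen.data").joinpath("zscales.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col="aa")
    return df


def translate_codons(seq: str, name: str = "?") -> str:
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"{name}: stop codon at codon offset {i // 3}")
        if codon not in CODON_TO_AA:
            raise ValueError(f"{name}: unrecognized codon {codon!r}")
        aas.append(CODON_TO_AA[codon])
    return "".join(aas)


def build_descriptor_matrix(
    catalog: "AlleleCatalog | dict",
    pbr_positions,
    z_table: "pd.DataFrame | None" = None,
    first_codon: int = 9,
) -> pd.DataFrame:
    """Allele x (5 descriptors x binding positions) matrix.

    ``catalog`` is an :class:`AlleleCatalog` or a plain name->nucleotide
    mapping; positions are codon numbers in the alignment's numbering
    (first codon = ``first_codon``).
    """
    z = z_table if z_table is not None else load_z_table()
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(z.index)
    if missing or list(z.columns) != list(Z_COLUMNS):
        raise ValueError("z-table must cover 20 amino acids x z1..z5")
    alleles = catalog.alleles if isinstance(catalog, AlleleCatalog) else catalog

    rows = {}
    columns = None
    for name, seq in alleles.items():
        protein = translate_codons(seq, name)
        values = []
        cols = []
        for pos in sorted(int(p) for p in pbr_positions):
            idx = pos - first_codon
            if not (0 <= idx < len(protein)):
                raise ValueError(
                    f"binding position {pos} outside codon range "
                    f"{first_codon}..{first_codon + len(protein) - 1}"
                )
            aa = protein[idx]
            values.extend(float(v) for v in z.loc[aa, list(Z_COLUMNS)])
            cols.extend(f"{zc}_p{pos}" for zc in Z_COLUMNS)
        rows[name] = values
        columns = cols
    if not rows:
        raise ValueError("empty allele catalog")
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
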