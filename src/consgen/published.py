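"""Published reference tables shipped as package data.

``load_published_differentiation`` returns the transcribed pairwise
microsatellite differentiation estimates for the seven study
populations (F_ST above the table diagonal, R_ST below), used for
regression checks of the pairwise-matrix summary utilities.
"""

from __future__ import annotations

from importlib import resources

from consgen.io_formats.tables import read_pairwise_csv
from consgen.msat_stats.pairwise import PairwiseStatMatrix

HAN_RIVER_POPULATIONS = ("JJ", "HC", "GD", "SG", "JC")


def load_published_differentiation() -> "tuple[PairwiseStatMatrix, PairwiseStatMatrix]":
    """(F_ST, R_ST) matrices over populations DC, MH, JJ, HC, GD, SG, JC."""
    path = resources.files("consgen.data").joinpath(
        "published_pairwise_differentiation.csv")
    with resources.as_file(path) as p:
        return read_pairwise_csv(p, "F_ST", "R_ST")
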