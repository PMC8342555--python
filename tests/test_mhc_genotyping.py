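"""Read filtering, demultiplexing and the two-rule allele validation."""

from __future__ import annotations

import numpy as np
import pytest

from consgen.io_formats.seqio import FastqRead
from consgen.mhc_genotyping import (
    demultiplex_and_trim,
    map_to_draft,
    merge_paired_reads,
    primer_mismatches,
    quality_filter,
    read_accounting,
    reverse_complement,
    validate_alleles,
)
from consgen.synthetic_data import (
    AmpliconSimModel,
    emit_raw_reads,
    simulate_amplicon_reads,
)
from consgen.types import AmpliconReadSet


def read(seq, q=40, name="r"):
    return FastqRead(name, seq, [q] * len(seq))


class TestQualityFilter:
    def test_good_read_kept(self):
        assert quality_filter([read("A" * 100)], expected_len=100) != []

    def test_ambiguous_base_dropped(self):
        assert quality_filter([read("A" * 50 + "N" + "A" * 49)],
                              expected_len=100) == []

    def test_length_window_boundary(self):
        short5 = read("A" * 95)
        short6 = read("A" * 94)
        long5 = read("A" * 105)
        long6 = read("A" * 106)
        kept = quality_filter([short5, short6, long5, long6], expected_len=100)
        assert kept == [short5, long5]

    def test_mean_quality_threshold(self):
        mixed = FastqRead("m", "ACGT" * 25, [20] * 50 + [39] * 50)
        assert quality_filter([mixed], expected_len=100) == []
        ok = FastqRead("o", "ACGT" * 25, [20] * 10 + [35] * 90)
        assert quality_filter([ok], expected_len=100) == [ok]

    def test_min_mode(self):
        r = FastqRead("x", "ACGT" * 25, [29] + [40] * 99)
        assert quality_filter([r], 100, quality_mode="min") == []
        assert quality_filter([r], 100, quality_mode="mean") == [r]


class TestMapToDraft:
    drafts = {"DAB1": ["ACGT" * 25], "DAB3": ["TTGC" * 25]}

    def test_exact_copy_assigned(self):
        out = map_to_draft([read("ACGT" * 25)], self.drafts)
        assert len(out["DAB1"]) == 1 and not out["DAB3"]

    def test_one_substitution_still_assigned(self):
        seq = "CCGT" + "ACGT" * 24
        out = map_to_draft([read(seq)], self.drafts)
        assert len(out["DAB1"]) == 1

    def test_random_sequence_discarded(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        # identity to either draft ~ 0.25 << 0.85
        out = map_to_draft([read(seq)], self.drafts)
        assert not out["DAB1"] and not out["DAB3"]


class TestDemultiplex:
    fwd, rev = "GATYACA", "TTGGCCA"
    index_table = {"i1": ("AAAAAAAA", "CCCCCCCC"),
                   "i2": ("GGGGGGGG", "TTTTTTTT")}

    def _raw(self, insert, idx=("AAAAAAAA", "CCCCCCCC"), fwd=None):
        fwd = fwd or "GATTACA"  # resolves Y -> T
        return read(idx[0] + fwd + insert + reverse_complement(self.rev) + idx[1])

    def test_exact_indices_assigned_and_trimmed(self):
        insert = "ACGT" * 10
        sets, report = demultiplex_and_trim(
            [self._raw(insert)], self.index_table, (self.fwd, self.rev))
        assert report.assigned == 1
        assert sets["i1"].variants == {insert: 1}

    def test_one_mismatch_index_dropped(self):
        insert = "ACGT" * 10
        bad = self._raw(insert, idx=("AAAAAAAT", "CCCCCCCC"))
        sets, report = demultiplex_and_trim(
            [bad], self.index_table, (self.fwd, self.rev))
        assert report.unknown_index == 1 and not sets

    def test_degenerate_primer_matches(self):
        # Y matches C or T; two mismatches are rejected
        insert = "ACGT" * 10
        ok = self._raw(insert, fwd="GATCACA")
        sets, _ = demultiplex_and_trim([ok], self.index_table,
                                       (self.fwd, self.rev))
        assert sets["i1"].variants == {insert: 1}
        bad = self._raw(insert, fwd="GGTAACA")
        _, report = demultiplex_and_trim([bad], self.index_table,
                                         (self.fwd, self.rev))
        assert report.bad_primer == 1

    def test_primer_mismatch_counting(self):
        assert primer_mismatches("RYK", "ACT") == 0
        assert primer_mismatches("RYK", "CCT") == 1
        assert primer_mismatches("AAA", "TTT") == 3

    def test_merge_paired_reads_exact_overlap(self):
        left = read("AAAACCCCGGGG")
        right = read(reverse_complement("CCCCGGGGTTTT"))
        merged = merge_paired_reads(left, right, min_overlap=8)
        assert merged.seq == "AAAACCCCGGGGTTTT"


class TestValidation:
    @staticmethod
    def _rs(ind, variants):
        return AmpliconReadSet(ind, "DAB1", variants)

    def test_supported_variant_in_two_individuals(self):
        rs = {
            "P": [self._rs("a", {"AAAA": 1200, "CCCC": 9000}),
                  self._rs("b", {"AAAA": 1500, "GGGG": 7000})],
        }
        cat = validate_alleles(rs, locus="DAB1")
        assert "AAAA" in cat.alleles.values()

    def test_low_support_rejected(self):
        # 500 reads at frequency 0.05: fails both clauses of rule 1
        rs = {"P": [self._rs("a", {"AAAA": 500, "CCCC": 9500}),
                    self._rs("b", {"CCCC": 9000})]}
        cat = validate_alleles(rs, locus="DAB1")
        assert "AAAA" not in cat.alleles.values()

    def test_heterozygote_exception(self):
        # variant in exactly 1 individual at freq 0.4 alongside another
        # retained variant
        rs = {"P": [self._rs("a", {"AAAA": 4000, "CCCC": 6000}),
                    self._rs("b", {"CCCC": 9000}),
                    self._rs("c", {"CCCC": 8000})]}
        cat = validate_alleles(rs, locus="DAB1")
        assert "AAAA" in cat.alleles.values()
        assert set(cat.genotypes["a"]) == {
            name for name, seq in cat.alleles.items()}

    def test_singleton_without_partner_rejected(self):
        rs = {"P": [self._rs("a", {"AAAA": 9000}),
                    self._rs("b", {"CCCC": 9000}),
                    self._rs("c", {"CCCC": 8000})]}
        cat = validate_alleles(rs, locus="DAB1")
        assert "AAAA" not in cat.alleles.values()

    def test_and_mode_stricter(self):
        rs = {"P": [self._rs("a", {"AAAA": 1200, "CCCC": 30000}),
                    self._rs("b", {"AAAA": 1100, "CCCC": 28000})]}
        # freq of AAAA ~ 0.04: kept under OR, dropped under AND
        assert "AAAA" in validate_alleles(rs, locus="DAB1").alleles.values()
        cat_and = validate_alleles(rs, locus="DAB1", rule_combine="and")
        assert "AAAA" not in cat_and.alleles.values()

    def test_more_than_two_variants_truncated(self, caplog):
        rs = {"P": [self._rs("a", {"AAAA": 5000, "CCCC": 4000, "GGGG": 3000}),
                    self._rs("b", {"AAAA": 5000, "CCCC": 4000, "GGGG": 3000})]}
        with caplog.at_level("WARNING"):
            cat = validate_alleles(rs, locus="DAB1")
        assert len(cat.genotypes["a"]) == 2
        assert "top 2" in caplog.text

    def test_idempotent_on_validated_support(self):
        rs = {"P": [self._rs("a", {"AAAA": 5000, "CCCC": 4000}),
                    self._rs("b", {"AAAA": 5000}),
                    self._rs("c", {"CCCC": 6000})]}
        cat1 = validate_alleles(rs, locus="DAB1")
        # rebuild read sets containing only validated alleles, re-validate
        seqs = set(cat1.alleles.values())
        rs2 = {"P": [self._rs(i.individual,
                              {s: c for s, c in i.variants.items() if s in seqs})
                     for i in rs["P"]]}
        cat2 = validate_alleles(rs2, locus="DAB1")
        assert set(cat2.alleles.values()) == seqs
        assert {i: set(cat2.alleles[a] for a in g)
                for i, g in cat2.genotypes.items()} == \
               {i: set(cat1.alleles[a] for a in g)
                for i, g in cat1.genotypes.items()}

    def test_noiseless_end_to_end_identity(self, rng):
        catalog = {}
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 212))
        for i in range(5):
            s = list(base)
            for pos in rng.choice(212, 4, replace=False):
                s[pos] = "ACGT"[rng.integers(0, 4)]
            catalog[f"T{i}"] = "".join(s)
        genotypes = {
            f"ind{j}": tuple(rng.choice(list(catalog), 2, replace=False))
            for j in range(10)
        }
        model = AmpliconSimModel("DAB1", catalog, genotypes, fixed_depth=2000)
        sets = simulate_amplicon_reads(model, seed=1)
        cat = validate_alleles({"P": list(sets.values())}, locus="DAB1")
        assert set(cat.alleles.values()) == set(catalog.values())
        for ind, geno in genotypes.items():
            want = {catalog[a] for a in geno}
            got = {cat.alleles[a] for a in cat.genotypes[ind]}
            assert want == got

    def test_read_accounting_format(self):
        rs = [self._rs("a", {"A": 5000}), self._rs("b", {"A": 12000})]
        acc = read_accounting(rs)
        assert acc.mean == pytest.approx(8500)
        assert acc.min == 5000 and acc.max == 12000
        assert "±" in str(acc)


class TestRawPipeline:
    def test_demux_of_emitted_reads(self, rng):
        catalog = {"A1": "ACGT" * 20, "A2": "TGCA" * 20}
        genotypes = {"i1": ("A1", "A2"), "i2": ("A2",)}
        model = AmpliconSimModel("DAB1", catalog, genotypes, fixed_depth=100)
        index_table = {"i1": ("AAAAAAAA", "CCCCCCCC"),
                       "i2": ("GGGGGGGG", "TTTTTTTT")}
        primers = ("GATYACAR", "TTGGCCAY")
        reads = emit_raw_reads(model, index_table, primers, seed=5)
        sets, report = demultiplex_and_trim(reads, index_table, primers)
        assert report.assigned == len(reads)
        assert set(sets["i1"].variants) == set(catalog.values())
        assert set(sets["i2"].variants) == {catalog["A2"]}
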