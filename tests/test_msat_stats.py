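"""Diversity summaries, exact tests and differentiation statistics,
checked against independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from consgen.msat_stats import (
    PairwiseStatMatrix,
    bonferroni,
    brookfield1,
    fst_weir_cockerham,
    gst_value,
    hwe_exact_test,
    ibd_test,
    ld_exact_test,
    locus_summaries,
    null_allele_screen,
    pcoa_from_fst,
    rarefied_richness,
    rst_value,
    unbiased_expected_het,
    weir_cockerham_theta,
)
from consgen.synthetic_data import SimPopModel, simulate_msat
from tests.conftest import make_table

# ---------------------------------------------------------------------------
# independent oracles


def wc_theta_oracle(pop_calls_per_locus):
    """Spreadsheet-style Weir-Cockerham theta: explicit per-allele ANOVA
    components, written independently of the library implementation."""
    num = den = 0.0
    for pop_calls in pop_calls_per_locus:
        pop_calls = [c for c in pop_calls if c]
        r = len(pop_calls)
        if r < 2:
            continue
        ns = [len(c) for c in pop_calls]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for calls in pop_calls for g in calls for a in g})
        if len(alleles) < 2:
            continue
        for al in alleles:
            ps = [sum(g.count(al) for g in calls) / (2 * n)
                  for calls, n in zip(pop_calls, ns)]
            hs = [sum(1 for g in calls if (g[0] == al) != (g[1] == al)) / n
                  for calls, n in zip(pop_calls, ns)]
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def rst_oracle(sizes_per_locus):
    """Brute-force variance decomposition on gene-copy allele sizes."""
    s_a = s_w = 0.0
    for groups in sizes_per_locus:
        groups = [g for g in groups if g]
        k = len(groups)
        if k < 2:
            continue
        allv = [x for g in groups for x in g]
        n = len(allv)
        grand = sum(allv) / n
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
        msw = ssw / (n - k)
        msb = ssb / (k - 1)
        n0 = (n - sum(len(g) ** 2 for g in groups) / n) / (k - 1)
        s_a += (msb - msw) / n0
        s_w += msw
    return s_a / (s_a + s_w)


def hwe_enumeration_p(n_aa, n_ab, n_bb):
    """Full-enumeration exact HWE p for a 2-allele table (probability
    ordering), via the heterozygote-count distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def log_prob(h):
        if (n_a - h) % 2 or h > min(n_a, 2 * n - n_a):
            return None
        aa = (n_a - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0:
            return None
        return (h * math.log(2)
                + math.lgamma(n + 1)
                - math.lgamma(aa + 1) - math.lgamma(h + 1) - math.lgamma(bb + 1)
                + math.lgamma(n_a + 1) + math.lgamma(2 * n - n_a + 1)
                - math.lgamma(2 * n + 1))
    lps = {h: lp for h in range(0, n + 1)
           if (lp := log_prob(h)) is not None}
    probs = {h: math.exp(lp) for h, lp in lps.items()}
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return sum(p for p in probs.values() if p / total <= obs * (1 + 1e-9)) / total


# ---------------------------------------------------------------------------
# summaries


class TestSummaries:
    def test_unbiased_expected_het_formula(self):
        assert unbiased_expected_het({1: 5, 2: 5}) == pytest.approx(10 / 9 * 0.5)

    def test_rarefaction_brute_force(self):
        # counts {a:2, b:2}, g=2: expectation over all C(4,2) subsamples
        copies = ["a", "a", "b", "b"]
        exp = np.mean([len(set(c)) for c in itertools.combinations(copies, 2)])
        assert rarefied_richness({"a": 2, "b": 2}, 2) == pytest.approx(exp)
        assert exp == pytest.approx(5 / 3)

    def test_monomorphic_locus(self):
        table = make_table({"A": [[(100, 100)], [(100, 100)]]})
        (s,) = locus_summaries(table)
        assert (s.A, s.H_E, s.H_O) == (1, 0.0, 0.0)
        assert s.F_IS is None

    def test_rarefaction_g_too_large(self):
        table = make_table({"A": [[(100, 102)], [(100, 100)]]})
        with pytest.raises(ValueError, match="rarefaction"):
            locus_summaries(table, rarefaction_g=10)

    def test_he_unbiasedness_property(self, rng):
        # mean over resamples of the unbiased estimator ~ population 1-sum p^2
        p = np.array([0.5, 0.3, 0.2])
        target = 1 - (p**2).sum()
        vals = []
        for _ in range(1000):
            draw = rng.choice(3, size=12, p=p)
            counts = {int(a): int((draw == a).sum()) for a in np.unique(draw)}
            vals.append(unbiased_expected_het(counts))
        assert np.mean(vals) == pytest.approx(target, abs=0.01)


# ---------------------------------------------------------------------------
# HWE exact test


class TestHwe:
    def test_hwe_proportions_high_p(self):
        res = hwe_exact_test({(1, 1): 25, (1, 2): 50, (2, 2): 25},
                             batches=20, iters_per_batch=2000,
                             burn_in=2000, seed=1)
        exact = hwe_enumeration_p(25, 50, 25)
        assert abs(res.p_value - exact) <= max(3 * res.se, 0.02)

    def test_all_homozygotes_tiny_p(self):
        res = hwe_exact_test({(1, 1): 50, (2, 2): 50},
                             batches=20, iters_per_batch=2000,
                             burn_in=2000, seed=1)
        assert res.p_value < 0.001

    def test_single_genotype_p_one(self):
        res = hwe_exact_test({(1, 1): 30}, seed=1)
        assert res.p_value == 1.0

    @pytest.mark.parametrize("counts", [(3, 10, 7), (8, 2, 10), (5, 5, 5)])
    def test_mc_matches_enumeration(self, counts):
        aa, ab, bb = counts
        res = hwe_exact_test({(1, 1): aa, (1, 2): ab, (2, 2): bb},
                             batches=30, iters_per_batch=2000,
                             burn_in=3000, seed=7)
        exact = hwe_enumeration_p(aa, ab, bb)
        assert abs(res.p_value - exact) <= max(3 * res.se, 0.02)


# ---------------------------------------------------------------------------
# linkage disequilibrium


class TestLd:
    def test_monomorphic_locus_p_one(self):
        table = make_table({"A": [[(100, 100), (150, 152)],
                                  [(100, 100), (150, 150)]]})
        res = ld_exact_test(table, ("L1", "L2"), batches=5,
                            iters_per_batch=200, burn_in=100, seed=1)
        assert res.p_value == 1.0

    def test_correlated_loci_small_p(self, rng):
        rows = []
        for _ in range(40):
            g = (100, 102) if rng.random() < 0.5 else (104, 106)
            rows.append([g, (g[0] + 50, g[1] + 50)])
        table = make_table({"A": rows})
        res = ld_exact_test(table, ("L1", "L2"), batches=20,
                            iters_per_batch=1000, burn_in=2000, seed=2)
        assert res.p_value < 0.01

    def test_independent_loci_uniform_p(self):
        # KS test on p-values over replicate independent tables
        ps = []
        gen = np.random.default_rng(3)
        for rep in range(60):
            rows = []
            for _ in range(30):
                a = tuple(sorted(gen.choice([100, 102, 104], 2)))
                b = tuple(sorted(gen.choice([150, 152, 154], 2)))
                rows.append([a, b])
            table = make_table({"A": rows})
            res = ld_exact_test(table, ("L1", "L2"), batches=10,
                                iters_per_batch=500, burn_in=1000,
                                seed=100 + rep)
            ps.append(res.p_value)
        assert kstest(ps, "uniform").pvalue > 0.001


# ---------------------------------------------------------------------------
# null alleles


class TestNullAlleles:
    def test_brookfield_zero_and_formula(self):
        assert brookfield1(0.6, 0.6) == 0.0
        assert brookfield1(0.6, 0.4) == pytest.approx(0.125)

    def test_simulated_null_alleles_flagged(self):
        gen = np.random.default_rng(11)
        hits = 0
        reps = 25
        for rep in range(reps):
            # 20% null allele: null homozygotes appear as spurious homozygotes
            alleles = [100, 102, 104, 106, 0]
            p = [0.2, 0.2, 0.2, 0.2, 0.2]
            rows = []
            for _ in range(50):
                a, b = gen.choice(alleles, size=2, p=p)
                if a == 0 and b == 0:
                    continue  # total dropout: missing, skip individual
                if a == 0:
                    a = b
                if b == 0:
                    b = a
                rows.append([(min(a, b), max(a, b))])
            table = make_table({"A": rows})
            rep_out = null_allele_screen(table, "L1", sims=500,
                                         seed=200 + rep)[0]
            hits += rep_out.homozygote_excess
        assert hits / reps >= 0.8


# ---------------------------------------------------------------------------
# F-statistics


class TestFst:
    def test_fixed_difference_theta_one(self):
        table = make_table({
            "A": [[(100, 100)]] * 8,
            "B": [[(120, 120)]] * 8,
        })
        assert weir_cockerham_theta(table) == pytest.approx(1.0)

    def test_duplicated_population_theta_near_zero(self):
        m = SimPopModel(1, 200, generations=150, mu=1e-3)
        t = simulate_msat(m, 6, 100, seed=4)
        half = 50
        pop = t.populations[0]
        split = make_table({
            "A": t.calls[pop][:half],
            "B": t.calls[pop][half:],
        })
        theta = weir_cockerham_theta(split)
        assert abs(theta) < 0.02
        res = fst_weir_cockerham(split, permutations=200, seed=9)
        assert res.pairwise.p_values[0, 1] > 0.05

    def test_theta_matches_oracle_random_instances(self, rng):
        for _ in range(30):
            n_pops = rng.integers(2, 4)
            n_loci = rng.integers(1, 4)
            pop_calls = {}
            for p in range(n_pops):
                rows = []
                for _ in range(rng.integers(5, 15)):
                    row = []
                    for _ in range(n_loci):
                        a, b = rng.choice([100, 102, 104, 106], size=2)
                        row.append((min(a, b), max(a, b)))
                    rows.append(row)
                pop_calls[f"P{p}"] = rows
            table = make_table(pop_calls)
            per_locus = [
                [[tuple(r[l]) for r in pop_calls[p]] for p in pop_calls]
                for l in range(n_loci)
            ]
            try:
                expected = wc_theta_oracle(per_locus)
            except ZeroDivisionError:
                continue
            assert weir_cockerham_theta(table) == pytest.approx(expected)

    def test_theta_invariant_to_allele_relabeling(self, rng):
        m = SimPopModel(2, 80, generations=100, mu=2e-3)
        t = simulate_msat(m, 4, 20, seed=6)
        theta = weir_cockerham_theta(t)
        relabel = {}

        def remap(c):
            if c is None:
                return None
            out = []
            for a in c:
                relabel.setdefault(a, 1000 + 2 * len(relabel))
                out.append(relabel[a])
            return (min(out), max(out))

        t2 = make_table({
            p: [[remap(c) for c in row] for row in t.calls[p]]
            for p in t.populations
        })
        assert weir_cockerham_theta(t2) == pytest.approx(theta)


class TestRst:
    def test_fixed_sizes_rst_one(self):
        table = make_table({
            "A": [[(100, 100)]] * 6,
            "B": [[(120, 120)]] * 6,
        }, motif=4)
        assert rst_value(table) == pytest.approx(1.0)

    def test_rst_matches_oracle(self, rng):
        for _ in range(30):
            table_calls = {}
            sizes_per_locus = [[] for _ in range(2)]
            for p in range(2):
                rows = []
                for _ in range(rng.integers(5, 12)):
                    row = []
                    for l in range(2):
                        a, b = rng.choice([100, 104, 108, 112, 116], size=2)
                        row.append((min(a, b), max(a, b)))
                    rows.append(row)
                table_calls[f"P{p}"] = rows
                for l in range(2):
                    sizes_per_locus[l].append(
                        [x / 4 for r in rows for x in r[l]])
            table = make_table(table_calls, motif=4)
            try:
                expected = rst_oracle(sizes_per_locus)
            except ZeroDivisionError:
                continue
            assert rst_value(table) == pytest.approx(expected)

    def test_rst_invariant_to_size_shift(self):
        base = {"A": [[(100, 104)], [(108, 108)]],
                "B": [[(112, 112)], [(104, 116)]]}
        shifted = {p: [[(c[0] + 40, c[1] + 40) for c in r] for r in rows]
                   for p, rows in base.items()}
        assert rst_value(make_table(base, motif=4)) == pytest.approx(
            rst_value(make_table(shifted, motif=4)))


class TestGst:
    def test_two_pop_two_allele_hand_value(self):
        # p = (0.2, 0.8) vs (0.8, 0.2): H_S = 0.32, H_T = 0.5, G_ST = 0.36
        a_rows = [[(100, 100)]] * 1 + [[(100, 102)]] * 2 + [[(102, 102)]] * 7
        # pop A frequencies: 100 -> 4/20 = 0.2
        b_rows = [[(102, 102)]] * 1 + [[(100, 102)]] * 2 + [[(100, 100)]] * 7
        table = make_table({"A": a_rows, "B": b_rows})
        assert gst_value(table) == pytest.approx(0.36)

    def test_identical_frequencies_zero(self):
        rows = [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)]]
        table = make_table({"A": rows, "B": [list(r) for r in rows]})
        assert gst_value(table) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_one(self):
        table = make_table({"A": [[(100, 100)]] * 4, "B": [[(120, 120)]] * 4})
        assert gst_value(table) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# isolation by distance, ordination, multiple testing


class TestIbd:
    @staticmethod
    def _matrices(k=5, seed=5):
        labels = [chr(65 + i) for i in range(k)]
        gen = np.random.default_rng(seed)
        d = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        d[iu] = gen.uniform(10, 200, size=len(iu[0]))
        d += d.T
        return labels, d

    def test_perfect_linear_relation(self):
        # 7 labels so the identity permutation is rarely redrawn; ties
        # (r == 1 under a redrawn identity) still make p > 1/(perm+1)
        labels, d = self._matrices(k=7, seed=5)
        g = 0.001 * d
        res = ibd_test(PairwiseStatMatrix(labels, g, "G_ST"),
                       PairwiseStatMatrix(labels, d, "km"),
                       permutations=499, seed=2)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.001)
        assert res.mantel_p <= 0.01

    def test_three_pop_regression_closed_form(self):
        labels = ["A", "B", "C"]
        g = np.array([[0, .1, .3], [.1, 0, .2], [.3, .2, 0]])
        d = np.array([[0, 10., 30.], [10., 0, 25.], [30., 25., 0]])
        res = ibd_test(PairwiseStatMatrix(labels, g, "g"),
                       PairwiseStatMatrix(labels, d, "km"),
                       permutations=99, seed=1)
        x, y = np.array([10, 30, 25.]), np.array([.1, .3, .2])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean())

    def test_shuffled_p_roughly_uniform(self):
        labels, d = self._matrices()
        gen = np.random.default_rng(8)
        ps = []
        for rep in range(40):
            g = np.zeros_like(d)
            iu = np.triu_indices(5, 1)
            g[iu] = gen.uniform(0, 1, size=len(iu[0]))
            g += g.T
            res = ibd_test(PairwiseStatMatrix(labels, g, "g"),
                           PairwiseStatMatrix(labels, d, "km"),
                           permutations=199, seed=300 + rep)
            ps.append(res.mantel_p)
        assert kstest(ps, "uniform").pvalue > 0.001


class TestPcoa:
    def test_two_populations_single_axis(self):
        m = PairwiseStatMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]), "d")
        res = pcoa_from_fst(m)
        assert res.coordinates.shape[1] == 1
        np.testing.assert_allclose(np.abs(res.coordinates[:, 0]), 0.2,
                                   atol=1e-12)

    def test_three_equidistant_equal_eigenvalues(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        res = pcoa_from_fst(PairwiseStatMatrix(["A", "B", "C"], d, "d"))
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_matrix_reconstructed(self, rng):
        pts = rng.normal(size=(5, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa_from_fst(PairwiseStatMatrix(list("ABCDE"), d, "d"))
        np.testing.assert_allclose(res.reconstructed_distances(), d, atol=1e-8)


class TestBonferroni:
    def test_threshold_cases(self):
        mask = bonferroni([0.002] + [0.5] * 19)
        assert mask[0] and not mask[1:].any()
        assert not bonferroni([0.003] + [0.5] * 19)[0]
        assert bonferroni([0.04])[0]

    def test_pairwise_p_values_in_unit_interval(self):
        m = SimPopModel(2, 60, generations=80, mu=2e-3)
        t = simulate_msat(m, 3, 15, seed=10)
        res = fst_weir_cockerham(t, permutations=99, seed=1)
        p = res.pairwise.p_values[0, 1]
        assert 0 < p <= 1
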