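"""TSS occupancy, divergent promoters and their classification, profiles,
and the cross-cell-line overlap — including brute-force oracle agreement."""

import numpy as np
import pandas as pd
import pytest

from lncmyc import promoters as pm
from lncmyc.models import (
    BIDIR_CONCORDANT,
    BIDIR_DISCORDANT,
    BIDIR_UNREG,
    NO_TRANSCRIPTION,
    UNIDIR_REG,
    UNIDIR_UNREG,
    BidirectionalPromoter,
    GeneModel,
    Peak,
)
from lncmyc.synthetic import SimConfig, simulate_annotation, simulate_peaks

from conftest import oracle_bidirectional, oracle_nearest_peak, oracle_venn, random_genes, random_peaks


def gene(gid, strand, start, end, chrom="chr1", biotype="lncRNA"):
    return GeneModel(gid, biotype, chrom, strand, start, end)


def peak(summit, chrom="chr1", name="p"):
    return Peak(chrom, summit - 50, summit + 51, summit, 1.0, name)


class TestOccupancy:
    def test_summit_at_tss(self):
        (o,) = pm.assign_peak_occupancy([gene("g", "+", 1000, 2000)], [peak(1000)])
        assert (o.distance, o.bound) == (0, True)

    def test_window_edge_inclusive(self):
        (o,) = pm.assign_peak_occupancy([gene("g", "+", 1000, 2000)], [peak(2000)], window=1000)
        assert (o.distance, o.bound) == (1000, True)

    def test_minus_strand_sign_flip(self):
        # summit 100 bp left of a minus-strand TSS is downstream (+100)
        g = gene("g", "-", 1000, 2000)  # tss = 1999
        (o,) = pm.assign_peak_occupancy([g], [peak(1899)])
        assert o.distance == 100

    def test_peak_free_chromosome_unbound(self):
        (o,) = pm.assign_peak_occupancy([gene("g", "+", 0, 100, chrom="chrZ")], [peak(50)])
        assert (o.nearest_peak, o.distance, o.bound) == (None, None, False)

    def test_tie_breaks_toward_smaller_summit(self):
        (o,) = pm.assign_peak_occupancy(
            [gene("g", "+", 1000, 2000)], [peak(900, name="left"), peak(1100, name="right")])
        assert o.nearest_peak == "left"

    def test_matches_brute_force_oracle(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            genes = random_genes(rng, 120)
            peaks = random_peaks(rng, 80)
            expected = oracle_nearest_peak(genes, peaks, 1000)
            summit_of = {p.name: p.summit for p in peaks}
            for o in pm.assign_peak_occupancy(genes, peaks, 1000):
                want = expected[o.gene_id]
                got = (None if o.nearest_peak is None else summit_of[o.nearest_peak],
                       o.distance, o.bound)
                assert got == want, (seed, o.gene_id)


class TestBoundFraction:
    def test_zero_peaks_gives_zero(self):
        genes = [gene(f"g{i}", "+", i * 1000, i * 1000 + 100) for i in range(5)]
        occ = pm.assign_peak_occupancy(genes, [peak(5, chrom="chrZ")])
        assert pm.bound_fraction(occ, genes, "lncRNA")[2] == 0.0

    def test_all_bound_gives_one(self):
        genes = [gene(f"g{i}", "+", i * 10_000, i * 10_000 + 100) for i in range(5)]
        occ = pm.assign_peak_occupancy(genes, [peak(g.tss, name=f"p{g.gene_id}") for g in genes])
        assert pm.bound_fraction(occ, genes, "lncRNA") == (5, 5, 1.0)

    def test_monotone_in_window(self):
        rng = np.random.default_rng(1)
        genes = random_genes(rng, 100)
        peaks = random_peaks(rng, 40)
        prev = -1.0
        for w in (100, 500, 1000, 5000):
            frac = pm.bound_fraction(pm.assign_peak_occupancy(genes, peaks, w), genes, "lncRNA")[2]
            assert frac >= prev
            prev = frac

    def test_recovers_planted_bound_fraction(self):
        # 60% planted-bound lncRNAs, summit sd 150 bp truncated at 500,
        # window 1000: recovery within 2 points of the planted fraction
        cfg = SimConfig(seed=9, n_coding=0, n_lncrna=800, frac_bound_lncrna=0.6,
                        bound_boost_regulated=0.0, frac_bidirectional_pairs=0.0,
                        n_decoy_peaks=50)
        genes, truth = simulate_annotation(cfg)
        peaks = simulate_peaks(genes, truth, cfg)
        occ = pm.assign_peak_occupancy(genes, peaks, 1000)
        _, _, frac = pm.bound_fraction(occ, genes, "lncRNA")
        planted = truth.genes["myc_bound"].mean()
        assert abs(frac - planted) <= 0.02


class TestBidirectional:
    def test_divergent_pair_detected(self):
        a, b = gene("a", "-", 0, 1000), gene("b", "+", 1199, 2000)
        (p,) = pm.detect_bidirectional([a, b])
        assert (p.gene_a, p.gene_b, p.gap) == ("a", "b", 200)

    def test_convergent_genes_not_paired(self):
        assert pm.detect_bidirectional([gene("a", "+", 0, 1000), gene("b", "-", 1200, 2000)]) == []

    def test_tandem_genes_not_paired(self):
        assert pm.detect_bidirectional([gene("a", "+", 0, 1000), gene("b", "+", 1200, 2000)]) == []

    def test_gap_at_max_is_inclusive(self):
        a, b = gene("a", "-", 0, 1000), gene("b", "+", 1999, 3000)
        (p,) = pm.detect_bidirectional([a, b], max_gap=1000)
        assert p.gap == 1000

    def test_tss_inside_other_body_excluded(self):
        # b's TSS falls inside a's body
        a, b = gene("a", "-", 0, 1000), gene("b", "+", 500, 2000)
        assert pm.detect_bidirectional([a, b]) == []

    def test_each_gene_in_at_most_one_pair(self):
        genes = [gene("a", "-", 0, 1000), gene("b", "+", 1100, 2000),
                 gene("c", "+", 1400, 2400)]
        (p,) = pm.detect_bidirectional(genes)
        assert (p.gene_a, p.gene_b) == ("a", "b")  # nearest gap wins

    def test_matches_brute_force_oracle(self):
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            genes = random_genes(rng, 150, span=80_000)
            got = {(p.gene_a, p.gene_b, p.gap) for p in pm.detect_bidirectional(genes)}
            assert got == oracle_bidirectional(genes, 1000), seed


def de_table(rows):
    df = pd.DataFrame(rows, columns=["gene", "significant", "direction"]).set_index("gene")
    return df


class TestClassification:
    @pytest.fixture
    def pair(self):
        return BidirectionalPromoter("a", "b", 200)

    def classify(self, pair, expressed, de_rows, bound=()):
        occ = {g: pm.TSSOccupancy(g, 0, "p", 0, True, 1000) for g in bound}
        return pm.classify_bidirectional(pair, set(expressed), de_table(de_rows), occ)

    def test_both_up_is_concordant(self, pair):
        out = self.classify(pair, {"a", "b"}, [("a", True, "up"), ("b", True, "up")])
        assert out.category == BIDIR_CONCORDANT and out.n_expressed == 2

    def test_opposite_directions_discordant(self, pair):
        out = self.classify(pair, {"a", "b"}, [("a", True, "up"), ("b", True, "down")])
        assert out.category == BIDIR_DISCORDANT

    def test_single_responder_discordant(self, pair):
        out = self.classify(pair, {"a", "b"}, [("a", True, "up"), ("b", False, "none")])
        assert out.category == BIDIR_DISCORDANT

    def test_neither_significant_unregulated(self, pair):
        out = self.classify(pair, {"a", "b"}, [("a", False, "none"), ("b", False, "none")])
        assert out.category == BIDIR_UNREG

    def test_one_expressed_regulated(self, pair):
        out = self.classify(pair, {"a"}, [("a", True, "down")])
        assert out.category == UNIDIR_REG and out.n_expressed == 1

    def test_one_expressed_unregulated(self, pair):
        out = self.classify(pair, {"b"}, [("b", False, "none")])
        assert out.category == UNIDIR_UNREG

    def test_neither_expressed(self, pair):
        out = self.classify(pair, set(), [])
        assert out.category == NO_TRANSCRIPTION and out.n_expressed == 0

    def test_bound_if_either_tss_bound(self, pair):
        out = self.classify(pair, set(), [], bound=("b",))
        assert out.myc_bound

    def test_expressed_gene_missing_from_de_errors(self, pair):
        with pytest.raises(ValueError, match="missing"):
            self.classify(pair, {"a"}, [("b", False, "none")])

    def test_category_counts_partition_pairs(self):
        rng = np.random.default_rng(2)
        pairs = []
        for i in range(200):
            p = BidirectionalPromoter(f"a{i}", f"b{i}", 100)
            expressed = {g for g in (p.gene_a, p.gene_b) if rng.random() < 0.7}
            rows = [(g, bool(rng.random() < 0.5), str(rng.choice(["up", "down"])))
                    for g in expressed]
            rows = [(g, s, d if s else "none") for g, s, d in rows]
            pairs.append(pm.classify_bidirectional(p, expressed, de_table(rows), {}))
        counts = pm.category_counts(pairs)
        assert sum(counts.values()) == len(pairs)


class TestProfile:
    def cov(self, intervals, chrom="chr1"):
        return {chrom: np.array(intervals, dtype=float)}

    def test_uniform_coverage(self):
        prof = pm.occupancy_profile([gene("g", "+", 5000, 6000)],
                                    self.cov([(0, 100_000, 1.0)]))
        np.testing.assert_allclose(prof.loc["g"].to_numpy(), 1.0)

    def test_delta_at_tss_hits_central_bin(self):
        g = gene("g", "+", 5000, 6000)
        prof = pm.occupancy_profile([g], self.cov([(5000, 5001, 1.0)]), flank=2000, bin_width=50)
        vals = prof.loc["g"].to_numpy()
        assert vals[40] > 0 and (np.delete(vals, 40) == 0).all()

    def test_minus_strand_profile_is_mirrored(self):
        step = self.cov([(0, 5000, 2.0)])  # high upstream of position 5000
        plus = pm.occupancy_profile([gene("gp", "+", 5000, 6000)], step)
        minus = pm.occupancy_profile([gene("gm", "-", 4000, 5001)], step)  # tss 5000
        np.testing.assert_allclose(plus.loc["gp"].to_numpy(),
                                   minus.loc["gm"].to_numpy()[::-1])

    def test_missing_chromosome_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="coverage"):
            prof = pm.occupancy_profile([gene("g", "+", 5000, 6000, chrom="chrZ")],
                                        self.cov([(0, 10, 1.0)]))
        assert (prof.loc["g"].to_numpy() == 0).all()

    def test_rows_ordered_by_expression_rank(self):
        genes = [gene(f"g{i}", "+", 5000 + 10_000 * i, 6000 + 10_000 * i) for i in range(3)]
        prof = pm.occupancy_profile(genes, self.cov([(0, 100_000, 1.0)]),
                                    order_by={"g0": 1.0, "g1": 5.0, "g2": 3.0})
        assert list(prof.index) == ["g1", "g2", "g0"]


class TestOverlap:
    def test_identical_sets(self):
        t = pm.expression_overlap({"a": {"x", "y"}, "b": {"x", "y"}, "c": {"x", "y"}})
        assert t.attrs["frac_all_lines"] == 1.0
        assert t.attrs["frac_exactly_one"] == 0.0

    def test_disjoint_sets(self):
        t = pm.expression_overlap({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        assert t.attrs["frac_all_lines"] == 0.0
        assert t.attrs["frac_exactly_one"] == 1.0

    def test_single_line_rejected(self):
        with pytest.raises(ValueError, match="cell lines"):
            pm.expression_overlap({"a": {"x"}})

    def test_matches_enumeration_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            universe = [f"g{i}" for i in range(300)]
            sets = {cl: set(rng.choice(universe, 100, replace=False)) for cl in "abc"}
            table = pm.expression_overlap(sets)
            want = oracle_venn(sets)
            for _, row in table.iterrows():
                pat = (bool(row["a"]), bool(row["b"]), bool(row["c"]))
                assert row["count"] == want.get(pat, 0), seed
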