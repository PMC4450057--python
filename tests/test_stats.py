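"""KS comparisons, exon-usage test, coding impact, fractionation."""

import itertools

import numpy as np
import pytest

from cissage.stats import (
    CodingImpact,
    FractionationRecord,
    JunctionRanks,
    NonCanonicalJunctionError,
    classify_coding_impact,
    exon2_usage_exact,
    exon2_usage_simulation,
    exon_position_histogram,
    junction_combination_counts,
    ks_two_sample,
    summarize_fractionation,
)

from conftest import make_gene


def brute_force_ks_d(x, y):
    """Max |F1(t) - F2(t)| over all pooled sample points."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        d = abs(np.mean(x <= t) - np.mean(y <= t))
        best = max(best, d)
    return best


class TestKS:
    def test_identical_samples_give_zero(self):
        r = ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.D == 0.0

    def test_disjoint_samples_give_one(self):
        r = ks_two_sample([0, 0, 0], [1, 1, 1])
        assert r.D == 1.0
        assert r.p_value < 0.2  # tiny n: asymptotic p is large-ish but < 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_cdf_gap(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 12, size=rng.integers(3, 25)).astype(float)
        y = rng.normal(3, 2, size=rng.integers(3, 25))
        r = ks_two_sample(list(x), list(y))
        assert r.D == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_statistic_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        x, y = list(rng.random(11)), list(rng.random(17))
        assert ks_two_sample(x, y).D == ks_two_sample(y, x).D

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestExonUsageExact:
    def test_no_gene_reaches_target_rank(self):
        assert exon2_usage_exact([1, 1, 1], observed_k=1, target_rank=2) == 0.0

    def test_two_coin_genes(self):
        assert exon2_usage_exact([2, 2], 2) == pytest.approx(0.25)
        assert exon2_usage_exact([2, 2], 1) == pytest.approx(0.75)
        assert exon2_usage_exact([2, 2], 0) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        E = list(rng.integers(1, 6, size=8))
        k = int(rng.integers(0, 9))
        total = 0.0
        for outcome in itertools.product(*[range(1, e + 1) for e in E]):
            hits = sum(1 for o in outcome if o == 2)
            if hits >= k:
                total += 1.0 / np.prod([float(e) for e in E])
        assert exon2_usage_exact(E, k) == pytest.approx(total, abs=1e-12)

    def test_acceptor_bearing_null_excludes_first_exon(self):
        # E=[2,2] restricted to exons 2..E: rank 2 is certain for both genes
        assert exon2_usage_exact([2, 2], 2, acceptor_bearing_only=True) == pytest.approx(1.0)


class TestExonUsageSimulation:
    def test_tail_at_zero_is_one(self):
        t = exon2_usage_simulation([1, 1, 1], observed_k=0, n_sim=100, seed=0)
        assert t.p_sim == 1.0
        assert t.p_exact == 1.0

    def test_two_coin_genes_close_to_quarter(self):
        t = exon2_usage_simulation([2, 2], observed_k=2, n_sim=10_000, seed=1)
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(t.p_sim - 0.25) <= 3 * se

    def test_reproducible_under_seed(self):
        a = exon2_usage_simulation([3, 4, 5, 2], 2, n_sim=2000, seed=7)
        b = exon2_usage_simulation([3, 4, 5, 2], 2, n_sim=2000, seed=7)
        assert a.p_sim == b.p_sim

    def test_strong_rank2_bias_is_significant(self):
        # 16 multi-exon genes, 11 observed rank-2 junctions
        E = [4, 5, 6, 4, 7, 5, 4, 8, 6, 5, 4, 9, 5, 6, 4, 7]
        t = exon2_usage_simulation(E, observed_k=11, n_sim=10_000, seed=3)
        assert t.p_exact < 0.001
        assert t.p_sim < 0.001

    def test_observed_k_beyond_n_genes_rejected(self):
        with pytest.raises(ValueError):
            exon2_usage_simulation([2, 2], observed_k=3, n_sim=10, seed=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulation_converges_to_exact(self, seed):
        E = [3, 4, 2, 6, 5, 3, 4]
        k = 2
        p = exon2_usage_exact(E, k)
        t = exon2_usage_simulation(E, k, n_sim=10_000, seed=seed)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(t.p_sim - p) <= 3 * se


def coding_pair(cds5_start=50):
    g5 = make_gene(
        "A", "chr1", "+", [(0, 100), (200, 300), (400, 500)], cds=(cds5_start, 450)
    )
    g3 = make_gene("B", "chr1", "+", [(1000, 1100), (1200, 1300)], cds=(1050, 1280))
    return g5, g3


class TestCodingImpact:
    def test_out_of_frame_by_hand(self):
        g5, g3 = coding_pair(cds5_start=50)
        # 150 coding bases kept from A, 50 skipped in B: difference 100 = 1 mod 3
        impact = classify_coding_impact(g5, donor_pos=300, gene3=g3, acceptor_pos=1200)
        assert impact is CodingImpact.OUT_OF_FRAME

    def test_in_frame_when_difference_is_multiple_of_three(self):
        g5, g3 = coding_pair(cds5_start=48)  # 152 kept - 50 skipped = 102 = 0 mod 3
        impact = classify_coding_impact(g5, 300, g3, 1200)
        assert impact is CodingImpact.IN_FRAME

    def test_one_base_shift_flips_frame(self):
        in_frame = classify_coding_impact(*_pair_args(48))
        shifted = classify_coding_impact(*_pair_args(49))
        assert in_frame is CodingImpact.IN_FRAME
        assert shifted is CodingImpact.OUT_OF_FRAME

    def test_junction_upstream_of_cds_is_nr(self):
        g5 = make_gene("A", "chr1", "+", [(0, 100), (200, 300)], cds=(250, 290))
        g3 = make_gene("B", "chr1", "+", [(1000, 1100), (1200, 1300)], cds=(1050, 1280))
        # donor at first exon end (100): upstream of A's CDS
        assert classify_coding_impact(g5, 100, g3, 1200) is CodingImpact.NR

    def test_acceptor_upstream_of_3prime_cds_is_nr(self):
        g5, _ = coding_pair()
        g3 = make_gene("B", "chr1", "+", [(1000, 1100), (1200, 1300)], cds=(1250, 1280))
        assert classify_coding_impact(g5, 300, g3, 1200) is CodingImpact.NR

    def test_noncoding_parent_is_nr(self):
        g5, g3 = coding_pair()
        nc = make_gene("N", "chr1", "+", [(1000, 1100), (1200, 1300)])
        assert classify_coding_impact(g5, 300, nc, 1200) is CodingImpact.NR

    def test_minus_strand_mirror_gives_same_classes(self):
        # mirrored gene structures on the minus strand: same transcript-space
        # anatomy, so the classification must match the plus-strand case
        g5m = make_gene("Am", "chr1", "-", [(0, 100), (200, 300), (400, 500)], cds=(50, 450))
        g3m = make_gene("Bm", "chr1", "-", [(1000, 1100), (1200, 1300)], cds=(1020, 1250))
        # donor = transcription-order exon 2 of Am = genomic (200,300), boundary
        # at its genomic start; transcript-space anatomy matches the '+' case
        # (150 coding bases kept, 50 skipped -> difference 100, out of frame)
        impact = classify_coding_impact(g5m, 200, g3m, 1100)
        plus = classify_coding_impact(*_pair_args(50))
        assert impact is plus is CodingImpact.OUT_OF_FRAME

    def test_off_boundary_junction_refused(self):
        g5, g3 = coding_pair()
        with pytest.raises(NonCanonicalJunctionError):
            classify_coding_impact(g5, 299, g3, 1200)


def _pair_args(cds5_start):
    g5, g3 = coding_pair(cds5_start)
    return g5, 300, g3, 1200


class TestHistograms:
    def _junctions(self):
        return [
            JunctionRanks("a", 4, 2, 2),
            JunctionRanks("b", 3, 2, 2),
            JunctionRanks("c", 5, 1, 3),
            JunctionRanks("d", None, None, None),
        ]

    def test_single_bin_when_all_rank2(self):
        js = [JunctionRanks(str(i), 1, 2, 2) for i in range(5)]
        h = exon_position_histogram(js, "3prime")
        assert h.counts == {2: 5}

    def test_totals_conserved(self):
        h = exon_position_histogram(self._junctions(), "5prime", "backward")
        assert h.n_ranked + h.n_unranked == 4
        assert sum(h.counts.values()) == h.n_ranked == 3

    def test_top_combination_is_2_2_for_planted_sets(self):
        combos = junction_combination_counts(self._junctions())
        assert max(combos, key=combos.get) == (2, 2)

    def test_combinations_marginalize_to_histograms(self):
        js = self._junctions()
        combos = junction_combination_counts(js)
        h5b = exon_position_histogram(js, "5prime", "backward").counts
        marginal5 = {}
        for (b5, _), n in combos.items():
            marginal5[b5] = marginal5.get(b5, 0) + n
        assert marginal5 == h5b


class TestFractionation:
    def test_crosstab_and_enrichment_rule(self):
        recs = [
            FractionationRecord("f1", 2.0, 1.0),   # ratio 2 -> enriched
            FractionationRecord("f2", 1.0, 1.0),   # ratio 1 -> NOT enriched (strict >)
            FractionationRecord("f3", 0.5, 1.0),
        ]
        impacts = {
            "f1": CodingImpact.NR,
            "f2": CodingImpact.IN_FRAME,
            "f3": CodingImpact.OUT_OF_FRAME,
        }
        s = summarize_fractionation(recs, impacts)
        assert s.crosstab[CodingImpact.NR]["enriched"] == 1
        assert s.crosstab[CodingImpact.IN_FRAME]["not_enriched"] == 1
        assert s.total() == 3

    def test_zero_cytoplasmic_flagged(self):
        s = summarize_fractionation(
            [FractionationRecord("f", 1.0, 0.0)], {"f": CodingImpact.NR}
        )
        assert s.flagged == ["f"]
        assert s.crosstab[CodingImpact.NR]["enriched"] == 1
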