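"""The six-criteria cascade and its evidence checks."""

import itertools

import numpy as np
import pytest

from cissage.criteria import (
    PASS_VALUE,
    STAGES,
    CriteriaRecord,
    FilterConfig,
    GenomicTrack,
    TrackInterval,
    TriState,
    apply_criteria,
    check_ctcf_binding,
    check_immediate_neighbor,
    check_intergenic_transcript,
    check_interstitial_deletion,
    classify_induction,
    default_junction_effective_length_kb,
    fkpm_from_junction_reads,
    fusion_parental_ratio,
    rank_ratios,
)
from cissage.synth import criteria_matrix_fixture


def track(*ivs):
    return GenomicTrack([TrackInterval(*iv) for iv in ivs])


class TestNeighborCheck:
    def test_adjacent_pair_passes(self, toy_ann):
        assert check_immediate_neighbor(("G1", "G2"), toy_ann) is TriState.Y

    def test_nested_antisense_gene_fails(self, toy_ann_nested):
        assert check_immediate_neighbor(("G2", "G3"), toy_ann_nested) is TriState.N

    def test_one_gene_between_fails(self, toy_ann):
        # the TFDP1-GRK1 situation: a third gene sits between the pair
        assert check_immediate_neighbor(("G1", "G3"), toy_ann) is TriState.N

    def test_missing_gene_gives_na(self, toy_ann):
        assert check_immediate_neighbor(("G1", "MISSING"), toy_ann) is TriState.NA


class TestDeletionCheck:
    def test_loss_segment_over_interval(self):
        cnv = track(("chr1", 0, 10_000, -1.0))
        assert check_interstitial_deletion(1000, 2000, "chr1", cnv) is TriState.Y

    def test_neutral_track_passes(self):
        cnv = track(("chr1", 0, 10_000, 0.02))
        assert check_interstitial_deletion(1000, 2000, "chr1", cnv) is TriState.N

    def test_shallow_dip_below_cutoff_passes(self):
        cnv = track(("chr1", 0, 10_000, -0.1))
        assert check_interstitial_deletion(1000, 2000, "chr1", cnv) is TriState.N

    def test_uncovered_region_is_na(self):
        cnv = track(("chr2", 0, 10_000, -1.0))
        assert check_interstitial_deletion(1000, 2000, "chr1", cnv) is TriState.NA


class TestCtcfCheck:
    def test_peak_inside_gap(self):
        peaks = track(("chr1", 1400, 1600, 10.0))
        assert check_ctcf_binding(1000, 2000, "chr1", peaks) is TriState.Y

    def test_peaks_only_in_gene_bodies(self):
        peaks = track(("chr1", 100, 900, 5.0), ("chr1", 2100, 2900, 5.0))
        assert check_ctcf_binding(1000, 2000, "chr1", peaks) is TriState.N

    def test_peak_straddling_gap_edge_by_one_bp(self):
        peaks = track(("chr1", 500, 1001, 5.0))
        assert check_ctcf_binding(1000, 2000, "chr1", peaks) is TriState.Y

    def test_empty_track_na(self):
        assert check_ctcf_binding(1000, 2000, "chr1", GenomicTrack([])) is TriState.NA


class TestInduction:
    @pytest.mark.parametrize(
        "neg,kd,expected",
        [(10, 20, "induced"), (10, 5, "down"), (10, 12, "unchanged")],
    )
    def test_fold_change_categories(self, neg, kd, expected):
        assert classify_induction(neg, kd) == expected

    def test_zero_expression_handled_by_pseudocount(self):
        assert classify_induction(0.0, 1.0) == "induced"
        assert classify_induction(1.0, 0.0) == "down"

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            classify_induction(-1.0, 2.0)


class TestIntergenicTranscript:
    def test_uniform_coverage_above_threshold(self):
        cov = track(("chr1", 1000, 2000, 5.0))
        assert check_intergenic_transcript(1000, 2000, "chr1", coverage=cov) is TriState.Y

    def test_zero_coverage(self):
        cov = track(("chr1", 0, 500, 5.0))
        assert check_intergenic_transcript(1000, 2000, "chr1", coverage=cov) is TriState.N

    def test_experimental_flag_takes_precedence(self):
        cov = track(("chr1", 0, 500, 0.0))
        assert (
            check_intergenic_transcript(1000, 2000, "chr1", coverage=cov, evidence_flag=True)
            is TriState.Y
        )

    def test_no_source_is_na(self):
        assert check_intergenic_transcript(1000, 2000, "chr1") is TriState.NA


def all_pass_record(pair_id="P"):
    return CriteriaRecord(
        pair_id=pair_id,
        sanger_confirmed=TriState.Y,
        immediate_neighbor=TriState.Y,
        interstitial_deletion=TriState.N,
        ctcf_binding=TriState.Y,
        sictcf_induced=TriState.Y,
        intergenic_transcript=TriState.Y,
    )


class TestCascade:
    def test_published_matrix_counts_and_final_set(self):
        records, starred = criteria_matrix_fixture()
        report = apply_criteria(records)
        assert report.n_input == 48
        assert [report.stage_survivors[s] for s in STAGES] == [46, 38, 38, 36, 16, 16]
        assert set(report.final_pairs) == starred

    def test_all_pass_record_survives(self):
        report = apply_criteria([all_pass_record()])
        assert report.final_pairs == ["P"]
        assert report.records[0].eliminated_at is None

    def test_first_stage_failure_recorded_and_propagated(self):
        rec = all_pass_record()
        rec.sanger_confirmed = TriState.N
        report = apply_criteria([rec])
        assert rec.eliminated_at == "sanger"
        assert all(report.stage_survivors[s] == 0 for s in STAGES)

    def test_na_at_active_stage_eliminates_with_warning(self, caplog):
        rec = all_pass_record()
        rec.ctcf_binding = TriState.NA
        with caplog.at_level("WARNING"):
            report = apply_criteria([rec])
        assert rec.eliminated_at == "ctcf_binding"
        assert any("not evaluated" in m for m in caplog.messages)

    def _random_records(self, n, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            kwargs = {}
            for stage in STAGES:
                kwargs_field = {
                    "sanger": "sanger_confirmed",
                    "immediate_neighbor": "immediate_neighbor",
                    "interstitial_deletion": "interstitial_deletion",
                    "ctcf_binding": "ctcf_binding",
                    "sictcf_induced": "sictcf_induced",
                    "intergenic_transcript": "intergenic_transcript",
                }[stage]
                kwargs[kwargs_field] = rng.choice([TriState.Y, TriState.N])
            recs.append(CriteriaRecord(pair_id=f"P{i}", **kwargs))
        return recs

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_survivor_counts_monotone_nonincreasing(self, seed):
        report = apply_criteria(self._random_records(60, seed))
        counts = [report.n_input] + [report.stage_survivors[s] for s in STAGES]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_final_set_is_pure_conjunction(self, seed):
        """Stage order affects only elimination labels, never membership."""
        recs = self._random_records(60, seed)
        report = apply_criteria(recs)
        expected = {
            r.pair_id
            for r in recs
            if all(r.flag(s) is PASS_VALUE[s] for s in STAGES)
        }
        assert set(report.final_pairs) == expected


class TestExpressionBookkeeping:
    def test_zero_reads_zero_fkpm(self):
        assert fkpm_from_junction_reads(0, 0.2, 50) == 0.0

    def test_arithmetic_example(self):
        assert fkpm_from_junction_reads(10, 0.2, 50) == pytest.approx(1.0)

    def test_linearity(self):
        a = fkpm_from_junction_reads(7, 0.186, 40)
        b = fkpm_from_junction_reads(14, 0.186, 40)
        assert b == pytest.approx(2 * a)

    def test_invalid_denominators(self):
        with pytest.raises(ValueError):
            fkpm_from_junction_reads(1, 0.0, 50)

    def test_default_effective_length(self):
        assert default_junction_effective_length_kb(FilterConfig()) == pytest.approx(0.186)

    def test_ratio_boundary_flagged_at_ten_percent(self):
        r = fusion_parental_ratio(1.0, 10.0, "f")
        assert r.ratio == pytest.approx(0.10)
        assert r.significant

    def test_zero_fusion_ratio(self):
        assert fusion_parental_ratio(0.0, 5.0).ratio == 0.0

    def test_zero_parental_flagged(self):
        with pytest.raises(ValueError):
            fusion_parental_ratio(1.0, 0.0)

    def test_rank_ratios_descending(self):
        rs = [fusion_parental_ratio(v, 1.0) for v in (0.2, 0.9, 0.5)]
        assert [r.ratio for r in rank_ratios(rs)] == sorted([0.2, 0.9, 0.5], reverse=True)
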