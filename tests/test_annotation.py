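"""Annotation loading, neighbor relations, exon ranking, background stats."""

import pytest

from cissage.annotation import (
    AnnotationError,
    NoRankError,
    exon_rank,
    genome_background,
    intervening_genes,
    load_annotation,
    match_breakpoint,
    neighbor_pairs,
    write_annotation,
)
from cissage.synth import SimConfig, simulate_annotation

from conftest import make_gene
from cissage.annotation import GenomeAnnotation


class TestLoading:
    def test_round_trip_is_lossless(self, toy_ann, tmp_path):
        p = tmp_path / "ann.gtf"
        write_annotation(toy_ann, p)
        reloaded = load_annotation(p)
        assert reloaded == toy_ann

    def test_coordinates_convert_one_based_inclusive(self, toy_ann, tmp_path):
        p = tmp_path / "ann.gtf"
        write_annotation(toy_ann, p)
        first_exon_line = next(
            l for l in p.read_text().splitlines() if "\texon\t" in l and "G1" in l
        )
        fields = first_exon_line.split("\t")
        assert (int(fields[3]), int(fields[4])) == (101, 400)  # 0-based [100,400)

    def test_descending_exon_order_sorted_after_load(self, tmp_path):
        p = tmp_path / "desc.gtf"
        attrs = 'gene_id "GX"; transcript_id "GX.t1"; gene_name "GX";'
        p.write_text(
            f"chr1\tsrc\texon\t601\t1000\t.\t+\t.\t{attrs}\n"
            f"chr1\tsrc\texon\t101\t400\t.\t+\t.\t{attrs}\n"
        )
        ann = load_annotation(p)
        exons = ann.get("GX").canonical.exons
        assert [(e.start, e.end) for e in exons] == [(100, 400), (600, 1000)]

    def test_exon_outside_declared_gene_span_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        attrs = 'gene_id "GX"; transcript_id "GX.t1";'
        p.write_text(
            f"chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id \"GX\";\n"
            f"chr1\tsrc\texon\t101\t900\t.\t+\t.\t{attrs}\n"
        )
        with pytest.raises(AnnotationError):
            load_annotation(p)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        p = tmp_path / "garbled.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(AnnotationError):
            load_annotation(p)

    def test_canonical_prefers_most_exons(self):
        from cissage.annotation import Exon, GeneModel, Transcript

        t1 = Transcript("a", "+", [Exon("chr1", 0, 100)])
        t2 = Transcript("b", "+", [Exon("chr1", 0, 50), Exon("chr1", 60, 100)])
        g = GeneModel(id="G", symbol="G", chrom="chr1", strand="+", transcripts=[t1, t2])
        assert g.canonical.id == "b"


class TestNeighborPairs:
    def test_adjacent_same_strand_pairs_and_distances(self, toy_ann):
        pairs = neighbor_pairs(toy_ann, same_strand_only=True)
        chr1 = [(p.gene5.id, p.gene3.id, p.intergenic_distance) for p in pairs
                if p.gene5.chrom == "chr1"]
        assert chr1 == [("G1", "G2", 1000), ("G2", "G3", 2000)]

    def test_max_distance_filters(self, toy_ann):
        pairs = neighbor_pairs(toy_ann, max_distance=1500)
        assert [(p.gene5.id, p.gene3.id) for p in pairs if p.gene5.chrom == "chr1"] == [
            ("G1", "G2")
        ]

    def test_opposite_strand_gene_breaks_adjacency(self, toy_ann_minus_g2):
        pairs = neighbor_pairs(toy_ann_minus_g2, same_strand_only=True)
        ids = {(p.gene5.id, p.gene3.id) for p in pairs}
        assert not any("G2" in pair for pair in ids)
        assert ("G1", "G3") not in ids  # G2 intervenes even on the other strand

    def test_minus_strand_pair_orients_five_prime_downstream_in_coordinates(self):
        ann = GenomeAnnotation(
            [
                make_gene("A", "chr1", "-", [(100, 400), (600, 1000)]),
                make_gene("B", "chr1", "-", [(2000, 2400), (2600, 3000)]),
            ]
        )
        (pair,) = neighbor_pairs(ann, same_strand_only=True)
        assert (pair.gene5.id, pair.gene3.id) == ("B", "A")
        assert pair.intergenic_distance == 1000

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_adjacency_scan(self, seed):
        ann = simulate_annotation(SimConfig(n_chromosomes=2, genes_per_chromosome=25, seed=seed))
        got = {
            (p.gene5.id, p.gene3.id, p.intergenic_distance)
            for p in neighbor_pairs(ann, same_strand_only=True)
        }
        expected = set()
        for chrom, glist in ann.by_chrom.items():
            key = {g.id: (g.span_start, g.span_end, g.id) for g in glist}
            for a in glist:
                for b in glist:
                    if key[a.id] >= key[b.id]:
                        continue
                    between = any(
                        key[a.id] < key[c.id] < key[b.id] for c in glist
                    )
                    if between or a.strand != b.strand:
                        continue
                    d = max(0, b.span_start - a.span_end)
                    g5, g3 = (a, b) if a.strand == "+" else (b, a)
                    expected.add((g5.id, g3.id, d))
        assert got == expected

    def test_each_gene_in_at_most_one_pair_per_side(self, small_ann):
        pairs = neighbor_pairs(small_ann, same_strand_only=True)
        as5 = [p.gene5.id for p in pairs]
        as3 = [p.gene3.id for p in pairs]
        assert len(as5) == len(set(as5))
        assert len(as3) == len(set(as3))


class TestInterveningGenes:
    def test_pair_with_gene_between(self, toy_ann):
        assert intervening_genes(toy_ann, toy_ann.get("G1"), toy_ann.get("G3")) == ["G2"]

    def test_adjacent_pair_has_none(self, toy_ann):
        assert intervening_genes(toy_ann, toy_ann.get("G1"), toy_ann.get("G2")) == []

    def test_nested_antisense_gene_counts(self, toy_ann_nested):
        ann = toy_ann_nested
        assert intervening_genes(ann, ann.get("G2"), ann.get("G3")) == ["G4"]

    def test_different_chromosomes_rejected(self, toy_ann):
        with pytest.raises(AnnotationError):
            intervening_genes(toy_ann, toy_ann.get("G1"), toy_ann.get("H1"))


class TestExonRank:
    def test_forward_4_of_5_is_backward_2(self):
        g = make_gene("G", "chr1", "+", [(i * 100, i * 100 + 50) for i in range(1, 6)])
        t = g.canonical
        assert exon_rank(t, exon_index=3, direction="forward") == 4
        assert exon_rank(t, exon_index=3, direction="backward") == 2

    def test_minus_strand_last_genomic_exon_is_first(self):
        g = make_gene("G", "chr1", "-", [(100, 150), (200, 250), (300, 350)])
        assert exon_rank(g.canonical, exon_index=2, direction="forward") == 1

    def test_duality_holds_for_every_exon(self, small_ann):
        for gene in small_ann:
            t = gene.canonical
            for i in range(t.n_exons):
                fwd = exon_rank(t, exon_index=i, direction="forward")
                bwd = exon_rank(t, exon_index=i, direction="backward")
                assert fwd + bwd == t.n_exons + 1

    def test_rank_by_position_and_no_rank_signal(self):
        g = make_gene("G", "chr1", "+", [(100, 200), (300, 400)])
        assert exon_rank(g.canonical, position=150, direction="forward") == 1
        with pytest.raises(NoRankError):
            exon_rank(g.canonical, position=250, direction="forward")

    def test_breakpoint_matching_slack(self):
        g = make_gene("G", "chr1", "+", [(100, 200), (300, 400)])
        m = match_breakpoint(g.canonical, 200, side="donor")
        assert (m.exon_index, m.offset, m.canonical) == (0, 0, True)
        m = match_breakpoint(g.canonical, 203, side="donor", slack=5)
        assert m.canonical and m.exon_index == 0
        m = match_breakpoint(g.canonical, 250, side="donor", slack=5)
        assert not m.canonical


class TestGenomeBackground:
    def test_toy_values_hand_computed(self, toy_ann):
        bg = genome_background(toy_ann)
        assert sorted(bg.exon_counts) == [2, 2, 2, 3]
        assert sorted(bg.intergenic_distances) == [1000, 2000]
        # G1: 200; G2: 200, 100; G3: 200; H1: 200
        assert sorted(bg.intron_lengths) == [100, 200, 200, 200, 200]

    def test_single_exon_genes_contribute_no_introns(self):
        ann = GenomeAnnotation([make_gene("S", "chr1", "+", [(0, 500)])])
        bg = genome_background(ann)
        assert bg.exon_counts == [1]
        assert bg.intron_lengths == []

    def test_intron_count_identity(self, small_ann):
        bg = genome_background(small_ann)
        expected = sum(g.canonical.n_exons - 1 for g in small_ann)
        assert len(bg.intron_lengths) == expected

    def test_intergenic_list_length_matches_pair_count(self, small_ann):
        bg = genome_background(small_ann)
        assert len(bg.intergenic_distances) == len(
            neighbor_pairs(small_ann, same_strand_only=True)
        )
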