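"""End-to-end orchestration: classify -> filter -> characterize -> predict.

The stages operate on in-memory objects (``run_stages``) so tests and the
acceptance script can drive them directly; ``run_pipeline`` is the file-based
wrapper used by the CLI, reading a :class:`~cissage.io.RunConfig` and writing
a run directory stamped with the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cio
from .annotation import (
    GenomeAnnotation,
    genome_background,
    load_annotation,
    match_breakpoint,
    exon_rank,
    write_annotation,
)
from .candidates import CandidatePair, RuleConfig, enumerate_candidates
from .classify import (
    CategoryFractions,
    FusionCall,
    FusionClass,
    UniquePair,
    category_fractions,
    classify_all,
    collapse_unique_pairs,
)
from .criteria import (
    CriteriaRecord,
    FilterConfig,
    FilterReport,
    GenomicTrack,
    TriState,
    apply_criteria,
    check_ctcf_binding,
    check_immediate_neighbor,
    check_intergenic_transcript,
    check_interstitial_deletion,
    classify_induction,
)
from .stats import (
    CodingImpact,
    ExonUsageTest,
    JunctionRanks,
    KSResult,
    NonCanonicalJunctionError,
    classify_coding_impact,
    exon2_usage_simulation,
    exon_position_histogram,
    junction_combination_counts,
    ks_two_sample,
)

logger = logging.getLogger(__name__)


@dataclass
class CharacterizationResult:
    ks_intergenic: Optional[KSResult]
    ks_exon5: Optional[KSResult]
    ks_exon3: Optional[KSResult]
    ks_intron5: Optional[KSResult]
    ks_intron3: Optional[KSResult]
    junctions: list[JunctionRanks]
    hist_5_forward: dict[int, int]
    hist_5_backward: dict[int, int]
    hist_3_forward: dict[int, int]
    combinations: dict[tuple[int, int], int]
    exon_usage: Optional[ExonUsageTest]
    coding_impacts: dict[str, str]  # pair_id -> impact or "unclassified"

    def to_jsonable(self) -> dict:
        def ks(r):
            return None if r is None else {"D": r.D, "p": r.p_value, "n": r.n_sample}

        return {
            "ks_intergenic_distance": ks(self.ks_intergenic),
            "ks_exon_count_5prime": ks(self.ks_exon5),
            "ks_exon_count_3prime": ks(self.ks_exon3),
            "ks_intron_length_5prime": ks(self.ks_intron5),
            "ks_intron_length_3prime": ks(self.ks_intron3),
            "exon_rank_hist_5prime_forward": self.hist_5_forward,
            "exon_rank_hist_5prime_backward": self.hist_5_backward,
            "exon_rank_hist_3prime_forward": self.hist_3_forward,
            "junction_combinations": {f"{a}-{b}": n for (a, b), n in self.combinations.items()},
            "exon2_usage": None
            if self.exon_usage is None
            else {
                "observed_k": self.exon_usage.observed_k,
                "n_genes": len(self.exon_usage.exon_totals),
                "p_sim": self.exon_usage.p_sim,
                "p_exact": self.exon_usage.p_exact,
            },
            "coding_impacts": self.coding_impacts,
        }


@dataclass
class PipelineResult:
    calls: list[FusionCall]
    fractions: list[CategoryFractions]
    unique_pairs: list[UniquePair]
    records: list[CriteriaRecord]
    report: FilterReport
    characterization: Optional[CharacterizationResult]
    candidates: list[CandidatePair]
    seed: int

    @property
    def final_pairs(self) -> list[str]:
        return self.report.final_pairs


# ---------------------------------------------------------------------------
# criteria evaluation from evidence


def build_criteria_records(
    ann: GenomeAnnotation,
    pairs: list[UniquePair],
    calls: list[FusionCall],
    cnv: Optional[GenomicTrack],
    peaks: Optional[GenomicTrack],
    coverage: Optional[GenomicTrack],
    fusion_expression: Optional[dict[str, dict[str, float]]],
    evidence: Optional[dict[str, dict[str, bool]]],
    cfg: FilterConfig = FilterConfig(),
) -> list[CriteriaRecord]:
    """Evaluate the six criteria for each candidate (SS-0GAP) pair.

    The pair id used throughout is ``GENE5SYMBOL-GENE3SYMBOL``.  Sanger and
    intergenic-transcript wet-lab outcomes enter through ``evidence``; the
    intergenic flag takes precedence over the coverage track.
    """
    first_call: dict[tuple[str, str], FusionCall] = {}
    for c in calls:
        first_call.setdefault((c.gene5_id, c.gene3_id), c)
    evidence = evidence or {}
    records = []
    for up in pairs:
        g5 = ann.get(up.gene5_id)
        g3 = ann.get(up.gene3_id)
        pair_id = f"{g5.symbol}-{g3.symbol}"
        ev = evidence.get(pair_id, {})
        sanger = (
            (TriState.Y if ev["sanger"] else TriState.N) if "sanger" in ev else TriState.NA
        )
        neighbor = check_immediate_neighbor((up.gene5_id, up.gene3_id), ann)

        call = first_call[(up.gene5_id, up.gene3_id)]
        lo = min(call.bp5.pos, call.bp3.pos)
        hi = max(call.bp5.pos, call.bp3.pos)
        if cnv is not None and hi > lo:
            deletion = check_interstitial_deletion(lo, hi, g5.chrom, cnv, cfg)
        else:
            deletion = TriState.NA

        left, right = sorted((g5, g3), key=lambda g: g.span_start)
        gap = (left.span_end, max(left.span_end, right.span_start))
        ctcf = (
            check_ctcf_binding(gap[0], gap[1], g5.chrom, peaks, cfg)
            if peaks is not None
            else TriState.NA
        )

        if fusion_expression is not None and pair_id in fusion_expression:
            cond = fusion_expression[pair_id]
            if "si_neg" in cond and "siCTCF" in cond:
                verdict = classify_induction(cond["si_neg"], cond["siCTCF"], cfg)
                induced = TriState.Y if verdict == "induced" else TriState.N
            else:
                induced = TriState.NA
        else:
            induced = TriState.NA

        intergenic = check_intergenic_transcript(
            gap[0],
            gap[1],
            g5.chrom,
            coverage=coverage,
            evidence_flag=ev.get("intergenic"),
            cfg=cfg,
        )
        records.append(
            CriteriaRecord(
                pair_id=pair_id,
                sanger_confirmed=sanger,
                immediate_neighbor=neighbor,
                interstitial_deletion=deletion,
                ctcf_binding=ctcf,
                sictcf_induced=induced,
                intergenic_transcript=intergenic,
            )
        )
    return records


# ---------------------------------------------------------------------------
# characterization


def characterize_survivors(
    ann: GenomeAnnotation,
    survivors: list[UniquePair],
    calls: list[FusionCall],
    n_sim: int = 10_000,
    seed: int = 0,
    slack: int = 5,
) -> CharacterizationResult:
    """Junction-anatomy and background statistics for the surviving pairs."""
    background = genome_background(ann)
    first_call: dict[tuple[str, str], FusionCall] = {}
    for c in calls:
        first_call.setdefault((c.gene5_id, c.gene3_id), c)

    junctions: list[JunctionRanks] = []
    distances: list[float] = []
    exon5: list[float] = []
    exon3: list[float] = []
    intron5: list[float] = []
    intron3: list[float] = []
    impacts: dict[str, str] = {}
    for up in survivors:
        g5, g3 = ann.get(up.gene5_id), ann.get(up.gene3_id)
        t5, t3 = g5.canonical, g3.canonical
        pair_id = f"{g5.symbol}-{g3.symbol}"
        call = first_call[(up.gene5_id, up.gene3_id)]

        left, right = sorted((g5, g3), key=lambda g: g.span_start)
        distances.append(max(0, right.span_start - left.span_end))
        exon5.append(t5.n_exons)
        exon3.append(t3.n_exons)

        m5 = match_breakpoint(t5, call.bp5.pos, side="donor", slack=slack)
        m3 = match_breakpoint(t3, call.bp3.pos, side="acceptor", slack=slack)
        if m5.canonical and m3.canonical:
            r5f = exon_rank(t5, exon_index=m5.exon_index, direction="forward")
            r5b = exon_rank(t5, exon_index=m5.exon_index, direction="backward")
            r3f = exon_rank(t3, exon_index=m3.exon_index, direction="forward")
            junctions.append(JunctionRanks(pair_id, r5f, r5b, r3f))
            donor_introns = t5.intron_lengths()
            # intron following the donor exon in transcription order
            di = m5.exon_index if t5.strand == "+" else m5.exon_index - 1
            if 0 <= di < len(donor_introns):
                intron5.append(donor_introns[di])
            acc_introns = t3.intron_lengths()
            ai = m3.exon_index - 1 if t3.strand == "+" else m3.exon_index
            if 0 <= ai < len(acc_introns):
                intron3.append(acc_introns[ai])
        else:
            logger.warning("pair %s: non-canonical junction, excluded from ranks", pair_id)
            junctions.append(JunctionRanks(pair_id, None, None, None))

        try:
            impacts[pair_id] = classify_coding_impact(
                g5, call.bp5.pos, g3, call.bp3.pos
            ).value
        except NonCanonicalJunctionError:
            impacts[pair_id] = "unclassified"

    def _ks(sample, bg):
        return ks_two_sample(sample, bg) if sample and bg else None

    ranked = [j for j in junctions if j.rank3_forward is not None]
    exon_usage = None
    if ranked:
        totals = [ann.get(up.gene3_id).canonical.n_exons for up in survivors]
        observed_k = sum(1 for j in ranked if j.rank3_forward == 2)
        exon_usage = exon2_usage_simulation(
            totals, observed_k, target_rank=2, n_sim=n_sim, seed=seed
        )

    return CharacterizationResult(
        ks_intergenic=_ks(distances, background.intergenic_distances),
        ks_exon5=_ks(exon5, background.exon_counts),
        ks_exon3=_ks(exon3, background.exon_counts),
        ks_intron5=_ks(intron5, background.intron_lengths),
        ks_intron3=_ks(intron3, background.intron_lengths),
        junctions=junctions,
        hist_5_forward=exon_position_histogram(junctions, "5prime", "forward").counts,
        hist_5_backward=exon_position_histogram(junctions, "5prime", "backward").counts,
        hist_3_forward=exon_position_histogram(junctions, "3prime", "forward").counts,
        combinations=junction_combination_counts(junctions),
        exon_usage=exon_usage,
        coding_impacts=impacts,
    )


# ---------------------------------------------------------------------------
# stage driver


def run_stages(
    ann: GenomeAnnotation,
    calls: list[FusionCall],
    cnv: Optional[GenomicTrack] = None,
    peaks: Optional[GenomicTrack] = None,
    coverage: Optional[GenomicTrack] = None,
    fusion_expression: Optional[dict[str, dict[str, float]]] = None,
    gene_expression: Optional[dict[str, float]] = None,
    evidence: Optional[dict[str, dict[str, bool]]] = None,
    filter_cfg: FilterConfig = FilterConfig(),
    rule_cfg: RuleConfig = RuleConfig(),
    n_sim: int = 10_000,
    seed: int = 0,
    characterize: bool = True,
) -> PipelineResult:
    """Classify calls, filter SS-0GAP candidates through the cascade,
    characterize the survivors and predict genome-wide candidates."""
    classify_all(calls, ann)
    fractions = category_fractions(calls, by_sample=True)
    unique = collapse_unique_pairs(calls)
    ss0gap = [u for u in unique if u.fusion_class is FusionClass.INTRACHR_SS_0GAP]
    records = build_criteria_records(
        ann, ss0gap, calls, cnv, peaks, coverage, fusion_expression, evidence, filter_cfg
    )
    report = apply_criteria(records)
    final_ids = set(report.final_pairs)
    survivors = [
        u
        for u in ss0gap
        if f"{ann.get(u.gene5_id).symbol}-{ann.get(u.gene3_id).symbol}" in final_ids
    ]
    char = (
        characterize_survivors(
            ann, survivors, calls, n_sim=n_sim, seed=seed, slack=filter_cfg.breakpoint_slack
        )
        if characterize and survivors
        else None
    )
    cands = enumerate_candidates(ann, gene_expression or {}, rule_cfg)
    return PipelineResult(
        calls=calls,
        fractions=fractions,
        unique_pairs=unique,
        records=records,
        report=report,
        characterization=char,
        candidates=cands,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file-based wrapper


def run_pipeline(cfg: cio.RunConfig) -> PipelineResult:
    """Execute all stages from a run configuration and write the run
    directory.  Missing inputs raise :class:`cissage.io.InputError` naming
    the file before any stage runs."""
    for p in cfg.required_paths():
        if not Path(p).exists():
            raise cio.InputError(f"missing input file: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.criteria_matrix:
        # matrix mode: the criteria are precomputed, only the cascade runs
        records = cio.read_criteria_matrix(cfg.criteria_matrix)
        report = apply_criteria(records)
        result = PipelineResult(
            calls=[],
            fractions=[],
            unique_pairs=[],
            records=records,
            report=report,
            characterization=None,
            candidates=[],
            seed=cfg.seed,
        )
        _write_outputs(result, cfg, outdir)
        return result

    ann = load_annotation(cfg.annotation)
    calls = cio.read_fusion_tsv(cfg.fusions)
    result = run_stages(
        ann,
        calls,
        cnv=cio.read_bed_track(cfg.cnv) if cfg.cnv else None,
        peaks=cio.read_bed_track(cfg.peaks) if cfg.peaks else None,
        coverage=cio.read_bedgraph(cfg.coverage) if cfg.coverage else None,
        fusion_expression=cio.read_condition_expression_tsv(cfg.fusion_expression)
        if cfg.fusion_expression
        else None,
        gene_expression=cio.read_gene_expression_tsv(cfg.gene_expression)
        if cfg.gene_expression
        else None,
        evidence=cio.read_evidence_tsv(cfg.evidence) if cfg.evidence else None,
        filter_cfg=cfg.filter,
        rule_cfg=cfg.rules,
        n_sim=cfg.n_sim,
        seed=cfg.seed,
    )
    _write_outputs(result, cfg, outdir)
    return result


def _write_outputs(result: PipelineResult, cfg: cio.RunConfig, outdir: Path) -> None:
    if result.calls:
        cio.write_fusion_tsv(result.calls, outdir / "classification.tsv")
    cio.write_filter_report(result.report, outdir / "criteria_report.tsv")
    (outdir / "stage_summary.txt").write_text(result.report.summary() + "\n")
    if result.characterization is not None:
        with open(outdir / "characterization.json", "w") as fh:
            json.dump(result.characterization.to_jsonable(), fh, indent=2)
    if result.candidates:
        write_candidates_tsv(result.candidates, outdir / "candidates.tsv")
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_calls": len(result.calls),
        "n_candidate_pairs": len(result.records),
        "stage_survivors": result.report.stage_survivors,
        "final_pairs": result.report.final_pairs,
        "n_predicted_candidates": len(result.candidates),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def write_candidates_tsv(cands: list[CandidatePair], path: str | Path) -> None:
    rows = []
    for c in cands:
        j = c.junction
        rows.append(
            {
                "pair_id": c.pair_id,
                "chrom": c.pair.gene5.chrom,
                "strand": c.pair.gene5.strand,
                "distance": c.pair.intergenic_distance,
                "fpkm5": c.fpkm5,
                "donor_exon_start": j.donor_exon.start if j else "",
                "donor_exon_end": j.donor_exon.end if j else "",
                "acceptor_exon_start": j.acceptor_exon.start if j else "",
                "acceptor_exon_end": j.acceptor_exon.end if j else "",
                "junction_donor": j.donor_boundary if j else "",
                "junction_acceptor": j.acceptor_boundary if j else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation run directories


def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Materialize a :class:`~cissage.synth.SimulatedCohort` as the file set a
    real run would consume; returns the path map (also usable as RunConfig
    fields)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "fusions": outdir / "fusions.tsv",
        "cnv": outdir / "cnv.bed",
        "peaks": outdir / "ctcf_peaks.bed",
        "coverage": outdir / "intergenic_coverage.bedgraph",
        "fusion_expression": outdir / "fusion_expression.tsv",
        "gene_expression": outdir / "gene_fpkm.tsv",
        "evidence": outdir / "evidence.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_annotation(cohort.annotation, paths["annotation"])
    cio.write_fusion_tsv(cohort.calls, paths["fusions"])
    cio.write_bed_track(cohort.tracks.cnv, paths["cnv"])
    cio.write_bed_track(cohort.tracks.peaks, paths["peaks"])
    cio.write_bed_track(cohort.tracks.coverage, paths["coverage"])
    cio.write_condition_expression_tsv(
        cohort.tracks.fusion_expression, paths["fusion_expression"]
    )
    cio.write_gene_expression_tsv(cohort.tracks.gene_fpkm, paths["gene_expression"])
    cio.write_evidence_tsv(cohort.evidence(), paths["evidence"])
    pd.DataFrame(
        [
            {
                "pair_id": ev.pair_id,
                "event_type": ev.event_type,
                "gene5": ev.gene5_id,
                "gene3": ev.gene3_id,
                "rank5_backward": ev.rank5_backward if ev.rank5_backward is not None else "",
                "rank3_forward": ev.rank3_forward if ev.rank3_forward is not None else "",
                "expected_class": ev.expected_class,
                "expected_eliminated_at": ev.expected_eliminated_at or "",
            }
            for ev in cohort.truth.events
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
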