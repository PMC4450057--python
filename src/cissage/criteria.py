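"""The six-criteria cascade separating true read-through (cis-SAGe) fusions
from look-alikes.

A same-strand adjacent-gene fusion RNA can arise from (a) genuine cis-splicing
of a read-through precursor, (b) an interstitial DNA deletion joining the loci,
or (c) trans-splicing between separate transcripts.  The cascade eliminates
(b) and (c) using orthogonal evidence, in this fixed order:

1. ``sanger``                 — junction confirmed by Sanger sequencing (Y passes);
2. ``immediate_neighbor``     — no other gene between the parents (Y passes);
3. ``interstitial_deletion``  — copy-number loss between the fused exons
   (N passes: *absence* of a deletion is the supporting evidence);
4. ``ctcf_binding``           — >= 1 CTCF peak in the intergenic gap (Y passes);
5. ``sictcf_induced``         — fusion induced >= 1.5-fold by CTCF knockdown
   (Y passes; insulator loss should de-repress read-through);
6. ``intergenic_transcript``  — RNA detected across the gap (Y passes).

A pair surviving all six stages is called a cis-SAGe event.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class TriState(str, Enum):
    Y = "Y"
    N = "N"
    NA = "NA"


STAGES: tuple[str, ...] = (
    "sanger",
    "immediate_neighbor",
    "interstitial_deletion",
    "ctcf_binding",
    "sictcf_induced",
    "intergenic_transcript",
)

#: the flag value that lets a pair through each stage (deletion polarity is
#: inverted: "N" = no deletion = pass)
PASS_VALUE: dict[str, TriState] = {s: TriState.Y for s in STAGES}
PASS_VALUE["interstitial_deletion"] = TriState.N

_FIELD = {
    "sanger": "sanger_confirmed",
    "immediate_neighbor": "immediate_neighbor",
    "interstitial_deletion": "interstitial_deletion",
    "ctcf_binding": "ctcf_binding",
    "sictcf_induced": "sictcf_induced",
    "intergenic_transcript": "intergenic_transcript",
}


@dataclass
class CriteriaRecord:
    pair_id: str
    sanger_confirmed: TriState = TriState.NA
    immediate_neighbor: TriState = TriState.NA
    interstitial_deletion: TriState = TriState.NA
    ctcf_binding: TriState = TriState.NA
    sictcf_induced: TriState = TriState.NA
    intergenic_transcript: TriState = TriState.NA
    eliminated_at: Optional[str] = None

    def flag(self, stage: str) -> TriState:
        return getattr(self, _FIELD[stage])


@dataclass
class FilterConfig:
    fc_threshold: float = 1.5
    deletion_log2_cutoff: float = -0.3
    min_peak_overlap_bp: int = 1
    min_intergenic_mean_coverage: float = 1.0
    pseudocount: float = 0.01
    read_length: int = 101
    min_anchor: int = 8
    breakpoint_slack: int = 5

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")


# ---------------------------------------------------------------------------
# genomic tracks


@dataclass(frozen=True)
class TrackInterval:
    chrom: str
    start: int
    end: int
    value: float = 0.0


class GenomicTrack:
    """Generic interval track (CNV segments, peaks, coverage)."""

    def __init__(self, intervals: Sequence[TrackInterval]):
        self.intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            if iv.end <= iv.start:
                raise ValueError(f"track interval with end <= start: {iv}")
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.value)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TrackInterval]:
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        return sorted(
            (TrackInterval(chrom, iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)),
            key=lambda iv: (iv.start, iv.end),
        )

    def mean_value(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over the interval; uncovered bases count 0."""
        if end <= start:
            raise ValueError("empty interval")
        total = 0.0
        for iv in self.overlapping(chrom, start, end):
            total += (min(iv.end, end) - max(iv.start, start)) * iv.value
        return total / (end - start)


# ---------------------------------------------------------------------------
# individual criteria


def check_immediate_neighbor(pair, ann) -> TriState:
    """Y iff no other gene overlaps the interval between the pair's genes."""
    from .annotation import intervening_genes

    try:
        g5 = ann.get(pair.gene5.id) if hasattr(pair, "gene5") else ann.get(pair[0])
        g3 = ann.get(pair.gene3.id) if hasattr(pair, "gene3") else ann.get(pair[1])
    except KeyError as exc:
        logger.warning("immediate-neighbor check: %s", exc)
        return TriState.NA
    return TriState.Y if not intervening_genes(ann, g5, g3) else TriState.N


def check_interstitial_deletion(
    fused_exon5_end: int,
    fused_exon3_start: int,
    chrom: str,
    cnv: GenomicTrack,
    cfg: FilterConfig = FilterConfig(),
) -> TriState:
    """Y iff a copy-number *loss* segment overlaps the region between the
    fused exons (Y means the pair FAILS the cascade stage)."""
    if not fused_exon5_end < fused_exon3_start:
        raise ValueError("fused_exon5_end must be < fused_exon3_start")
    hits = cnv.overlapping(chrom, fused_exon5_end, fused_exon3_start)
    if not hits:
        return TriState.NA
    for iv in hits:
        if iv.value <= cfg.deletion_log2_cutoff:
            ov = min(iv.end, fused_exon3_start) - max(iv.start, fused_exon5_end)
            if ov >= cfg.min_peak_overlap_bp:
                return TriState.Y
    return TriState.N


def check_ctcf_binding(
    gap_start: int,
    gap_end: int,
    chrom: str,
    peaks: GenomicTrack,
    cfg: FilterConfig = FilterConfig(),
) -> TriState:
    """Y iff at least one peak overlaps the intergenic gap by >= the
    configured minimum."""
    if len(peaks) == 0:
        logger.warning("CTCF check: empty peak track")
        return TriState.NA
    if gap_end <= gap_start:
        return TriState.N
    for iv in peaks.overlapping(chrom, gap_start, gap_end):
        if min(iv.end, gap_end) - max(iv.start, gap_start) >= cfg.min_peak_overlap_bp:
            return TriState.Y
    return TriState.N


def classify_induction(
    value_neg: float, value_kd: float, cfg: FilterConfig = FilterConfig()
) -> str:
    """Knockdown response category from normalized expression in control
    (``si-``) vs CTCF-silenced (``siCTCF``) cells."""
    if value_neg < 0 or value_kd < 0:
        raise ValueError("expression values must be >= 0")
    fc = (value_kd + cfg.pseudocount) / (value_neg + cfg.pseudocount)
    if fc >= cfg.fc_threshold:
        return "induced"
    if fc <= 1.0 / cfg.fc_threshold:
        return "down"
    return "unchanged"


def check_intergenic_transcript(
    gap_start: int,
    gap_end: int,
    chrom: str,
    coverage: Optional[GenomicTrack] = None,
    evidence_flag: Optional[bool] = None,
    cfg: FilterConfig = FilterConfig(),
) -> TriState:
    """Y iff intergenic RNA is supported, either by an experimental flag
    (RT-PCR; takes precedence) or by mean coverage >= the threshold."""
    if evidence_flag is not None:
        return TriState.Y if evidence_flag else TriState.N
    if coverage is None:
        return TriState.NA
    if gap_end <= gap_start:
        return TriState.N
    mean = coverage.mean_value(chrom, gap_start, gap_end)
    return TriState.Y if mean >= cfg.min_intergenic_mean_coverage else TriState.N


# ---------------------------------------------------------------------------
# the cascade


@dataclass
class FilterReport:
    n_input: int
    stage_survivors: dict[str, int]
    final_pairs: list[str]
    records: list[CriteriaRecord]

    def summary(self) -> str:
        lines = [f"input pairs: {self.n_input}"]
        for s in STAGES:
            lines.append(f"after {s}: {self.stage_survivors[s]}")
        lines.append(f"final cis-SAGe set ({len(self.final_pairs)}): " + ", ".join(self.final_pairs))
        return "\n".join(lines)


def apply_criteria(records: list[CriteriaRecord]) -> FilterReport:
    """Run the cascade over Table-1-style records.

    A pair survives a stage iff its flag equals that stage's passing value;
    ``eliminated_at`` records the first failing stage.  An NA flag at a stage
    the pair reached is treated as a failure (conservative) with a warning.
    """
    survivors = list(records)
    stage_counts: dict[str, int] = {}
    for rec in records:
        rec.eliminated_at = None
    for stage in STAGES:
        nxt = []
        for rec in survivors:
            flag = rec.flag(stage)
            if flag is TriState.NA:
                logger.warning(
                    "pair %s: criterion %s not evaluated; treated as failure", rec.pair_id, stage
                )
            if flag is PASS_VALUE[stage]:
                nxt.append(rec)
            else:
                rec.eliminated_at = stage
        survivors = nxt
        stage_counts[stage] = len(survivors)
    return FilterReport(
        n_input=len(records),
        stage_survivors=stage_counts,
        final_pairs=[r.pair_id for r in survivors],
        records=records,
    )


# ---------------------------------------------------------------------------
# expression bookkeeping


def fkpm_from_junction_reads(
    junction_reads: int, effective_length_kb: float, total_fragments_millions: float
) -> float:
    """Convert fusion junction-read counts to FPKM-scale expression, using the
    junction's effective (mappable) length."""
    if effective_length_kb <= 0 or total_fragments_millions <= 0:
        raise ValueError("effective length and library size must be positive")
    return junction_reads / (effective_length_kb * total_fragments_millions)


def default_junction_effective_length_kb(cfg: FilterConfig = FilterConfig()) -> float:
    """Mappable junction span: a fragment must anchor >= ``min_anchor`` bases
    on each side, leaving 2*(read_length - min_anchor) placeable positions."""
    return 2 * (cfg.read_length - cfg.min_anchor) / 1000.0


@dataclass
class ExpressionRatio:
    feature_id: str
    ratio: float
    significant: bool  # fusion contributes >= 10% of parental expression


def fusion_parental_ratio(
    fusion_fkpm: float, parental_fkpm: float, feature_id: str = ""
) -> ExpressionRatio:
    if parental_fkpm <= 0:
        raise ValueError(f"{feature_id}: parental FPKM must be > 0 for a ratio")
    r = fusion_fkpm / parental_fkpm
    return ExpressionRatio(feature_id, r, r >= 0.10)


def rank_ratios(ratios: list[ExpressionRatio]) -> list[ExpressionRatio]:
    """Highest-to-lowest ordering, as the expression-contribution plot uses."""
    return sorted(ratios, key=lambda x: -x.ratio)
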