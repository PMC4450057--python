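"""Taxonomy of chimeric-RNA calls.

Fusion calls (e.g. SOAPfuse rows) are classified into three mutually
exclusive classes by the genomic relation of their parental genes:

* ``INTERCHR``          — parental genes on different chromosomes;
* ``INTRACHR_SS_0GAP``  — same chromosome, same strand, immediate neighbors
  (zero genes in between), with the call's 5' gene transcriptionally
  upstream: the read-through / cis-SAGe candidate class;
* ``INTRACHR_OTHER``    — everything else on one chromosome.

A same-strand adjacent pair reported in reverse transcriptional order is
classed ``INTRACHR_OTHER`` and annotated ``reversed-order``: a read-through
precursor can only be spliced in transcription direction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from scipy import stats

from .annotation import GenomeAnnotation, intervening_genes


class FusionClass(str, Enum):
    INTERCHR = "INTERCHR"
    INTRACHR_SS_0GAP = "INTRACHR_SS_0GAP"
    INTRACHR_OTHER = "INTRACHR_OTHER"


class ClassificationError(Exception):
    pass


class SelfFusionError(ClassificationError):
    pass


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"breakpoint position must be >= 0, got {self.pos}")


@dataclass
class FusionCall:
    sample_id: str
    gene5_id: str
    gene3_id: str
    bp5: Breakpoint
    bp3: Breakpoint
    junction_reads: int = 0
    spanning_reads: int = 0
    fusion_class: Optional[FusionClass] = None
    note: str = ""

    @property
    def pair_id(self) -> str:
        return f"{self.gene5_id}-{self.gene3_id}"


@dataclass
class CategoryFractions:
    sample_id: str
    counts: dict[FusionClass, int]
    total_calls: int

    @property
    def fractions(self) -> dict[FusionClass, float]:
        if self.total_calls == 0:
            raise ClassificationError(f"sample {self.sample_id}: no calls, fractions undefined")
        return {c: self.counts.get(c, 0) / self.total_calls for c in FusionClass}


def classify_fusion(call: FusionCall, ann: GenomeAnnotation) -> FusionClass:
    """Assign the call's taxonomy class (also stored on ``call.fusion_class``)."""
    if call.gene5_id == call.gene3_id:
        raise SelfFusionError(f"self-fusion rejected: {call.gene5_id}")
    g5 = ann.get(call.gene5_id)
    g3 = ann.get(call.gene3_id)
    if g5.chrom != g3.chrom:
        cls = FusionClass.INTERCHR
    elif g5.strand != g3.strand:
        cls = FusionClass.INTRACHR_OTHER
        call.note = "different-strand"
    elif intervening_genes(ann, g5, g3):
        cls = FusionClass.INTRACHR_OTHER
        call.note = "intervening-genes"
    else:
        # strand-aware order: the call's 5' gene must be upstream in
        # transcription direction
        upstream_first = (
            g5.span_start <= g3.span_start if g5.strand == "+" else g5.span_start >= g3.span_start
        )
        if upstream_first:
            cls = FusionClass.INTRACHR_SS_0GAP
        else:
            cls = FusionClass.INTRACHR_OTHER
            call.note = "reversed-order"
    call.fusion_class = cls
    return cls


def classify_all(calls: list[FusionCall], ann: GenomeAnnotation) -> list[FusionCall]:
    for c in calls:
        classify_fusion(c, ann)
    return calls


def category_fractions(
    calls: list[FusionCall], by_sample: bool = True, unique_pairs: bool = False
) -> list[CategoryFractions]:
    """Per-sample class counts and fractions.

    ``unique_pairs=True`` counts each ordered parental gene pair once per
    sample instead of counting every junction isoform as an event.
    """
    for c in calls:
        if c.fusion_class is None:
            raise ClassificationError(f"call {c.pair_id} not classified")
    groups: dict[str, list[FusionCall]] = {}
    for c in calls:
        key = c.sample_id if by_sample else "all"
        groups.setdefault(key, []).append(c)
    out = []
    for sid in sorted(groups):
        grp = groups[sid]
        if unique_pairs:
            seen: dict[tuple[str, str], FusionClass] = {}
            for c in grp:
                seen.setdefault((c.gene5_id, c.gene3_id), c.fusion_class)
            counts = Counter(seen.values())
        else:
            counts = Counter(c.fusion_class for c in grp)
        out.append(CategoryFractions(sid, dict(counts), sum(counts.values())))
    return out


def paired_fraction_correlation(tumor: list[float], normal: list[float]) -> float:
    """Pearson correlation of matched per-sample class fractions."""
    if len(tumor) != len(normal):
        raise ValueError("matched vectors must have equal length")
    if len(tumor) < 3:
        raise ValueError("need at least 3 matched pairs")
    import numpy as np

    if np.std(tumor) == 0 or np.std(normal) == 0:
        raise ClassificationError("zero variance in a fraction vector: correlation undefined")
    r, _ = stats.pearsonr(tumor, normal)
    return float(r)


@dataclass
class UniquePair:
    gene5_id: str
    gene3_id: str
    n_calls: int
    junction_reads: int
    isoform_count: int
    fusion_class: Optional[FusionClass]
    samples: tuple[str, ...]

    @property
    def pair_id(self) -> str:
        return f"{self.gene5_id}-{self.gene3_id}"


def collapse_unique_pairs(calls: list[FusionCall]) -> list[UniquePair]:
    """One record per ordered parental gene pair, junction support summed and
    distinct junction isoforms (distinct breakpoint pairs) counted."""
    groups: dict[tuple[str, str], list[FusionCall]] = {}
    for c in calls:
        groups.setdefault((c.gene5_id, c.gene3_id), []).append(c)
    out = []
    for (g5, g3), grp in sorted(groups.items()):
        isoforms = {(c.bp5.chrom, c.bp5.pos, c.bp3.chrom, c.bp3.pos) for c in grp}
        out.append(
            UniquePair(
                gene5_id=g5,
                gene3_id=g3,
                n_calls=len(grp),
                junction_reads=sum(c.junction_reads for c in grp),
                isoform_count=len(isoforms),
                fusion_class=grp[0].fusion_class,
                samples=tuple(sorted({c.sample_id for c in grp})),
            )
        )
    return out
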