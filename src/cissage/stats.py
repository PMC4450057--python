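"""Characterization statistics for cis-SAGe parental gene pairs.

Covers the comparisons of validated read-through pairs against the genome
background (two-sample Kolmogorov-Smirnov tests on exon counts, intergenic
distances and intron lengths), the exon-position histograms around the fusion
junction, the significance test for preferential use of the 3' gene's second
exon (Monte-Carlo simulation plus an exact Poisson-binomial reference), the
coding-impact classification of junctions, and the nuclear/cytoplasmic
fractionation summary.

The exon-usage null model: each of the n 3' parental genes independently
contributes a junction at one of its exons chosen uniformly, so the number of
genes hitting a target rank r is Poisson-binomial with per-gene success
probability 1/E_i (0 when the gene has fewer than r exons).  The exact tail
Pr(K >= k) is computed by convolution; the Monte-Carlo estimate mirrors the
resampling procedure usually reported alongside it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import GeneModel, Transcript


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


@dataclass
class KSResult:
    D: float
    p_value: float
    n_sample: int
    n_background: int


def ks_two_sample(sample: Sequence[float], background: Sequence[float]) -> KSResult:
    """Two-sample KS test: D is the maximum vertical gap between the two
    empirical CDFs; p from the asymptotic two-sample Smirnov formula (falls
    back to the exact distribution at degenerate sizes where the asymptotic
    formula is undefined)."""
    if len(sample) == 0 or len(background) == 0:
        raise ValueError("ks_two_sample: both samples must be non-empty")
    with np.errstate(divide="ignore"):
        res = sps.ks_2samp(sample, background, method="asymp")
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = float(sps.ks_2samp(sample, background, method="exact").pvalue)
    return KSResult(float(res.statistic), p, len(sample), len(background))


# ---------------------------------------------------------------------------
# exon-position histograms


@dataclass
class JunctionRanks:
    """Exon ranks flanking one fusion junction (transcription order)."""

    pair_id: str
    rank5_forward: Optional[int]  # donor exon, counted from the 5' gene's start
    rank5_backward: Optional[int]  # donor exon, counted from the 5' gene's end
    rank3_forward: Optional[int]  # acceptor exon, counted from the 3' gene's start


@dataclass
class ExonPositionHistogram:
    counts: dict[int, int]
    n_ranked: int
    n_unranked: int


def exon_position_histogram(
    junctions: Sequence[JunctionRanks], side: str, direction: str = "forward"
) -> ExonPositionHistogram:
    """Histogram of exon ranks adjacent to the junction on one side."""
    if side not in ("5prime", "3prime"):
        raise ValueError("side must be '5prime' or '3prime'")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if side == "3prime" and direction == "backward":
        raise ValueError("backward ranks are tracked for the 5' side only")
    attr = {
        ("5prime", "forward"): "rank5_forward",
        ("5prime", "backward"): "rank5_backward",
        ("3prime", "forward"): "rank3_forward",
    }[(side, direction)]
    counts: Counter[int] = Counter()
    unranked = 0
    for j in junctions:
        r = getattr(j, attr)
        if r is None:
            unranked += 1
        else:
            counts[r] += 1
    return ExonPositionHistogram(dict(counts), sum(counts.values()), unranked)


def junction_combination_counts(
    junctions: Sequence[JunctionRanks],
) -> dict[tuple[int, int], int]:
    """Joint counts of (5' backward rank, 3' forward rank) combinations;
    the read-through signature is a dominant (2, 2) cell."""
    counts: Counter[tuple[int, int]] = Counter()
    for j in junctions:
        if j.rank5_backward is not None and j.rank3_forward is not None:
            counts[(j.rank5_backward, j.rank3_forward)] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# exon-2 usage test


@dataclass
class ExonUsageTest:
    exon_totals: list[int]
    observed_k: int
    target_rank: int
    n_sim: int
    seed: Optional[int]
    p_sim: float
    p_exact: float


def exon2_usage_exact(
    exon_totals: Sequence[int],
    observed_k: int,
    target_rank: int = 2,
    acceptor_bearing_only: bool = False,
) -> float:
    """Exact tail Pr(K >= observed_k) under the uniform-exon null.

    Success probability per gene is 1/E_i (or 1/(E_i - 1) restricted to
    acceptor-bearing exons 2..E_i when ``acceptor_bearing_only``), zero for
    genes with fewer than ``target_rank`` exons.  The Poisson-binomial PMF is
    built by exact convolution.
    """
    probs = _success_probs(exon_totals, target_rank, acceptor_bearing_only)
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    k = max(0, observed_k)
    return float(pmf[k:].sum()) if k < len(pmf) else 0.0


def exon2_usage_simulation(
    exon_totals: Sequence[int],
    observed_k: int,
    target_rank: int = 2,
    n_sim: int = 10_000,
    seed: Optional[int] = None,
    acceptor_bearing_only: bool = False,
) -> ExonUsageTest:
    """Monte-Carlo version: each replicate draws one exon uniformly per gene
    and counts genes whose draw lands on the target rank; the reported p is
    the fraction of replicates at or above the observed count."""
    E = np.asarray(exon_totals, dtype=int)
    if np.any(E < 1):
        raise ValueError("all exon totals must be >= 1")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if observed_k > len(E):
        raise ValueError("observed_k cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    lo = 2 if acceptor_bearing_only else 1
    eligible = E >= lo
    # draw one exon uniformly in [lo, E_i] per gene per replicate
    high = np.where(eligible, E + 1, lo + 1)
    draws = rng.integers(lo, high, size=(n_sim, len(E)))
    hits = (draws == target_rank) & eligible & (target_rank >= lo)
    counts = hits.sum(axis=1)
    p_sim = float(np.mean(counts >= observed_k))
    p_exact = exon2_usage_exact(exon_totals, observed_k, target_rank, acceptor_bearing_only)
    return ExonUsageTest(
        list(map(int, E)), observed_k, target_rank, n_sim, seed, p_sim, p_exact
    )


def _success_probs(
    exon_totals: Sequence[int], target_rank: int, acceptor_bearing_only: bool
) -> list[float]:
    lo = 2 if acceptor_bearing_only else 1
    probs = []
    for e in exon_totals:
        if e < 1:
            raise ValueError("all exon totals must be >= 1")
        if e < max(lo, target_rank) or target_rank < lo:
            probs.append(0.0)
        else:
            probs.append(1.0 / (e - (lo - 1)))
    return probs


# ---------------------------------------------------------------------------
# coding impact


class CodingImpact(str, Enum):
    NR = "NR"                    # junction in UTR: protein coding unaffected
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"


class NonCanonicalJunctionError(Exception):
    """Junction inside a CDS but not at an annotated exon boundary."""


def classify_coding_impact(
    gene5: GeneModel,
    donor_pos: int,
    gene3: GeneModel,
    acceptor_pos: int,
) -> CodingImpact:
    """Reading-frame consequence of a junction at annotated exon boundaries.

    ``donor_pos`` is the genomic boundary where the 5' gene's contribution
    ends (transcription-order end of the donor exon); ``acceptor_pos`` where
    the 3' gene's contribution begins.  NR when either junction point lies in
    UTR (including a 3' junction upstream of the 3' CDS, which leaves the
    downstream coding sequence intact); otherwise the cumulative coding
    lengths to the two junction points are compared modulo 3.
    """
    t5, t3 = gene5.canonical, gene3.canonical
    j5 = _boundary_tx_pos(t5, donor_pos, side="donor")
    j3 = _boundary_tx_pos(t3, acceptor_pos, side="acceptor")
    if t5.cds_start is None or t3.cds_start is None:
        return CodingImpact.NR  # non-coding parent: coding sequence unaffected
    cds5 = _tx_cds(t5)
    cds3 = _tx_cds(t3)
    if j5 <= cds5[0] or j5 >= cds5[1]:
        return CodingImpact.NR
    if j3 <= cds3[0] or j3 >= cds3[1]:
        return CodingImpact.NR
    coding5 = j5 - cds5[0]  # coding bases retained from the 5' gene
    coding3 = j3 - cds3[0]  # coding bases skipped in the 3' gene
    return CodingImpact.IN_FRAME if (coding5 - coding3) % 3 == 0 else CodingImpact.OUT_OF_FRAME


def _boundary_tx_pos(t: Transcript, genomic: int, side: str) -> int:
    """Transcript offset of an exon-boundary junction; refuses positions that
    are not exactly at the expected boundary."""
    want_end = (side == "donor") == (t.strand == "+")
    boundaries = {e.end if want_end else e.start for e in t.exons}
    if genomic not in boundaries:
        raise NonCanonicalJunctionError(
            f"{t.id}: {side} position {genomic} is not at an annotated exon "
            f"{'end' if want_end else 'start'}"
        )
    return t.tx_pos(genomic)


def _tx_cds(t: Transcript) -> tuple[int, int]:
    a, b = t.tx_pos(t.cds_start), t.tx_pos(t.cds_end)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# fractionation


@dataclass
class FractionationRecord:
    fusion_id: str
    nuclear_level: float
    cytoplasmic_level: float

    def __post_init__(self) -> None:
        if self.nuclear_level < 0 or self.cytoplasmic_level < 0:
            raise ValueError("fractionation levels must be >= 0")

    @property
    def ratio(self) -> Optional[float]:
        if self.cytoplasmic_level == 0:
            return None
        return self.nuclear_level / self.cytoplasmic_level


@dataclass
class FractionationSummary:
    crosstab: dict[CodingImpact, dict[str, int]]  # impact -> {enriched, not_enriched}
    flagged: list[str]  # records with cytoplasmic level 0 (ratio undefined)

    def total(self) -> int:
        return sum(sum(v.values()) for v in self.crosstab.values())


def summarize_fractionation(
    records: Sequence[FractionationRecord], impacts: dict[str, CodingImpact]
) -> FractionationSummary:
    """Cross-tabulate coding impact against nuclear enrichment
    (nuclear/cytoplasmic ratio strictly > 1)."""
    tab: dict[CodingImpact, dict[str, int]] = {
        c: {"enriched": 0, "not_enriched": 0} for c in CodingImpact
    }
    flagged = []
    for rec in records:
        impact = impacts[rec.fusion_id]
        r = rec.ratio
        if r is None:
            flagged.append(rec.fusion_id)
            enriched = rec.nuclear_level > 0  # all signal nuclear
        else:
            enriched = r > 1
        tab[impact]["enriched" if enriched else "not_enriched"] += 1
    return FractionationSummary(tab, flagged)
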