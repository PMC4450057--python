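"""Synthetic cohorts with known ground truth.

The generator emulates the data a read-through discovery run consumes:

* a multi-exon gene annotation whose background shapes loosely imitate the
  human genome (single-exon mass ~12%, a secondary mode near 5 exons, median
  same-strand intergenic distance ~54 kb);
* planted fusion events of four kinds — true cis-SAGe pairs (biased toward
  the "second-to-last -> second exon" junction), deletion-driven decoys with
  a matching copy-number loss, interchromosomal decoys, and trans-splicing
  -like decoys that go *down* when CTCF is silenced;
* the evidence tracks the cascade consumes: CNV segments, CTCF peaks,
  intergenic coverage, and si-/siCTCF expression tables.

Every output is a pure function of (config, seed), so recovery tests can
assert exact sensitivity/specificity against the truth set.

Also ships the transcription of the published 48-row criteria matrix
(``criteria_matrix_fixture``) used to validate the cascade arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotation import (
    Exon,
    GeneModel,
    GenomeAnnotation,
    NeighborPair,
    Transcript,
    exon_rank,
    neighbor_pairs,
)
from .classify import Breakpoint, FusionCall
from .criteria import CriteriaRecord, GenomicTrack, TrackInterval, TriState


class GenerationError(Exception):
    pass


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    genes_per_chromosome: int = 1000
    single_exon_prob: float = 0.12       # point mass at one exon
    extra_exon_poisson_mean: float = 3.0  # multi-exon count = 2 + Poisson(mean)
    exon_length_mean: float = 150.0       # exon length = 30 + Exponential(mean)
    intron_length_median: float = 1500.0  # lognormal median
    intron_length_sigma: float = 1.0
    intergenic_median: float = 54_000.0   # lognormal median (same-strand neighbors)
    intergenic_sigma: float = 1.1
    minus_strand_prob: float = 0.5
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("exon_length_mean", "intron_length_median", "intergenic_median"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if not 0 <= self.single_exon_prob <= 1:
            raise GenerationError("single_exon_prob must be a probability")


@dataclass
class PlantedEvent:
    pair_id: str
    event_type: str              # cis_sage | deletion_driven | interchr | trans_like
    gene5_id: str
    gene3_id: str
    rank5_backward: Optional[int]
    rank3_forward: Optional[int]
    expected_class: str
    expected_eliminated_at: Optional[str]  # None = survives the cascade
    fused_interval: Optional[tuple[str, int, int]] = None  # between the fused exons
    gap: Optional[tuple[str, int, int]] = None             # intergenic interval


@dataclass
class TruthSet:
    events: list[PlantedEvent]

    def of_type(self, event_type: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.event_type == event_type]

    @property
    def cis_pair_ids(self) -> set[str]:
        return {e.pair_id for e in self.of_type("cis_sage")}


# ---------------------------------------------------------------------------
# annotation generator


def simulate_annotation(cfg: SimConfig = SimConfig()) -> GenomeAnnotation:
    """Non-overlapping genes per chromosome with sampled exon/intron/intergenic
    structure; deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 10_000
        for gi in range(cfg.genes_per_chromosome):
            strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
            if rng.random() < cfg.single_exon_prob:
                n_exons = 1
            else:
                n_exons = 2 + int(rng.poisson(cfg.extra_exon_poisson_mean))
            exons: list[Exon] = []
            p = pos
            for k in range(n_exons):
                elen = 30 + int(rng.exponential(cfg.exon_length_mean))
                exons.append(Exon(chrom, p, p + elen))
                p += elen
                if k < n_exons - 1:
                    p += _lognormal_int(rng, cfg.intron_length_median, cfg.intron_length_sigma)
            gid = f"{chrom.upper()}G{gi:04d}"
            cds_start = cds_end = None
            if n_exons >= 2:
                cds_start = exons[0].start + len(exons[0]) // 2
                cds_end = exons[-1].end - len(exons[-1]) // 2
                if cds_end <= cds_start:  # degenerate tiny gene
                    cds_start = cds_end = None
            genes.append(
                GeneModel(
                    id=gid,
                    symbol=gid,
                    chrom=chrom,
                    strand=strand,
                    transcripts=[
                        Transcript(f"{gid}.t1", strand, exons, cds_start=cds_start, cds_end=cds_end)
                    ],
                )
            )
            pos = p + _lognormal_int(rng, cfg.intergenic_median, cfg.intergenic_sigma)
    return GenomeAnnotation(genes)


def _lognormal_int(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(rng.lognormal(math.log(median), sigma)))


# ---------------------------------------------------------------------------
# event planting


def plant_events(
    ann: GenomeAnnotation,
    n_per_type: tuple[int, int, int, int] = (16, 5, 13, 5),
    exon_bias: float = 11 / 16,
    seed: int = 0,
    max_cis_distance: int = 30_000,
    min_gap: int = 1_000,
    min_exons3: int = 4,
) -> tuple[list[FusionCall], TruthSet]:
    """Plant fusion calls of the four event types on an annotation.

    ``n_per_type`` orders (cis_sage, deletion_driven, interchr, trans_like).
    Exactly ``round(exon_bias * n_cis)`` cis events get the "2-2" junction
    (5' backward rank 2 -> 3' forward rank 2); the rest use a random valid
    configuration with the acceptor away from rank 2.  Planted cis pairs have
    a 5' gene of >= 2 exons and a 3' gene of >= ``min_exons3`` exons, and an
    intergenic distance in [min_gap, max_cis_distance).
    """
    n_cis, n_del, n_inter, n_trans = n_per_type
    rng = np.random.default_rng(seed)
    pairs = neighbor_pairs(ann, same_strand_only=True)
    used: set[str] = set()
    calls: list[FusionCall] = []
    events: list[PlantedEvent] = []

    def _take(filter_fn, n, what):
        # disjoint genes across all planted events: each parental gene
        # participates in at most one event
        chosen = []
        eligible = [
            p
            for p in pairs
            if p.gene5.id not in used and p.gene3.id not in used and filter_fn(p)
        ]
        order = rng.permutation(len(eligible))
        taken_idx = []
        for i in order:
            p = eligible[i]
            if p.gene5.id in used or p.gene3.id in used:
                continue
            used.update((p.gene5.id, p.gene3.id))
            taken_idx.append(i)
            if len(taken_idx) == n:
                break
        if len(taken_idx) < n:
            raise GenerationError(
                f"only {len(taken_idx)} eligible disjoint pairs for {what}, need {n}"
            )
        for i in sorted(taken_idx):
            chosen.append(eligible[i])
        return chosen

    # --- true cis-SAGe events
    cis_pairs = _take(
        lambda p: min_gap <= p.intergenic_distance < max_cis_distance
        and p.gene5.canonical.n_exons >= 2
        and p.gene3.canonical.n_exons >= min_exons3,
        n_cis,
        "cis_sage",
    )
    n_biased = round(exon_bias * n_cis)
    biased = np.zeros(n_cis, dtype=bool)
    biased[rng.choice(n_cis, size=n_biased, replace=False)] = True
    for p, two_two in zip(cis_pairs, biased):
        t5, t3 = p.gene5.canonical, p.gene3.canonical
        if two_two:
            b5, f3 = 2, 2
        else:
            b5 = int(rng.integers(1, t5.n_exons + 1))
            choices = [r for r in range(1, t3.n_exons + 1) if r != 2]
            f3 = int(choices[rng.integers(0, len(choices))])
        call = _make_call(rng, p, b5_rank=b5, f3_rank=f3)
        calls.append(call)
        events.append(
            PlantedEvent(
                pair_id=p.pair_id,
                event_type="cis_sage",
                gene5_id=p.gene5.id,
                gene3_id=p.gene3.id,
                rank5_backward=b5,
                rank3_forward=f3,
                expected_class="INTRACHR_SS_0GAP",
                expected_eliminated_at=None,
                fused_interval=_fused_interval(p, call),
                gap=(p.gene5.chrom, *p.gap),
            )
        )

    # --- deletion-driven decoys: junction at last exon -> first exon, with a
    # matching copy-number loss spanning the fused interval
    for p in _take(lambda p: p.intergenic_distance >= min_gap, n_del, "deletion_driven"):
        call = _make_call(rng, p, b5_rank=1, f3_rank=1)
        calls.append(call)
        events.append(
            PlantedEvent(
                pair_id=p.pair_id,
                event_type="deletion_driven",
                gene5_id=p.gene5.id,
                gene3_id=p.gene3.id,
                rank5_backward=1,
                rank3_forward=1,
                expected_class="INTRACHR_SS_0GAP",
                expected_eliminated_at="interstitial_deletion",
                fused_interval=_fused_interval(p, call),
                gap=(p.gene5.chrom, *p.gap),
            )
        )

    # --- trans-splicing-like decoys: CTCF bound in the gap but the fusion is
    # down-regulated by siCTCF
    for p in _take(lambda p: p.intergenic_distance >= min_gap, n_trans, "trans_like"):
        t5, t3 = p.gene5.canonical, p.gene3.canonical
        b5 = int(rng.integers(1, t5.n_exons + 1))
        f3 = int(rng.integers(1, t3.n_exons + 1))
        call = _make_call(rng, p, b5_rank=b5, f3_rank=f3)
        calls.append(call)
        events.append(
            PlantedEvent(
                pair_id=p.pair_id,
                event_type="trans_like",
                gene5_id=p.gene5.id,
                gene3_id=p.gene3.id,
                rank5_backward=b5,
                rank3_forward=f3,
                expected_class="INTRACHR_SS_0GAP",
                expected_eliminated_at="sictcf_induced",
                fused_interval=_fused_interval(p, call),
                gap=(p.gene5.chrom, *p.gap),
            )
        )

    # --- interchromosomal decoys
    chroms = sorted(ann.by_chrom)
    if len(chroms) < 2 and n_inter > 0:
        raise GenerationError("interchr events need >= 2 chromosomes")
    free = [g for g in ann if g.id not in used]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in free:
        by_chrom.setdefault(g.chrom, []).append(g)
    for _ in range(n_inter):
        c5, c3 = rng.choice(chroms, size=2, replace=False)
        g5 = by_chrom[c5][int(rng.integers(0, len(by_chrom[c5])))]
        g3 = by_chrom[c3][int(rng.integers(0, len(by_chrom[c3])))]
        while g3.id == g5.id or g3.id in used or g5.id in used:  # pragma: no cover
            g5 = by_chrom[c5][int(rng.integers(0, len(by_chrom[c5])))]
            g3 = by_chrom[c3][int(rng.integers(0, len(by_chrom[c3])))]
        used.update((g5.id, g3.id))
        t5, t3 = g5.canonical, g3.canonical
        donor = t5.exons_in_transcription_order()[-1]
        acceptor = t3.exons_in_transcription_order()[0]
        call = FusionCall(
            sample_id="sim",
            gene5_id=g5.id,
            gene3_id=g3.id,
            bp5=Breakpoint(g5.chrom, donor.end if g5.strand == "+" else donor.start, g5.strand),
            bp3=Breakpoint(
                g3.chrom, acceptor.start if g3.strand == "+" else acceptor.end, g3.strand
            ),
            junction_reads=int(rng.integers(3, 51)),
            spanning_reads=int(rng.integers(1, 20)),
        )
        calls.append(call)
        events.append(
            PlantedEvent(
                pair_id=f"{g5.symbol}-{g3.symbol}",
                event_type="interchr",
                gene5_id=g5.id,
                gene3_id=g3.id,
                rank5_backward=None,
                rank3_forward=None,
                expected_class="INTERCHR",
                expected_eliminated_at=None,
                fused_interval=None,
                gap=None,
            )
        )

    return calls, TruthSet(events)


def _exon_by_rank(t: Transcript, rank: int, direction: str) -> Exon:
    for i, e in enumerate(t.exons):
        if exon_rank(t, exon_index=i, direction=direction) == rank:
            return e
    raise GenerationError(f"{t.id}: no exon with {direction} rank {rank}")


def _make_call(
    rng: np.random.Generator, p: NeighborPair, b5_rank: int, f3_rank: int
) -> FusionCall:
    t5, t3 = p.gene5.canonical, p.gene3.canonical
    donor = _exon_by_rank(t5, b5_rank, "backward")
    acceptor = _exon_by_rank(t3, f3_rank, "forward")
    strand = p.gene5.strand
    return FusionCall(
        sample_id="sim",
        gene5_id=p.gene5.id,
        gene3_id=p.gene3.id,
        bp5=Breakpoint(p.gene5.chrom, donor.end if strand == "+" else donor.start, strand),
        bp3=Breakpoint(p.gene3.chrom, acceptor.start if strand == "+" else acceptor.end, strand),
        junction_reads=int(rng.integers(3, 51)),
        spanning_reads=int(rng.integers(1, 20)),
    )


def _fused_interval(p: NeighborPair, call: FusionCall) -> tuple[str, int, int]:
    lo = min(call.bp5.pos, call.bp3.pos)
    hi = max(call.bp5.pos, call.bp3.pos)
    return (p.gene5.chrom, lo, hi)


# ---------------------------------------------------------------------------
# tracks and expression


@dataclass
class SimulatedTracks:
    cnv: GenomicTrack
    peaks: GenomicTrack
    coverage: GenomicTrack
    fusion_expression: dict[str, dict[str, float]]  # pair_id -> {si_neg, siCTCF}
    gene_fpkm: dict[str, float]


def simulate_tracks_and_expression(
    ann: GenomeAnnotation,
    truth: TruthSet,
    seed: int = 0,
    loss_log2: float = -1.0,
    peak_width: int = 600,
    gap_coverage: float = 5.0,
    induced_fc: float = 2.0,
    down_fc: float = 0.5,
    baseline: float = 10.0,
) -> SimulatedTracks:
    """Evidence tracks consistent with the planted truth.

    Copy-number losses appear only under deletion-driven events; CTCF peaks
    sit in the gaps of cis-SAGe and trans-like pairs (both have a bound
    insulator, they differ in the knockdown response); intergenic coverage
    exceeds threshold only for cis-SAGe pairs; siCTCF/si- fold change is
    ``induced_fc`` for cis-SAGe fusions and ``down_fc`` for trans-like ones.
    """
    rng = np.random.default_rng(seed)
    chrom_span: dict[str, tuple[int, int]] = {}
    for chrom, glist in ann.by_chrom.items():
        chrom_span[chrom] = (0, max(g.span_end for g in glist) + 10_000)

    losses: dict[str, list[tuple[int, int]]] = {}
    for ev in truth.of_type("deletion_driven"):
        chrom, lo, hi = ev.fused_interval
        losses.setdefault(chrom, []).append((lo, hi))

    cnv_ivs: list[TrackInterval] = []
    for chrom, (lo, hi) in sorted(chrom_span.items()):
        cuts = sorted(losses.get(chrom, []))
        pos = lo
        for a, b in cuts:
            if a > pos:
                cnv_ivs.append(TrackInterval(chrom, pos, a, 0.0))
            cnv_ivs.append(TrackInterval(chrom, a, b, loss_log2))
            pos = b
        if hi > pos:
            cnv_ivs.append(TrackInterval(chrom, pos, hi, 0.0))

    peak_ivs: list[TrackInterval] = []
    cov_ivs: list[TrackInterval] = []
    for ev in truth.events:
        if ev.event_type in ("cis_sage", "trans_like"):
            chrom, g0, g1 = ev.gap
            mid = (g0 + g1) // 2
            half = min(peak_width // 2, max(1, (g1 - g0) // 2))
            peak_ivs.append(TrackInterval(chrom, mid - half, mid + half, 1.0))
        if ev.event_type == "cis_sage":
            chrom, g0, g1 = ev.gap
            cov_ivs.append(TrackInterval(chrom, g0, g1, gap_coverage))

    fusion_expr: dict[str, dict[str, float]] = {}
    for ev in truth.events:
        fc = {
            "cis_sage": induced_fc,
            "trans_like": down_fc,
            "deletion_driven": 1.0,
            "interchr": 1.0,
        }[ev.event_type]
        fusion_expr[ev.pair_id] = {"si_neg": baseline, "siCTCF": baseline * fc}

    gene_fpkm = {
        g.id: float(rng.lognormal(math.log(2.0), 1.5)) for g in ann
    }
    for ev in truth.of_type("cis_sage"):
        gene_fpkm[ev.gene5_id] = max(gene_fpkm[ev.gene5_id], 5.0)

    return SimulatedTracks(
        cnv=GenomicTrack(cnv_ivs),
        peaks=GenomicTrack(peak_ivs),
        coverage=GenomicTrack(cov_ivs),
        fusion_expression=fusion_expr,
        gene_fpkm=gene_fpkm,
    )


@dataclass
class SimulatedCohort:
    config: SimConfig
    annotation: GenomeAnnotation
    calls: list[FusionCall]
    truth: TruthSet
    tracks: SimulatedTracks

    def evidence(self) -> dict[str, dict[str, bool]]:
        """Wet-lab evidence flags for the planted events (all junctions are
        real by construction, so Sanger confirmation is positive)."""
        return {ev.pair_id: {"sanger": True} for ev in self.truth.events}


def simulate_cohort(
    cfg: SimConfig = SimConfig(),
    n_per_type: tuple[int, int, int, int] = (16, 5, 13, 5),
    exon_bias: float = 11 / 16,
) -> SimulatedCohort:
    """Full study-condition cohort: annotation + planted calls + tracks.

    Sub-seeds for planting and tracks are derived deterministically from
    ``cfg.seed`` so one seed fixes the whole cohort.
    """
    ann = simulate_annotation(cfg)
    calls, truth = plant_events(ann, n_per_type=n_per_type, exon_bias=exon_bias, seed=cfg.seed + 1)
    tracks = simulate_tracks_and_expression(ann, truth, seed=cfg.seed + 2)
    return SimulatedCohort(cfg, ann, calls, truth, tracks)


# ---------------------------------------------------------------------------
# published criteria-matrix fixture (48 candidate pairs)

# columns: pair id, starred (member of the final 16), Sanger, immediate
# neighbor, interstitial deletion, CTCF binding, siCTCF induction, intergenic
# transcript; "." = not evaluated (blank in the published table)
_TABLE1_ROWS = """\
SLC39A1-CRTC2     . Y Y N Y N .
SMG5-PAQR6        . Y Y N Y N .
METTL10-FAM53B    . Y Y N Y N .
TFDP1-GRK1        . Y N N Y Y .
ZNF592-ALPK3      * Y Y N Y Y Y
MFGE8-HAPLN3      * Y Y N Y Y Y
KIAA0753-PITPNM3  . Y Y N Y N .
CIRBP-C19orf24    . Y Y N Y N .
PROM2-KCNIP3      * Y Y N Y Y Y
TP53RK-SLC13A3    . N . . . . .
LINC00680-GUSBP4  . Y N N Y Y .
TMED4-DDX56       * Y Y N Y Y Y
PPP1R16A-GPT      . Y Y N Y N .
TTTY15-USP9Y      . Y Y N Y N .
ADCK4-Numbl       * Y Y N Y Y Y
ADSL-SGSM3        . Y Y N Y N .
AKAP8L-AKAP8      . Y Y N Y N .
AP5S1-MAVS        * Y Y N Y Y Y
BAIAP2L2-SLC16A8  * Y Y N Y Y Y
C14orf80-TMEM121  * Y Y N Y Y Y
CHCHD10-VPREB3F   . Y N N N N .
CLN6-CALML4       * Y Y N Y Y Y
CTNNBIP1-CLSTN1   * Y Y N Y Y Y
D2HGDH-GAL3ST2    * Y Y N Y Y Y
DMC1-DDX17        . Y Y N Y N .
DMKN-KRTDAP       . Y Y N Y N .
DPM2-PIP5KL1      . Y Y N Y N .
EIF3K-ACTN4       . Y Y N N N .
HDAC8-CITED1      . Y Y N Y N .
MED12-NLGN3       . Y Y N Y N .
NUDT14-JAG2       * Y Y N Y Y Y
PRIM1-NACA        * Y Y N Y Y Y
RRM2-C2orf48      . Y Y N Y N .
SCNN1A-TNFRSF1A   * Y Y N Y Y Y
SIDT2-TAGLN       . Y N N Y N .
SLC29A1-HSP90AB1  . Y Y N Y N .
TRADD-B3GNT9      . Y Y N Y N .
WRB-SH3BGR        . Y N N Y N .
AZGP1-GJC3        . Y Y N Y N .
BRCA1-VAT1        . Y N . . . .
DTD2-HEATR5A      . Y Y N N Y .
MBD1-CCDC11       * Y Y N Y Y Y
RNF4-FAM193A      . Y Y N Y N .
CTBS-GNG5         . Y N N Y Y .
DHRS1-RABGGTA     . N . . . . .
VAMP1-CD27-AS1    . Y N N N N .
LMAN2-MXD3        * Y Y N Y Y Y
POLA2-CDC42EP2    . Y Y N Y N .
"""


def criteria_matrix_fixture() -> tuple[list[CriteriaRecord], set[str]]:
    """The published 48-pair criteria matrix and the 16-pair final set.

    Returns the records in table order plus the set of starred pair ids (the
    pairs satisfying all six criteria).
    """
    records: list[CriteriaRecord] = []
    starred: set[str] = set()

    def ts(tok: str) -> TriState:
        return TriState.NA if tok == "." else TriState(tok)

    for line in _TABLE1_ROWS.strip().splitlines():
        toks = line.split()
        pair_id, star = toks[0], toks[1]
        flags = [ts(t) for t in toks[2:8]]
        records.append(
            CriteriaRecord(
                pair_id=pair_id,
                sanger_confirmed=flags[0],
                immediate_neighbor=flags[1],
                interstitial_deletion=flags[2],
                ctcf_binding=flags[3],
                sictcf_induced=flags[4],
                intergenic_transcript=flags[5],
            )
        )
        if star == "*":
            starred.add(pair_id)
    return records, starred
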