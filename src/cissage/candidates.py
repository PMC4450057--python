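"""Genome-wide prediction of novel read-through (cis-SAGe) candidates.

Validated cis-SAGe events share four properties that become prediction rules:
(1) the parents are immediate same-strand neighbors; (2) their intergenic
distance is under 30 kb; (3) the 5' gene is actively transcribed (FPKM > 1);
and (4) the junction favors the 5' gene's second-to-last exon spliced to the
3' gene's second exon.  Rules 1-3 select pairs; rule 4 predicts the junction
to assay, so the emitted coordinates are the donor/acceptor exon spans an
RT-PCR primer pair would target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation import Exon, GenomeAnnotation, NeighborPair, exon_rank, neighbor_pairs

logger = logging.getLogger(__name__)


class NoPredictionError(Exception):
    """Junction prediction impossible (single-exon parent)."""


@dataclass
class RuleConfig:
    max_distance: int = 30_000        # rule 2: strictly less than
    min_fpkm: float = 1.0             # rule 3: strictly greater than
    require_multi_exon: bool = True   # both parents need >= 2 exons
    require_3prime_expression: bool = False

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


@dataclass
class PredictedJunction:
    donor_exon: Exon       # 5' gene, backward rank 2 (second-to-last)
    acceptor_exon: Exon    # 3' gene, forward rank 2
    donor_boundary: int    # genomic coordinate where the 5' contribution ends
    acceptor_boundary: int # genomic coordinate where the 3' contribution starts


@dataclass
class CandidatePair:
    pair: NeighborPair
    rule_flags: dict[str, bool]
    fpkm5: float
    fpkm3: float
    junction: Optional[PredictedJunction]

    @property
    def pair_id(self) -> str:
        return self.pair.pair_id


def enumerate_candidates(
    ann: GenomeAnnotation, expression: dict[str, float], cfg: RuleConfig = RuleConfig()
) -> list[CandidatePair]:
    """All neighbor pairs satisfying the four rules, with predicted junctions."""
    out = []
    for pair in neighbor_pairs(ann, same_strand_only=True):
        fpkm5 = _fpkm(expression, pair.gene5.id)
        fpkm3 = _fpkm(expression, pair.gene3.id)
        flags = {
            "same_strand": pair.same_strand,
            "distance_ok": pair.intergenic_distance < cfg.max_distance,
            "five_prime_expressed": fpkm5 > cfg.min_fpkm,
            "multi_exonic_ok": (
                pair.gene5.canonical.n_exons >= 2 and pair.gene3.canonical.n_exons >= 2
            )
            if cfg.require_multi_exon
            else True,
        }
        if cfg.require_3prime_expression:
            flags["three_prime_expressed"] = fpkm3 > cfg.min_fpkm
        if not all(flags.values()):
            continue
        junction = (
            predicted_junction(pair)
            if pair.gene5.canonical.n_exons >= 2 and pair.gene3.canonical.n_exons >= 2
            else None
        )
        out.append(CandidatePair(pair, flags, fpkm5, fpkm3, junction))
    return out


def predicted_junction(pair: NeighborPair) -> PredictedJunction:
    """The '2-2' junction: second-to-last exon of the 5' gene joined to the
    second exon of the 3' gene (strand-aware), plus the amplicon exon spans."""
    t5 = pair.gene5.canonical
    t3 = pair.gene3.canonical
    if t5.n_exons < 2 or t3.n_exons < 2:
        raise NoPredictionError(f"{pair.pair_id}: single-exon parent, no junction predicted")
    donor = _exon_with_rank(t5, backward=2)
    acceptor = _exon_with_rank(t3, forward=2)
    donor_boundary = donor.end if t5.strand == "+" else donor.start
    acceptor_boundary = acceptor.start if t3.strand == "+" else acceptor.end
    return PredictedJunction(donor, acceptor, donor_boundary, acceptor_boundary)


def _exon_with_rank(t, forward: Optional[int] = None, backward: Optional[int] = None) -> Exon:
    for i, e in enumerate(t.exons):
        if forward is not None and exon_rank(t, exon_index=i, direction="forward") == forward:
            return e
        if backward is not None and exon_rank(t, exon_index=i, direction="backward") == backward:
            return e
    raise NoPredictionError(f"{t.id}: no exon with requested rank")


def sample_candidates(
    candidates: Sequence[CandidatePair], n: int, seed: Optional[int] = None
) -> list[CandidatePair]:
    """Uniform random subset of size n (without replacement), reproducible by
    seed; input order is preserved in the output."""
    if n > len(candidates):
        raise ValueError(f"cannot sample {n} from {len(candidates)} candidates")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(candidates), size=n, replace=False))
    return [candidates[i] for i in idx]


def verify_rules(cand: CandidatePair, cfg: RuleConfig = RuleConfig()) -> bool:
    """Re-check the four rules from scratch on an emitted candidate."""
    p = cand.pair
    ok = (
        p.same_strand
        and p.intergenic_distance < cfg.max_distance
        and cand.fpkm5 > cfg.min_fpkm
    )
    if cfg.require_multi_exon:
        ok = ok and p.gene5.canonical.n_exons >= 2 and p.gene3.canonical.n_exons >= 2
    return ok


def _fpkm(expression: dict[str, float], gene_id: str) -> float:
    if gene_id not in expression:
        logger.info("gene %s missing from expression table; FPKM treated as 0", gene_id)
        return 0.0
    return expression[gene_id]
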