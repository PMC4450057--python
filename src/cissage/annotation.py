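"""Gene-annotation model with strand-aware neighbor relations and exon ranking.

Internally all coordinates are 0-based half-open; GTF input/output is 1-based
inclusive and BED input/output is 0-based half-open.  Gene models carry one or
more transcripts; a single *canonical* transcript per gene (most exons, ties
broken by longest span then lexicographic id) is used for exon ranking,
genome-background statistics and reading-frame arithmetic.

The neighbor relation underlying read-through (cis-SAGe) analysis is strictly
*immediate* adjacency: two genes are neighbors when no other annotated gene
lies between them in genomic order, and a same-strand pair is oriented so that
``gene5`` is the transcriptionally upstream partner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils
from intervaltree import IntervalTree


class AnnotationError(Exception):
    """Malformed or inconsistent annotation input."""


class NoRankError(Exception):
    """A genomic position does not map onto any exon of the transcript."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based
    end: int    # half-open

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"exon with start >= end: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    id: str
    strand: str
    exons: list[Exon]
    cds_start: Optional[int] = None  # genomic, 0-based
    cds_end: Optional[int] = None    # genomic, half-open

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"transcript {self.id}: strand must be + or -")
        if not self.exons:
            raise AnnotationError(f"transcript {self.id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(f"transcript {self.id}: overlapping exons {a} / {b}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"transcript {self.id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
                raise AnnotationError(f"transcript {self.id}: CDS outside transcript span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_in_transcription_order(self) -> list[Exon]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def intron_lengths(self) -> list[int]:
        return [b.start - a.end for a, b in zip(self.exons, self.exons[1:])]

    def tx_pos(self, genomic: int) -> int:
        """Transcript offset of a genomic boundary: the number of exonic bases
        transcribed 5' of that point (strand-aware)."""
        if self.strand == "+":
            return sum(max(0, min(e.end, genomic) - e.start) for e in self.exons)
        return sum(max(0, e.end - max(e.start, genomic)) for e in self.exons)

    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    span_start: int = -1
    span_end: int = -1

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.id}: no transcripts")
        lo = min(t.span[0] for t in self.transcripts)
        hi = max(t.span[1] for t in self.transcripts)
        if self.span_start < 0:
            self.span_start = lo
        if self.span_end < 0:
            self.span_end = hi
        if lo < self.span_start or hi > self.span_end:
            raise AnnotationError(
                f"gene {self.id}: exon outside declared gene span "
                f"[{self.span_start}, {self.span_end})"
            )
        for t in self.transcripts:
            if t.strand != self.strand:
                raise AnnotationError(f"gene {self.id}: transcript {t.id} on wrong strand")

    @property
    def canonical(self) -> Transcript:
        """Most exons; ties: longest span, then lexicographically smallest id."""
        return max(
            self.transcripts,
            key=lambda t: (t.n_exons, t.span[1] - t.span[0], _neg_id(t.id)),
        )

    # transcription-direction helpers
    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end

    @property
    def tes(self) -> int:
        return self.span_end if self.strand == "+" else self.span_start


class _neg_id(str):
    """Reverse lexicographic comparison so max() picks the smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str(self) > str(other)


@dataclass(frozen=True)
class NeighborPair:
    gene5: GeneModel
    gene3: GeneModel
    intergenic_distance: int
    same_strand: bool
    intervening_gene_ids: tuple[str, ...] = ()

    @property
    def pair_id(self) -> str:
        return f"{self.gene5.symbol}-{self.gene3.symbol}"

    @property
    def gap(self) -> tuple[int, int]:
        """The (possibly empty) genomic interval between the two gene spans."""
        left, right = sorted((self.gene5, self.gene3), key=lambda g: g.span_start)
        return left.span_end, max(left.span_end, right.span_start)


@dataclass
class BackgroundDistributions:
    exon_counts: list[int]
    intergenic_distances: list[int]
    intron_lengths: list[int]


class GenomeAnnotation:
    """Indexed collection of gene models with overlap and adjacency queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort(key=lambda g: (g.span_start, g.span_end, g.id))
        self._trees: dict[str, IntervalTree] = {}
        for chrom, glist in self.by_chrom.items():
            self._trees[chrom] = IntervalTree.from_tuples(
                (g.span_start, g.span_end, g.id) for g in glist
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        for chrom in sorted(self.by_chrom):
            yield from self.by_chrom[chrom]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.genes == other.genes

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id}") from None

    def by_symbol(self, symbol: str) -> GeneModel:
        for g in self.genes.values():
            if g.symbol == symbol:
                return g
        raise KeyError(f"unknown gene symbol: {symbol}")

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.genes[i] for i in hits]


# ---------------------------------------------------------------------------
# neighbor relations


def neighbor_pairs(
    ann: GenomeAnnotation,
    same_strand_only: bool = True,
    max_distance: Optional[int] = None,
) -> list[NeighborPair]:
    """Immediate neighboring gene pairs per chromosome.

    Adjacency is over *all* genes in coordinate order (a gene of either strand
    between two genes breaks their adjacency).  For same-strand pairs the 5'
    member is the transcriptionally upstream gene; intergenic distance is
    ``max(0, start_right - end_left)`` so overlapping neighbors stay eligible
    at distance 0.
    """
    out: list[NeighborPair] = []
    for chrom in sorted(ann.by_chrom):
        glist = ann.by_chrom[chrom]
        for left, right in zip(glist, glist[1:]):
            same = left.strand == right.strand
            if same_strand_only and not same:
                continue
            dist = max(0, right.span_start - left.span_end)
            if max_distance is not None and dist > max_distance:
                continue
            if same and left.strand == "-":
                g5, g3 = right, left
            else:
                g5, g3 = left, right
            out.append(NeighborPair(g5, g3, dist, same))
    return out


def intervening_genes(ann: GenomeAnnotation, g5: GeneModel, g3: GeneModel) -> list[str]:
    """Ids of genes (any strand) overlapping the open interval between the two
    gene spans by at least 1 bp; the pair itself is excluded."""
    if g5.chrom != g3.chrom:
        raise AnnotationError(
            f"intervening_genes: {g5.id} and {g3.id} are on different chromosomes"
        )
    left, right = sorted((g5, g3), key=lambda g: g.span_start)
    lo, hi = left.span_end, right.span_start
    if hi <= lo:
        return []
    return [g.id for g in ann.overlapping(g5.chrom, lo, hi) if g.id not in (g5.id, g3.id)]


# ---------------------------------------------------------------------------
# exon ranking


def exon_rank(
    t: Transcript,
    exon_index: Optional[int] = None,
    position: Optional[int] = None,
    direction: str = "forward",
    tolerance: int = 0,
) -> int:
    """1-based exon rank in transcription order.

    ``forward`` counts from the transcript's 5' end, ``backward`` from its 3'
    end, so forward + backward = exon count + 1 for every exon.  Either a
    genomic-sorted ``exon_index`` or a genomic ``position`` may be given; a
    position that falls on no exon (within ``tolerance`` bp of a boundary)
    raises :class:`NoRankError`.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    if (exon_index is None) == (position is None):
        raise ValueError("give exactly one of exon_index or position")
    if position is not None:
        exon_index = exon_index_at(t, position, tolerance=tolerance)
    n = t.n_exons
    if not 0 <= exon_index < n:
        raise NoRankError(f"exon index {exon_index} out of range for {t.id}")
    fwd = exon_index + 1 if t.strand == "+" else n - exon_index
    return fwd if direction == "forward" else n + 1 - fwd


def exon_index_at(t: Transcript, position: int, tolerance: int = 0) -> int:
    """Genomic-sorted index of the exon containing ``position`` (or within
    ``tolerance`` bp of one of its boundaries)."""
    for i, e in enumerate(t.exons):
        if e.start - tolerance <= position < e.end + tolerance:
            return i
    raise NoRankError(f"position {position} maps to no exon of {t.id}")


@dataclass(frozen=True)
class JunctionMatch:
    exon_index: int       # genomic-sorted index
    offset: int           # signed distance from the canonical boundary
    canonical: bool       # |offset| <= slack


def match_breakpoint(
    t: Transcript, position: int, side: str, slack: int = 5
) -> JunctionMatch:
    """Match a fusion breakpoint to the exon boundary it should represent.

    ``side='donor'`` expects the transcription-order *end* of an exon (the 5'
    partner's contribution ends there); ``side='acceptor'`` expects an exon
    *start*.  A breakpoint farther than ``slack`` bp from the nearest such
    boundary is matched to its nearest exon but flagged non-canonical.
    """
    if side not in ("donor", "acceptor"):
        raise ValueError("side must be 'donor' or 'acceptor'")
    want_end = (side == "donor") == (t.strand == "+")
    # candidate boundaries: exon ends (half-open) or exon starts
    best: Optional[JunctionMatch] = None
    for i, e in enumerate(t.exons):
        boundary = e.end if want_end else e.start
        off = position - boundary
        if best is None or abs(off) < abs(best.offset):
            best = JunctionMatch(i, off, abs(off) <= slack)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# genome background


def genome_background(ann: GenomeAnnotation) -> BackgroundDistributions:
    """Whole-annotation distributions used as the null in the characterization
    comparisons: exon counts and intron lengths of canonical transcripts, and
    intergenic distances of same-strand immediate neighbor pairs."""
    exon_counts: list[int] = []
    intron_lengths: list[int] = []
    for g in ann:
        t = g.canonical
        exon_counts.append(t.n_exons)
        intron_lengths.extend(t.intron_lengths())
    dists = [p.intergenic_distance for p in neighbor_pairs(ann, same_strand_only=True)]
    return BackgroundDistributions(exon_counts, dists, intron_lengths)


# ---------------------------------------------------------------------------
# GTF / GFF3 I/O


def load_annotation(path: str | Path) -> GenomeAnnotation:
    """Load a GTF or GFF3 annotation into a :class:`GenomeAnnotation`.

    Exon (and optional CDS) features are grouped by ``transcript_id`` and
    ``gene_id`` attributes (GTF) or by ``Parent`` chains (GFF3).  1-based
    inclusive file coordinates become 0-based half-open internally.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise AnnotationError(
                    f"{path}: malformed feature line {lineno} (expected 9 tab-separated fields)"
                )
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise AnnotationError(f"cannot parse {path}: {exc}") from exc

    # transcript -> gene resolution for Parent-style (GFF3) files
    tx_parent: dict[str, str] = {}
    tx_strand: dict[str, str] = {}
    gene_meta: dict[str, dict] = {}
    for f in db.all_features():
        if f.featuretype in ("transcript", "mRNA"):
            tid = _attr(f, "transcript_id") or _attr(f, "ID")
            gid = _attr(f, "gene_id") or _attr(f, "Parent")
            if tid and gid:
                tx_parent[tid] = gid
        if f.featuretype == "gene":
            gid = _attr(f, "gene_id") or _attr(f, "ID")
            if gid:
                gene_meta[gid] = {
                    "symbol": _attr(f, "gene_name") or _attr(f, "Name") or gid,
                    "span": (f.start - 1, f.end),
                    "strand": f.strand,
                    "chrom": f.seqid,
                }

    exons: dict[str, list[Exon]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}
    tx_info: dict[str, tuple[str, str]] = {}  # tid -> (chrom, strand)
    gene_symbol: dict[str, str] = {}
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS"):
            continue
        tid = _attr(f, "transcript_id") or _attr(f, "Parent")
        if tid is None:
            raise AnnotationError(f"{path}: {f.featuretype} feature without transcript id")
        gid = _attr(f, "gene_id") or tx_parent.get(tid)
        if gid is None:
            raise AnnotationError(f"{path}: cannot resolve gene id for transcript {tid}")
        if f.strand not in ("+", "-"):
            raise AnnotationError(f"{path}: feature for {tid} lacks a +/- strand")
        tx_gene[tid] = gid
        tx_info[tid] = (f.seqid, f.strand)
        sym = _attr(f, "gene_name")
        if sym:
            gene_symbol[gid] = sym
        if f.featuretype == "exon":
            exons.setdefault(tid, []).append(Exon(f.seqid, f.start - 1, f.end))
        else:
            cds.setdefault(tid, []).append((f.start - 1, f.end))

    genes: dict[str, GeneModel] = {}
    by_gene: dict[str, list[Transcript]] = {}
    for tid, ex in exons.items():
        chrom, strand = tx_info[tid]
        c = cds.get(tid)
        cs, ce = (min(a for a, _ in c), max(b for _, b in c)) if c else (None, None)
        by_gene.setdefault(tx_gene[tid], []).append(
            Transcript(tid, strand, ex, cds_start=cs, cds_end=ce)
        )
    for gid, txs in by_gene.items():
        meta = gene_meta.get(gid, {})
        chrom, strand = tx_info[txs[0].id]
        kwargs = {}
        if "span" in meta:
            kwargs = {"span_start": meta["span"][0], "span_end": meta["span"][1]}
        genes[gid] = GeneModel(
            id=gid,
            symbol=gene_symbol.get(gid) or meta.get("symbol", gid),
            chrom=meta.get("chrom", chrom),
            strand=meta.get("strand", strand),
            transcripts=sorted(txs, key=lambda t: t.id),
            **kwargs,
        )
    if not genes:
        warnings.warn(f"{path}: no exon features found", stacklevel=2)
    return GenomeAnnotation(genes.values())


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write a GenomeAnnotation as GTF (1-based inclusive coordinates)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in ann:
            attrs = f'gene_id "{g.id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tcissage\tgene\t{g.span_start + 1}\t{g.span_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in sorted(g.transcripts, key=lambda t: t.id):
                tattrs = f'gene_id "{g.id}"; transcript_id "{t.id}"; gene_name "{g.symbol}";'
                lo, hi = t.span
                fh.write(
                    f"{g.chrom}\tcissage\ttranscript\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\tcissage\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds_start is not None:
                    for e in t.exons:
                        lo_c = max(e.start, t.cds_start)
                        hi_c = min(e.end, t.cds_end)
                        if lo_c < hi_c:
                            fh.write(
                                f"{g.chrom}\tcissage\tCDS\t{lo_c + 1}\t{hi_c}\t.\t"
                                f"{g.strand}\t.\t{tattrs}\n"
                            )


def _attr(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    if not vals:
        return None
    return vals[0]
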