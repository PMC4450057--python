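"""Readers and writers for the pipeline's tabular formats.

TSV for fusion calls, expression and criteria matrices; BED (0-based
half-open) for CNV segments and peaks; bedGraph for coverage.  Every writer
produces files its paired reader parses losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .candidates import CandidatePair, RuleConfig
from .classify import Breakpoint, FusionCall, FusionClass
from .criteria import (
    CriteriaRecord,
    FilterConfig,
    FilterReport,
    GenomicTrack,
    STAGES,
    TrackInterval,
    TriState,
)

FUSION_COLUMNS = [
    "sample_id",
    "gene5",
    "chrom5",
    "pos5",
    "strand5",
    "gene3",
    "chrom3",
    "pos3",
    "strand3",
    "junction_reads",
    "spanning_reads",
]


class InputError(Exception):
    """Missing or malformed input file."""


# ---------------------------------------------------------------------------
# fusion call tables


def read_fusion_tsv(path: str | Path) -> list[FusionCall]:
    df = _read_tsv(path, required=FUSION_COLUMNS)
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            FusionCall(
                sample_id=str(row.sample_id),
                gene5_id=str(row.gene5),
                gene3_id=str(row.gene3),
                bp5=Breakpoint(str(row.chrom5), int(row.pos5), str(row.strand5)),
                bp3=Breakpoint(str(row.chrom3), int(row.pos3), str(row.strand3)),
                junction_reads=int(row.junction_reads),
                spanning_reads=int(row.spanning_reads),
                fusion_class=FusionClass(row.fusion_class)
                if "fusion_class" in df.columns and pd.notna(row.fusion_class)
                else None,
            )
        )
    return calls


def write_fusion_tsv(calls: list[FusionCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "gene5": c.gene5_id,
                "chrom5": c.bp5.chrom,
                "pos5": c.bp5.pos,
                "strand5": c.bp5.strand,
                "gene3": c.gene3_id,
                "chrom3": c.bp3.chrom,
                "pos3": c.bp3.pos,
                "strand3": c.bp3.strand,
                "junction_reads": c.junction_reads,
                "spanning_reads": c.spanning_reads,
                "fusion_class": c.fusion_class.value if c.fusion_class else "",
                "note": c.note,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval tracks


def read_bed_track(path: str | Path, value_column: bool = True) -> GenomicTrack:
    """BED-like TSV: chrom, start, end[, value] with 0-based half-open
    coordinates.  Works for CNV segments (value = log2 ratio), peaks
    (value = score) and bedGraph coverage."""
    names = ["chrom", "start", "end", "value"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except (FileNotFoundError, pd.errors.EmptyDataError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise InputError(f"missing track file: {path}") from exc
        return GenomicTrack([])
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    ivs = [
        TrackInterval(
            str(r.chrom),
            int(r.start),
            int(r.end),
            float(r.value) if value_column and "value" in df.columns else 0.0,
        )
        for r in df.itertuples(index=False)
    ]
    return GenomicTrack(ivs)


read_bedgraph = read_bed_track


def write_bed_track(track: GenomicTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value:g}\n")


# ---------------------------------------------------------------------------
# expression tables


def read_gene_expression_tsv(path: str | Path) -> dict[str, float]:
    """Columns: gene_id, fpkm."""
    df = _read_tsv(path, required=["gene_id", "fpkm"])
    return {str(r.gene_id): float(r.fpkm) for r in df.itertuples(index=False)}


def write_gene_expression_tsv(expr: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(expr), "fpkm": [expr[g] for g in expr]}
    ).to_csv(path, sep="\t", index=False)


def read_condition_expression_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    """Columns: feature_id, condition (si_neg | siCTCF), value."""
    df = _read_tsv(path, required=["feature_id", "condition", "value"])
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.feature_id), {})[str(r.condition)] = float(r.value)
    return out


def write_condition_expression_tsv(
    expr: dict[str, dict[str, float]], path: str | Path
) -> None:
    rows = [
        {"feature_id": f, "condition": cond, "value": v}
        for f, conds in expr.items()
        for cond, v in conds.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence flags (wet-lab outcomes entering as data)


def read_evidence_tsv(path: str | Path) -> dict[str, dict[str, bool]]:
    """Columns: pair_id, plus any of sanger / intergenic with Y/N values."""
    df = _read_tsv(path, required=["pair_id"])
    out: dict[str, dict[str, bool]] = {}
    for r in df.itertuples(index=False):
        flags = {}
        for col in ("sanger", "intergenic"):
            if col in df.columns:
                val = getattr(r, col)
                if pd.notna(val) and str(val) != "":
                    flags[col] = str(val) == "Y"
        out[str(r.pair_id)] = flags
    return out


def write_evidence_tsv(evidence: dict[str, dict[str, bool]], path: str | Path) -> None:
    rows = []
    for pid, flags in evidence.items():
        rows.append(
            {
                "pair_id": pid,
                **{k: ("Y" if v else "N") for k, v in flags.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# criteria matrices and reports

_CRITERIA_COLS = [
    "sanger",
    "neighboring",
    "deletion",
    "ctcf_binding",
    "sictcf_induction",
    "intergenic_transcript",
]
_COL_TO_FIELD = dict(
    zip(
        _CRITERIA_COLS,
        [
            "sanger_confirmed",
            "immediate_neighbor",
            "interstitial_deletion",
            "ctcf_binding",
            "sictcf_induced",
            "intergenic_transcript",
        ],
    )
)


def read_criteria_matrix(path: str | Path) -> list[CriteriaRecord]:
    """TSV with header pair_id + the six criterion columns, cells Y/N/empty
    (empty = not evaluated)."""
    df = _read_tsv(path, required=["pair_id"] + _CRITERIA_COLS, keep_default_na=False)
    records = []
    for r in df.itertuples(index=False):
        kwargs = {}
        for col, fld in _COL_TO_FIELD.items():
            val = str(getattr(r, col)).strip()
            kwargs[fld] = TriState(val) if val in ("Y", "N") else TriState.NA
        records.append(CriteriaRecord(pair_id=str(r.pair_id), **kwargs))
    return records


def write_criteria_matrix(records: list[CriteriaRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {"pair_id": rec.pair_id}
        for col, fld in _COL_TO_FIELD.items():
            v = getattr(rec, fld)
            row[col] = "" if v is TriState.NA else v.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    rows = []
    for rec in report.records:
        row = {"pair_id": rec.pair_id}
        for col, fld in _COL_TO_FIELD.items():
            v = getattr(rec, fld)
            row[col] = "" if v is TriState.NA else v.value
        row["eliminated_at"] = rec.eliminated_at or ""
        row["is_cis_sage"] = "Y" if rec.eliminated_at is None else "N"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    annotation: str
    fusions: str
    outdir: str
    cnv: Optional[str] = None
    peaks: Optional[str] = None
    coverage: Optional[str] = None
    fusion_expression: Optional[str] = None
    gene_expression: Optional[str] = None
    evidence: Optional[str] = None
    criteria_matrix: Optional[str] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    rules: RuleConfig = field(default_factory=RuleConfig)
    n_sim: int = 10_000
    seed: int = 0

    def required_paths(self) -> list[str]:
        paths = [self.annotation, self.fusions]
        for p in (
            self.cnv,
            self.peaks,
            self.coverage,
            self.fusion_expression,
            self.gene_expression,
            self.evidence,
            self.criteria_matrix,
        ):
            if p:
                paths.append(p)
        return paths

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_KNOWN_KEYS = {
    "annotation",
    "fusions",
    "outdir",
    "cnv",
    "peaks",
    "coverage",
    "fusion_expression",
    "gene_expression",
    "evidence",
    "criteria_matrix",
    "filter",
    "rules",
    "n_sim",
    "seed",
}


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "filter" in raw:
        raw["filter"] = FilterConfig(**raw["filter"])
    if "rules" in raw:
        raw["rules"] = RuleConfig(**raw["rules"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise InputError(f"invalid run config: {exc}") from exc


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers


def _read_tsv(path: str | Path, required: list[str], **kwargs) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except FileNotFoundError as exc:
        raise InputError(f"missing input file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df
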