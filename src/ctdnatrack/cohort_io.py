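"""Typed readers and writers for the pipeline's tabular formats.

All tables are headered TSV; plasma/PBMC call tables may alternatively be
VCF (parsed with cyvcf2, taking allele depths from the first sample's
AD/DP fields). Validation failures are reported with 1-based data-row line
numbers so a broken row can be located in the source file.
"""

from __future__ import annotations

import math
import os
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .types import (
    Arm,
    CNSegment,
    Compartment,
    Histology,
    NeoPeptide,
    PatientRecord,
    PlasmaCall,
    Smoking,
    Status,
    Variant,
)


class FormatError(ValueError):
    """The file cannot be interpreted at all (missing columns, bad header)."""


class TableValidationError(ValueError):
    """One or more rows violated a type invariant.

    ``rows`` maps 1-based data-row numbers to the offending message.
    """

    def __init__(self, path: str, rows: Dict[int, str]):
        self.path = path
        self.rows = rows
        detail = "; ".join(f"row {i}: {msg}" for i, msg in sorted(rows.items()))
        super().__init__(f"{path}: {detail}")


VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]
CALL_COLUMNS = VARIANT_COLUMNS + ["alt_reads", "depth"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_variant_table(
    path: Union[str, os.PathLike],
    compartment: Compartment = Compartment.PLASMA,
    sample_id: Optional[str] = None,
) -> Union[List[PlasmaCall], List[Variant]]:
    """Read a variant or call table from TSV or VCF.

    Returns :class:`PlasmaCall` records when read support is available
    (``alt_reads``/``depth`` columns, or VCF AD/DP), otherwise bare
    :class:`Variant` identities. Alleles are normalized on ingest.
    """
    path = os.fspath(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path, compartment, sample_id)

    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, VARIANT_COLUMNS, path)
    with_support = {"alt_reads", "depth"}.issubset(df.columns)

    records: list = []
    errors: Dict[int, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            gene = getattr(row, "gene", None)
            if gene is not None and (not isinstance(gene, str) or gene == ""):
                gene = None
            variant = Variant.normalized(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=gene,
            )
            if with_support:
                records.append(
                    PlasmaCall(
                        variant=variant,
                        alt_reads=int(row.alt_reads),
                        depth=int(row.depth),
                        sample_id=sample_id or str(getattr(row, "sample_id", "")),
                        compartment=Compartment(
                            getattr(row, "compartment", compartment)
                        ),
                    )
                )
            else:
                records.append(variant)
        except (ValueError, TypeError) as exc:
            errors[i] = str(exc)
    if errors:
        raise TableValidationError(path, errors)
    return records


def _read_vcf(
    path: str, compartment: Compartment, sample_id: Optional[str]
) -> List[PlasmaCall]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sid = sample_id or (vcf.samples[0] if vcf.samples else "")
    calls: List[PlasmaCall] = []
    errors: Dict[int, str] = {}
    for i, rec in enumerate(vcf, start=1):
        try:
            alt = rec.ALT[0]
            ad = rec.format("AD")
            if ad is None:
                raise ValueError("VCF record lacks AD field")
            alt_reads = int(ad[0][1])
            dp = rec.format("DP")
            depth = int(dp[0][0]) if dp is not None else int(ad[0].sum())
            calls.append(
                PlasmaCall(
                    variant=Variant.normalized(rec.CHROM, rec.POS, rec.REF, alt),
                    alt_reads=alt_reads,
                    depth=depth,
                    sample_id=sid,
                    compartment=compartment,
                )
            )
        except (ValueError, IndexError, TypeError) as exc:
            errors[i] = str(exc)
    if errors:
        raise TableValidationError(path, errors)
    return calls


def write_variant_table(
    records: Sequence[Union[PlasmaCall, Variant]], path: Union[str, os.PathLike]
) -> None:
    rows = []
    for rec in records:
        if isinstance(rec, PlasmaCall):
            v = rec.variant
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene or "",
                    "alt_reads": rec.alt_reads,
                    "depth": rec.depth,
                    "sample_id": rec.sample_id,
                    "compartment": rec.compartment.value,
                }
            )
        else:
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "gene": rec.gene or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = [
    "patient_id",
    "arm",
    "histology",
    "smoking",
    "tumor_size",
    "pd_l1_tc",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]


def read_clinical_table(
    path: Union[str, os.PathLike],
    column_map: Optional[Dict[str, str]] = None,
) -> List[PatientRecord]:
    """Read the per-patient clinical table.

    ``column_map`` renames source columns to the canonical names. Missing
    on-treatment ctDNA status is a first-class MISSING value, never
    imputed; duplicate patient ids and unknown categorical levels are
    rejected.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    _require_columns(df, CLINICAL_COLUMNS, path)
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"].unique())
        raise FormatError(f"{path}: duplicate patient_id(s) {dupes}")

    def _status(value) -> Status:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return Status.MISSING
        if str(value) in ("", "NA", "MISSING"):
            return Status.MISSING
        return Status(str(value))

    records: List[PatientRecord] = []
    errors: Dict[int, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    arm=Arm(str(row.arm)),
                    histology=Histology(str(row.histology)),
                    smoking=Smoking(str(row.smoking)),
                    tumor_size=float(row.tumor_size),
                    pd_l1_tc=float(row.pd_l1_tc),
                    pfs_time=float(row.pfs_time),
                    pfs_event=int(row.pfs_event),
                    os_time=float(row.os_time),
                    os_event=int(row.os_event),
                    ctdna_baseline=_status(getattr(row, "ctdna_baseline", None)),
                    ctdna_c3d1=_status(getattr(row, "ctdna_c3d1", None)),
                )
            )
        except ValueError as exc:
            errors[i] = str(exc)
    if errors:
        raise TableValidationError(path, errors)
    return records


def write_clinical_table(
    records: Sequence[PatientRecord], path: Union[str, os.PathLike]
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "arm": r.arm.value,
            "histology": r.histology.value,
            "smoking": r.smoking.value,
            "tumor_size": r.tumor_size,
            "pd_l1_tc": r.pd_l1_tc,
            "pfs_time": r.pfs_time,
            "pfs_event": r.pfs_event,
            "os_time": r.os_time,
            "os_event": r.os_event,
            "ctdna_baseline": r.ctdna_baseline.value,
            "ctdna_c3d1": r.ctdna_c3d1.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]


def segment_from_bed(
    chrom: str, start0: int, end: int, total_cn: int, minor_cn: int
) -> CNSegment:
    """Convert one BED-style half-open interval (0-based start) into the
    1-based inclusive convention used everywhere else. Applied exactly once
    on ingest."""
    return CNSegment(chrom=chrom, start=start0 + 1, end=end, total_cn=total_cn, minor_cn=minor_cn)


def read_segment_table(
    path: Union[str, os.PathLike], coords: str = "one_based"
) -> Union[List[CNSegment], Dict[str, List[CNSegment]]]:
    """Read a SEG-like TSV. With a ``patient_id`` column the result is a
    dict keyed by patient; otherwise a flat list. ``coords='bed'`` converts
    half-open 0-based intervals."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SEGMENT_COLUMNS, path)
    if coords not in ("one_based", "bed"):
        raise ValueError(f"unknown coords convention {coords!r}")

    def _make(row) -> CNSegment:
        args = (
            str(row.chrom),
            int(row.start),
            int(row.end),
            int(row.total_cn),
            int(row.minor_cn),
        )
        if coords == "bed":
            return segment_from_bed(*args)
        return CNSegment(*args)

    errors: Dict[int, str] = {}
    if "patient_id" in df.columns:
        out: Dict[str, List[CNSegment]] = {}
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                out.setdefault(str(row.patient_id), []).append(_make(row))
            except ValueError as exc:
                errors[i] = str(exc)
        if errors:
            raise TableValidationError(path, errors)
        return out
    segments: List[CNSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            segments.append(_make(row))
        except ValueError as exc:
            errors[i] = str(exc)
    if errors:
        raise TableValidationError(path, errors)
    return segments


def write_segment_table(
    segments: Union[Sequence[CNSegment], Dict[str, Sequence[CNSegment]]],
    path: Union[str, os.PathLike],
) -> None:
    rows = []
    if isinstance(segments, dict):
        for pid, segs in segments.items():
            for s in segs:
                rows.append(
                    {
                        "patient_id": pid,
                        "chrom": s.chrom,
                        "start": s.start,
                        "end": s.end,
                        "total_cn": s.total_cn,
                        "minor_cn": s.minor_cn,
                    }
                )
    else:
        for s in segments:
            rows.append(
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "total_cn": s.total_cn,
                    "minor_cn": s.minor_cn,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peptide_table(path: Union[str, os.PathLike]) -> List[NeoPeptide]:
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["peptide", "allele", "percentile_rank"], path)
    peptides: List[NeoPeptide] = []
    errors: Dict[int, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            peptides.append(
                NeoPeptide(str(row.peptide), str(row.allele), float(row.percentile_rank))
            )
        except ValueError as exc:
            errors[i] = str(exc)
    if errors:
        raise TableValidationError(path, errors)
    return peptides


def read_gene_list(path: Union[str, os.PathLike]) -> frozenset:
    """Plain-text list, one gene symbol per line; blank lines and lines
    starting with '#' ignored."""
    with open(path) as fh:
        return frozenset(
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        )
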