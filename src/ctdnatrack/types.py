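"""Domain types shared by every pipeline stage.

The central identity in a tumor-informed analysis is the :class:`Variant`:
a genomic alteration called in tumor tissue and subsequently looked up in
plasma. Identity is the normalized ``(chrom, pos, ref, alt)`` tuple —
annotations such as the gene symbol never participate in matching, so a
tissue call and a plasma call annotated by different tools still pair up.

Coordinates are 1-based inclusive throughout (VCF convention). BED-style
half-open intervals must be converted exactly once on ingest
(:func:`ctdnatrack.cohort_io.segment_from_bed`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Tuple



class VarType(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Compartment(str, enum.Enum):
    PLASMA = "PLASMA"
    PBMC = "PBMC"


class Arm(str, enum.Enum):
    ICI_CHEMO = "ICI_CHEMO"
    CHEMO = "CHEMO"


class Histology(str, enum.Enum):
    LUSC = "LUSC"
    NON_LUSC = "NON_LUSC"


class Smoking(str, enum.Enum):
    EVER = "EVER"
    NEVER = "NEVER"


class Status(str, enum.Enum):
    """ctDNA status of one sample (or a missing timepoint)."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    MISSING = "MISSING"


def normalize_allele(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Normalize an allele pair: uppercase, then left-align by trimming the
    shared suffix and shared prefix (prefix trimming shifts ``pos``).

    This is the minimal parsimonious representation used for indel matching
    between exome-derived tissue calls and panel-derived plasma calls.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class Variant:
    """A genomic alteration identity (SNV or indel).

    ``var_type`` is derived from the alleles and ``gene`` is annotation
    only; neither participates in equality or hashing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: VarType = field(default=None, compare=False)  # type: ignore[assignment]
    gene: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        inferred = (
            VarType.SNV if len(self.ref) == 1 and len(self.alt) == 1 else VarType.INDEL
        )
        if self.var_type is None:
            object.__setattr__(self, "var_type", inferred)
        elif self.var_type != inferred:
            raise ValueError(
                f"var_type {self.var_type} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )

    @classmethod
    def normalized(
        cls, chrom: str, pos: int, ref: str, alt: str, gene: Optional[str] = None
    ) -> "Variant":
        pos, ref, alt = normalize_allele(pos, ref, alt)
        return cls(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PlasmaCall:
    """One variant observation in a plasma or PBMC sample."""

    variant: Variant
    alt_reads: int
    depth: int
    sample_id: str = ""
    compartment: Compartment = Compartment.PLASMA
    af: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
            )
        computed = self.alt_reads / self.depth
        if self.af is None:
            object.__setattr__(self, "af", computed)
        elif abs(self.af - computed) >= 1e-9:
            raise ValueError(
                f"af {self.af} inconsistent with alt_reads/depth {computed}"
            )


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number segment (1-based inclusive bp)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > (self.total_cn + 1) // 2:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds half of total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity: minor allele absent with at least one
        copy retained (includes copy-neutral LOH)."""
        return self.minor_cn == 0 and self.total_cn >= 1


@dataclass
class TissueProfile:
    """Per-patient tumor tissue summary: the tracked mutation set plus the
    inputs to mutational-burden and instability indices."""

    patient_id: str
    variants: FrozenSet[Variant]
    nonsyn_count: int = 0
    purity: float = 1.0
    ploidy: float = 2.0
    segments: List[CNSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = frozenset(self.variants)
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


@dataclass
class PatientRecord:
    """Clinical covariates and survival outcomes for one trial patient."""

    patient_id: str
    arm: Arm
    histology: Histology
    smoking: Smoking
    tumor_size: float  # longest diameter, mm
    pd_l1_tc: float  # tumor-cell PD-L1 expression, percent
    pfs_time: float  # months
    pfs_event: int
    os_time: float  # months
    os_event: int
    ctdna_baseline: Status = Status.MISSING
    ctdna_c3d1: Status = Status.MISSING

    def __post_init__(self) -> None:
        if self.pfs_time < 0 or self.os_time < 0:
            raise ValueError(
                f"{self.patient_id}: survival times must be non-negative"
            )
        if self.pfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError(f"{self.patient_id}: events must be 0/1")
        if self.tumor_size <= 0:
            raise ValueError(f"{self.patient_id}: tumor size must be positive")


@dataclass(frozen=True)
class NeoPeptide:
    """A predicted MHC class I peptide with its percentile binding rank."""

    peptide: str
    allele: str
    percentile_rank: float

    def __post_init__(self) -> None:
        if not 9 <= len(self.peptide) <= 10:
            raise ValueError(
                f"peptide must be a 9- or 10-mer, got {len(self.peptide)} aa"
            )
        if self.percentile_rank < 0:
            raise ValueError("percentile rank must be non-negative")


def variant_keys(variants: Sequence[Variant]) -> FrozenSet[Tuple[str, int, str, str]]:
    return frozenset(v.key for v in variants)
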