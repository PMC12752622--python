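"""Plasma call filters.

The fixed composition order is support -> population SNP -> matched-PBMC
exclusion. Read-level criteria (mapping quality >= 60, at most 8 mismatches
per read) act upstream of the variant tables this pipeline consumes; they
are carried in :class:`FilterConfig` as recorded metadata and as parameters
of the read simulator, not re-applied here.

Clonal hematopoiesis (CH) handling is two-layered: variants observed in the
matched PBMC compartment are presumed germline/CH and removed outright,
while a configurable CH gene list is used only to *flag* plasma-only calls
whose gene is CH-associated (undetected CH), feeding the "CH-only patient"
statistic rather than any exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Sequence, Tuple

from . import defaults
from .types import Compartment, PlasmaCall, VarType, Variant

#: Shipped stand-in for the CH-associated gene list (the assay's full
#: 21-gene list is proprietary); configurable via ``FilterConfig``.
DEFAULT_CHIP_GENES: FrozenSet[str] = frozenset(
    {"DNMT3A", "TET2", "ASXL1", "NOTCH1", "IDH2", "CALR", "CCND3", "JAK2", "PPM1D"}
)


@dataclass(frozen=True)
class FilterConfig:
    min_snv_reads: int = defaults.MIN_SNV_READS
    min_indel_reads: int = defaults.MIN_INDEL_READS
    min_mapq: int = defaults.MIN_MAPQ
    max_mismatches: int = defaults.MAX_MISMATCHES
    population_blacklist: FrozenSet[Variant] = frozenset()
    chip_genes: FrozenSet[str] = DEFAULT_CHIP_GENES

    def __post_init__(self) -> None:
        if self.min_snv_reads < 1 or self.min_indel_reads < 1:
            raise ValueError("support thresholds must be >= 1")


def support_filter(
    calls: Sequence[PlasmaCall], cfg: FilterConfig = FilterConfig()
) -> List[PlasmaCall]:
    """Keep SNVs with >= ``min_snv_reads`` and indels with >=
    ``min_indel_reads`` supporting reads; order preserved."""
    out = []
    for c in calls:
        threshold = (
            cfg.min_snv_reads
            if c.variant.var_type == VarType.SNV
            else cfg.min_indel_reads
        )
        if c.alt_reads >= threshold:
            out.append(c)
    return out


def population_snp_filter(
    calls: Sequence[PlasmaCall], blacklist: Iterable[Variant]
) -> List[PlasmaCall]:
    """Remove calls whose variant identity matches a known common
    polymorphism (stand-in for 1000 Genomes / ExAC / dbSNP membership)."""
    keys = {v.key for v in blacklist}
    return [c for c in calls if c.variant.key not in keys]


def pbmc_exclusion(
    plasma_calls: Sequence[PlasmaCall], pbmc_calls: Sequence[PlasmaCall]
) -> Tuple[List[PlasmaCall], List[PlasmaCall]]:
    """Partition plasma calls into (somatic, excluded).

    Any plasma variant also called in the matched PBMC sample is presumed
    germline or clonal hematopoiesis and moved to ``excluded``. The
    partition is exact: every input call lands in exactly one output.
    """
    for c in plasma_calls:
        if c.compartment != Compartment.PLASMA:
            raise ValueError(
                f"non-plasma call passed as plasma: {c.variant.key} ({c.compartment})"
            )
    for c in pbmc_calls:
        if c.compartment != Compartment.PBMC:
            raise ValueError(
                f"non-PBMC call passed as PBMC: {c.variant.key} ({c.compartment})"
            )
    pbmc_keys = {c.variant.key for c in pbmc_calls}
    somatic = [c for c in plasma_calls if c.variant.key not in pbmc_keys]
    excluded = [c for c in plasma_calls if c.variant.key in pbmc_keys]
    return somatic, excluded


def flag_chip_genes(
    calls: Sequence[PlasmaCall], chip_genes: Iterable[str] = DEFAULT_CHIP_GENES
) -> List[bool]:
    """Per-call flag: gene annotation is CH-associated. Annotation only —
    flagged calls are never removed here."""
    genes = set(chip_genes)
    return [c.variant.gene in genes for c in calls]


def is_ch_only(
    calls: Sequence[PlasmaCall], chip_genes: Iterable[str] = DEFAULT_CHIP_GENES
) -> bool:
    """True when a patient's plasma calls are non-empty and every call sits
    in a CH-associated gene (the likely-false-positive pattern of the
    tumor-naive approach)."""
    flags = flag_chip_genes(calls, chip_genes)
    return bool(flags) and all(flags)


@dataclass
class FilterResult:
    """Outcome of the full filter chain with per-stage accounting.

    ``somatic`` has the de novo support thresholds applied and feeds
    tumor-naive calling. ``somatic_all_reads`` is the same population- and
    PBMC-filtered set *without* the support thresholds: tumor-informed
    tracking applies its own, lower, read rule to known variants, which is
    what lets it detect allele fractions well below the de novo floor.
    """

    somatic: List[PlasmaCall]
    somatic_all_reads: List[PlasmaCall]
    removed_support: int
    removed_population: int
    excluded_pbmc: List[PlasmaCall] = field(default_factory=list)


def apply_filters(
    plasma_calls: Sequence[PlasmaCall],
    pbmc_calls: Sequence[PlasmaCall] = (),
    cfg: FilterConfig = FilterConfig(),
) -> FilterResult:
    """Run the fixed filter chain: support -> population SNP -> PBMC."""
    after_support = support_filter(plasma_calls, cfg)
    after_pop = population_snp_filter(after_support, cfg.population_blacklist)
    somatic, excluded = pbmc_exclusion(after_pop, pbmc_calls)
    unthresholded = population_snp_filter(plasma_calls, cfg.population_blacklist)
    somatic_all, _ = pbmc_exclusion(unthresholded, pbmc_calls)
    return FilterResult(
        somatic=somatic,
        somatic_all_reads=somatic_all,
        removed_support=len(plasma_calls) - len(after_support),
        removed_population=len(after_support) - len(after_pop),
        excluded_pbmc=excluded,
    )
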