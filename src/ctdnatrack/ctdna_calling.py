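"""Core ctDNA status calling.

Two routes to a positive/negative call for one plasma sample:

* **Tumor-informed** — the patient's tissue mutations are looked up in the
  (filtered) plasma call set; one or more tracked variants with at least
  ``tracked_min_reads`` supporting reads makes the sample positive. Prior
  knowledge of the variant allows a lower evidence bar than de novo
  calling, which is what pushes the informed limit of detection well below
  the 0.5% assay LOD.
* **Tumor-naive** — no tissue prior; the sample is positive when any fully
  filtered call reaches the assay's allele-fraction LOD (default 0.5%).

Per-sample quantitative metrics: MSAF (maximum somatic allele fraction over
the detected/somatic calls) and MTM/mL (mean tumor molecules per milliliter
plasma, the mean tracked allele fraction scaled by cfDNA genome
equivalents).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

import pandas as pd

from . import defaults
from .types import PlasmaCall, Status, TissueProfile, Variant
from .util import percent


class Method(str, enum.Enum):
    INFORMED = "INFORMED"
    NAIVE = "NAIVE"


class ConcordanceCategory(str, enum.Enum):
    CONCORDANT_POS = "CONCORDANT_POS"
    CONCORDANT_NEG = "CONCORDANT_NEG"
    INFORMED_ONLY = "INFORMED_ONLY"
    NAIVE_ONLY = "NAIVE_ONLY"


class NotEvaluableError(ValueError):
    """The patient has no tissue mutation profile to track."""


@dataclass
class CtdnaResult:
    sample_id: str
    method: Method
    status: Status
    detected_variants: FrozenSet[Variant] = frozenset()
    msaf: float = 0.0
    mean_af: float = 0.0
    mtm_per_ml: Optional[float] = None
    detected_calls: Tuple[PlasmaCall, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        self.detected_variants = frozenset(self.detected_variants)
        positive = self.status == Status.POSITIVE
        if positive != bool(self.detected_variants):
            raise ValueError(
                "status and detected variant set are inconsistent for "
                f"{self.sample_id}"
            )
        if self.mean_af > self.msaf + 1e-12:
            raise ValueError("mean AF cannot exceed the maximum AF")


def compute_msaf(calls: Sequence[PlasmaCall]) -> float:
    """Maximum somatic allele fraction; 0 for an empty call set."""
    return max((c.af for c in calls), default=0.0)


def compute_mean_af(calls: Sequence[PlasmaCall]) -> float:
    if not calls:
        return 0.0
    return sum(c.af for c in calls) / len(calls)


def compute_mtm_per_ml(
    calls: Sequence[PlasmaCall],
    cfdna_ng_per_ml: float,
    ng_per_genome: float = defaults.NG_PER_HAPLOID_GENOME,
) -> float:
    """ctDNA concentration as mean tumor molecules per mL plasma.

    mean AF x (cfDNA ng/mL / ng per haploid genome equivalent). The genome
    mass constant (default 0.0033 ng) is exposed so alternative conventions
    can be recorded in run metadata.
    """
    if cfdna_ng_per_ml <= 0:
        raise ValueError("cfDNA concentration must be positive")
    if not calls:
        return 0.0
    return compute_mean_af(calls) * cfdna_ng_per_ml / ng_per_genome


def _result(
    sample_id: str,
    method: Method,
    detected: Sequence[PlasmaCall],
    cfdna_ng_per_ml: Optional[float],
) -> CtdnaResult:
    mtm = (
        compute_mtm_per_ml(detected, cfdna_ng_per_ml)
        if cfdna_ng_per_ml is not None
        else None
    )
    return CtdnaResult(
        sample_id=sample_id,
        method=method,
        status=Status.POSITIVE if detected else Status.NEGATIVE,
        detected_variants=frozenset(c.variant for c in detected),
        msaf=compute_msaf(detected),
        mean_af=compute_mean_af(detected),
        mtm_per_ml=mtm,
        detected_calls=tuple(detected),
    )


def call_tumor_informed(
    tissue: TissueProfile,
    plasma_calls: Sequence[PlasmaCall],
    tracked_min_reads: int = defaults.TRACKED_MIN_READS,
    sample_id: Optional[str] = None,
    cfdna_ng_per_ml: Optional[float] = None,
) -> CtdnaResult:
    """Tumor-informed call: positive iff >= 1 tissue-tracked variant is
    seen in plasma with at least ``tracked_min_reads`` supporting reads.

    ``plasma_calls`` must already be support/population filtered with PBMC
    exclusion applied. MSAF is computed over the detected tracked calls
    only.
    """
    if not tissue.variants:
        raise NotEvaluableError(
            f"{tissue.patient_id}: empty tissue variant set, "
            "patient is not biomarker-evaluable"
        )
    tracked = {v.key for v in tissue.variants}
    detected = [
        c
        for c in plasma_calls
        if c.variant.key in tracked and c.alt_reads >= tracked_min_reads
    ]
    sid = sample_id or (plasma_calls[0].sample_id if plasma_calls else tissue.patient_id)
    return _result(sid, Method.INFORMED, detected, cfdna_ng_per_ml)


def call_tumor_naive(
    plasma_calls: Sequence[PlasmaCall],
    lod: float = defaults.NAIVE_LOD,
    sample_id: Optional[str] = None,
    cfdna_ng_per_ml: Optional[float] = None,
) -> CtdnaResult:
    """Tumor-naive call: positive iff any fully filtered call reaches the
    assay allele-fraction LOD (default 0.5%)."""
    detected = [c for c in plasma_calls if c.af >= lod]
    sid = sample_id or (plasma_calls[0].sample_id if plasma_calls else "")
    return _result(sid, Method.NAIVE, detected, cfdna_ng_per_ml)


def classify_concordance(
    informed: CtdnaResult, naive: CtdnaResult
) -> ConcordanceCategory:
    """Map one sample's (informed, naive) status pair onto the 2x2 grid."""
    if informed.method != Method.INFORMED or naive.method != Method.NAIVE:
        raise ValueError(
            f"expected (INFORMED, NAIVE) results, got "
            f"({informed.method}, {naive.method})"
        )
    pos_i = informed.status == Status.POSITIVE
    pos_n = naive.status == Status.POSITIVE
    if pos_i and pos_n:
        return ConcordanceCategory.CONCORDANT_POS
    if pos_i:
        return ConcordanceCategory.INFORMED_ONLY
    if pos_n:
        return ConcordanceCategory.NAIVE_ONLY
    return ConcordanceCategory.CONCORDANT_NEG


def concordance_summary(categories: Iterable[ConcordanceCategory]) -> Dict[str, float]:
    """Aggregate per-sample categories into counts and the concordance
    percentage (half-up, 1 decimal)."""
    counts = Counter(categories)
    n = sum(counts.values())
    concordant = (
        counts[ConcordanceCategory.CONCORDANT_POS]
        + counts[ConcordanceCategory.CONCORDANT_NEG]
    )
    summary: Dict[str, float] = {c.value: counts[c] for c in ConcordanceCategory}
    summary["n"] = n
    summary["concordant"] = concordant
    summary["concordance_pct"] = percent(concordant, n) if n else 0.0
    return summary


def concordance_from_counts(
    n_total: int, n_informed_only: int, n_naive_only: int
) -> Dict[str, float]:
    """Concordance arithmetic from marginal counts alone (the form in
    which published 2x2 discordance tables are reported)."""
    if n_informed_only + n_naive_only > n_total:
        raise ValueError("discordant counts exceed the total")
    concordant = n_total - n_informed_only - n_naive_only
    return {
        "n": n_total,
        "INFORMED_ONLY": n_informed_only,
        "NAIVE_ONLY": n_naive_only,
        "concordant": concordant,
        "concordance_pct": percent(concordant, n_total),
    }


def cohort_rates(results: Iterable[CtdnaResult]) -> pd.DataFrame:
    """Per-method positivity counts and percentages (1 decimal)."""
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for method in Method:
        subset = [r for r in results if r.method == method]
        if not subset:
            continue
        pos = sum(r.status == Status.POSITIVE for r in subset)
        rows.append(
            {
                "method": method.value,
                "n": len(subset),
                "positive": pos,
                "positivity_pct": percent(pos, len(subset)),
            }
        )
    return pd.DataFrame(rows)
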