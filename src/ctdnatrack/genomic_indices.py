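"""Tumor-level genomic indices compared between ctDNA groups.

* TMB — count of nonsynonymous somatic mutations (raw count by default,
  optionally per Mb given a footprint size).
* Neoantigen binder counts — a peptide is a predicted binder when its best
  (minimum) percentile rank over the patient's MHC-I alleles is <= 2;
  strong binders additionally have min rank <= 0.5, the remainder of the
  binders are weak. Each peptide is counted once.
* wGII — weighted genome instability index: per-chromosome fraction of
  covered length at a copy number different from the rounded sample
  ploidy, averaged over covered chromosomes (a pooled genome-wide variant
  is available behind a flag). Ties in ploidy rounding go half-to-even.
* LOH fraction and HRD-LOH — LOH means minor copy number 0 with at least
  one copy retained (copy-neutral LOH included). The HRD-LOH score counts
  LOH segments longer than 15 Mb that do not span their whole chromosome.
  Adjacent LOH segments are not merged across gaps by default; an optional
  ``merge_gap`` exposes the alternative.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import defaults
from .types import CNSegment, NeoPeptide

#: Consequence classes counted by TMB.
NONSYNONYMOUS = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "splice_site",
        "stop_lost",
        "start_lost",
        "nonsynonymous",
    }
)
#: Consequence classes excluded from TMB.
SYNONYMOUS = frozenset({"synonymous", "silent", "intronic", "utr", "intergenic"})


def compute_tmb(
    consequences: Union[pd.DataFrame, Iterable[Optional[str]]],
    footprint_mb: Optional[float] = None,
) -> float:
    """Count of nonsynonymous mutations; per Mb when ``footprint_mb`` is
    given. Accepts a DataFrame with a ``consequence`` column or an
    iterable of consequence labels; missing or unknown labels are errors.
    """
    if isinstance(consequences, pd.DataFrame):
        if "consequence" not in consequences.columns:
            raise ValueError("mutation table lacks a 'consequence' column")
        consequences = consequences["consequence"].tolist()
    count = 0
    for i, c in enumerate(consequences, start=1):
        if c is None or (isinstance(c, float) and np.isnan(c)):
            raise ValueError(f"mutation {i} lacks a consequence annotation")
        label = str(c).lower()
        if label in NONSYNONYMOUS:
            count += 1
        elif label not in SYNONYMOUS:
            raise ValueError(f"unknown consequence class {c!r} at mutation {i}")
    if footprint_mb is not None:
        if footprint_mb <= 0:
            raise ValueError("footprint must be positive")
        return count / footprint_mb
    return count


def count_neoantigen_binders(
    peptides: Sequence[NeoPeptide],
    rank_cut: float = defaults.NEO_RANK_CUT,
    strong_cut: float = defaults.NEO_STRONG_CUT,
) -> Tuple[int, int, int]:
    """(binders, strong, weak) over unique peptides using the minimum rank
    across alleles."""
    best: Dict[str, float] = {}
    for p in peptides:
        best[p.peptide] = min(best.get(p.peptide, np.inf), p.percentile_rank)
    binders = sum(r <= rank_cut for r in best.values())
    strong = sum(r <= strong_cut for r in best.values())
    weak = binders - strong
    return binders, strong, weak


def _check_disjoint(segments: Sequence[CNSegment]) -> Dict[str, List[CNSegment]]:
    by_chrom: Dict[str, List[CNSegment]] = defaultdict(list)
    for s in segments:
        by_chrom[s.chrom].append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )
    return by_chrom


def compute_wgii(
    segments: Sequence[CNSegment],
    ploidy: float,
    per_chromosome: bool = True,
) -> float:
    """Fraction of the covered genome at aberrant total copy number.

    Aberrant means total_cn != round(ploidy) with ties rounded half to
    even. Default is the weighted convention — aberrant fraction per
    chromosome, averaged over chromosomes with any coverage — so long and
    short chromosomes contribute equally; ``per_chromosome=False`` pools
    genome-wide.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if not segments:
        return 0.0
    reference_cn = int(np.rint(ploidy))
    by_chrom = _check_disjoint(segments)
    fractions = []
    total_len = 0
    aberrant_len = 0
    for segs in by_chrom.values():
        covered = sum(s.length for s in segs)
        aberrant = sum(s.length for s in segs if s.total_cn != reference_cn)
        fractions.append(aberrant / covered)
        total_len += covered
        aberrant_len += aberrant
    if per_chromosome:
        return float(np.mean(fractions))
    return aberrant_len / total_len


def compute_loh_fraction(segments: Sequence[CNSegment]) -> float:
    """Covered-length fraction with the minor allele lost."""
    if not segments:
        return 0.0
    _check_disjoint(segments)
    total = sum(s.length for s in segments)
    loh = sum(s.length for s in segments if s.is_loh)
    return loh / total


def _merge_loh(
    segs: Sequence[CNSegment], merge_gap: int
) -> List[Tuple[int, int]]:
    spans: List[Tuple[int, int]] = []
    for s in sorted(segs, key=lambda s: s.start):
        if spans and s.start - spans[-1][1] - 1 <= merge_gap:
            spans[-1] = (spans[-1][0], max(spans[-1][1], s.end))
        else:
            spans.append((s.start, s.end))
    return spans


def compute_hrd_loh(
    segments: Sequence[CNSegment],
    chrom_lengths: Mapping[str, int],
    min_mb: float = defaults.HRD_LOH_MIN_MB,
    merge_gap: Optional[int] = None,
) -> int:
    """HRD-LOH score: count of LOH segments longer than ``min_mb`` Mb that
    do not span their entire chromosome."""
    by_chrom = _check_disjoint(segments)
    min_bp = min_mb * 1e6
    score = 0
    for chrom, segs in by_chrom.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length provided for {chrom}")
        clen = chrom_lengths[chrom]
        for s in segs:
            if s.end > clen:
                raise ValueError(
                    f"segment {s.start}-{s.end} exceeds {chrom} length {clen}"
                )
        loh_segs = [s for s in segs if s.is_loh]
        if merge_gap is not None:
            spans = _merge_loh(loh_segs, merge_gap)
        else:
            spans = [(s.start, s.end) for s in loh_segs]
        for start, end in spans:
            length = end - start + 1
            if length > min_bp and not (start == 1 and end == clen):
                score += 1
    return score


def index_table(
    per_patient: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Assemble per-patient index dicts into one tidy table."""
    rows = [{"patient_id": pid, **vals} for pid, vals in per_patient.items()]
    return pd.DataFrame(rows)
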