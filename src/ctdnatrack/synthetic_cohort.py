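"""Seedable synthetic trial cohort generator.

Emulates the data structure of a randomized advanced-NSCLC trial with
tumor-informed ctDNA tracking, so that the full pipeline is exercisable
without any patient-level download:

* per-patient tissue mutation sets (exome-scale burden, panel-tracked
  variants) with allele-specific copy-number segments and predicted
  neoantigen peptide tables;
* a log-linear shedding law — log10 MSAF is linear in log10 tumor size
  with a squamous-histology shift plus Gaussian noise — with a configured
  fraction of biological non-shedders (true MSAF 0);
* plasma read counts binomially sampled at ~10,000x for each tracked
  variant (per-variant allele fractions are the patient MSAF scaled by a
  Beta-distributed relative clonality, so MSAF is the maximum by
  construction), CHIP variants injected into plasma AND the matched PBMC
  sample at ~2,000x;
* exponential survival with a treatment x true-ctDNA-status interaction
  at the configured stratum hazard ratios and administrative censoring;
* an on-treatment (C3D1) plasma draw for a configurable subset, with
  arm-specific clearance probabilities.

All randomness flows through a single ``numpy.random.Generator``; no
global state is touched, and the same seed reproduces the cohort exactly.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import defaults
from .ctdna_calling import call_tumor_informed, call_tumor_naive
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
    TissueProfile,
    Variant,
)
from .variant_filtering import DEFAULT_CHIP_GENES, FilterConfig, apply_filters

#: Approximate autosome lengths, bp (GRCh37 scale).
CHROM_LENGTHS: Dict[str, int] = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 136_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000,
}

_TUMOR_GENES = (
    "TP53", "EGFR", "KRAS", "KEAP1", "STK11", "LRP1B", "PIK3CA", "BRAF",
    "CDKN2A", "RB1", "NF1", "SMARCA4", "ARID1A", "MET", "ERBB2", "FAT1",
)
_CH_GENES = tuple(sorted(DEFAULT_CHIP_GENES))
_ALLELES = ("HLA-A*02:01", "HLA-A*11:01", "HLA-B*07:02", "HLA-C*07:01")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Stratum hazard ratios default to the trial's reported treatment
    effects (PFS 0.45 / 0.74 and OS 0.66 / 1.13 in the ctDNA-positive /
    -negative strata); the chemotherapy-arm medians (8 months PFS, 17
    months OS) set a plausible advanced-NSCLC scale.
    """

    n_patients: int = 393
    allocation_ratio: Tuple[int, int] = (2, 1)  # ICI_CHEMO : CHEMO
    plasma_depth: int = defaults.PLASMA_DEPTH
    pbmc_depth: int = defaults.PBMC_DEPTH
    # shedding law on log10 MSAF: intercept + slope*log10(size_mm) + lusc
    shedding_beta: Tuple[float, float, float] = (-3.0, 1.2, 0.4)
    shedding_sigma: float = 0.5
    nonshedder_fraction: float = 0.24
    lusc_fraction: float = 0.30
    smoker_fraction: float = 0.70
    tumor_size_log_mean: float = math.log(40.0)  # mm
    tumor_size_log_sd: float = 0.45
    tracked_mean: float = 12.0  # tracked variants per patient (>=1)
    chip_rate: float = 0.25
    chip_log10_af_mean: float = -1.8
    chip_log10_af_sd: float = 0.3
    chip_pbmc_detect_prob: float = 1.0
    hr_pfs_pos: float = 0.45
    hr_pfs_neg: float = 0.74
    hr_os_pos: float = 0.66
    hr_os_neg: float = 1.13
    chemo_median_pfs: float = 8.0  # months
    chemo_median_os: float = 17.0
    pfs_horizon: float = 30.0  # administrative censoring, months
    os_horizon: float = 48.0
    clearance_prob: Dict[str, float] = field(
        default_factory=lambda: {"ICI_CHEMO": 0.40, "CHEMO": 0.15}
    )
    turn_positive_prob: float = 0.05
    c3d1_availability: float = 91.0 / 393.0

    def validate(self) -> None:
        probs = [
            self.nonshedder_fraction, self.lusc_fraction, self.smoker_fraction,
            self.chip_rate, self.chip_pbmc_detect_prob, self.turn_positive_prob,
            self.c3d1_availability, *self.clearance_prob.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.hr_pfs_pos, self.hr_pfs_neg, self.hr_os_pos, self.hr_os_neg) <= 0:
            raise ValueError("hazard ratios must be positive")
        if self.plasma_depth <= 0 or self.pbmc_depth <= 0:
            raise ValueError("depths must be positive")
        if self.shedding_sigma < 0:
            raise ValueError("shedding sigma must be non-negative")


@dataclass
class Cohort:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SimConfig
    seed: int
    clinical: List[PatientRecord]
    tissue: Dict[str, TissueProfile]
    plasma_c1d1: Dict[str, List[PlasmaCall]]
    plasma_c3d1: Dict[str, List[PlasmaCall]]
    pbmc: Dict[str, List[PlasmaCall]]
    peptides: Dict[str, List[NeoPeptide]]
    truth: pd.DataFrame


def _random_variant(rng: np.random.Generator, gene: str, used: set) -> Variant:
    while True:
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1, CHROM_LENGTHS[chrom] - 1))
        ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        if ref == alt:
            continue
        key = (chrom, pos, ref, alt)
        if key in used:
            continue
        used.add(key)
        return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)


def _sample_reads(
    rng: np.random.Generator,
    variants: Sequence[Variant],
    afs: Sequence[float],
    depth: int,
    sample_id: str,
    compartment: Compartment,
) -> List[PlasmaCall]:
    calls = []
    for v, af in zip(variants, afs):
        alt = int(rng.binomial(depth, min(af, 1.0)))
        if alt >= 1:
            calls.append(
                PlasmaCall(
                    variant=v, alt_reads=alt, depth=depth,
                    sample_id=sample_id, compartment=compartment,
                )
            )
    return calls


def _segments_for_patient(
    rng: np.random.Generator, shedder: bool
) -> Tuple[List[CNSegment], float]:
    """Copy-number segments with instability coupled to shedding status
    (ctDNA-positive tumors carry more aberrant genome and LOH)."""
    p_aberrant = float(rng.beta(3, 4)) if shedder else float(rng.beta(2, 7))
    p_loh = 0.6 * p_aberrant
    segments = []
    for chrom, clen in CHROM_LENGTHS.items():
        breakpoint_ = int(rng.integers(int(clen * 0.3), int(clen * 0.7)))
        for start, end in ((1, breakpoint_), (breakpoint_ + 1, clen)):
            if rng.random() < p_aberrant:
                total_cn = int(rng.choice([1, 3, 4]))
            else:
                total_cn = 2
            if total_cn == 1:
                minor_cn = 0
            elif rng.random() < p_loh:
                minor_cn = 0
            else:
                minor_cn = 1
            segments.append(
                CNSegment(chrom=chrom, start=start, end=end,
                          total_cn=total_cn, minor_cn=minor_cn)
            )
    ploidy = 2.0 + float(rng.normal(0.4 if shedder else 0.1, 0.15))
    return segments, max(ploidy, 1.2)


def _peptides_for_patient(
    rng: np.random.Generator, nonsyn: int, shedder: bool
) -> List[NeoPeptide]:
    lam = nonsyn * (1.0 if shedder else 0.7)
    n = int(rng.poisson(lam * 0.6))
    peptides = []
    for _ in range(n):
        length = int(rng.choice([9, 10]))
        pep = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))
        allele = _ALLELES[rng.integers(len(_ALLELES))]
        rank = float(rng.lognormal(math.log(3.0), 1.0))
        peptides.append(NeoPeptide(pep, allele, rank))
    return peptides


def simulate_stratum_survival(
    n: int,
    hr: float,
    control_median: float,
    horizon: float,
    rng: np.random.Generator,
    allocation_ratio: Tuple[int, int] = (2, 1),
) -> pd.DataFrame:
    """Two-arm exponential survival for one biomarker stratum.

    Treatment assignment follows the allocation ratio; event times are
    exponential with the control-arm median setting the baseline hazard
    and ``hr`` acting multiplicatively in the treated arm; censoring is
    administrative at ``horizon`` months. Returns columns
    ``treated, time, event``.
    """
    a, b = allocation_ratio
    treated = rng.random(n) < a / (a + b)
    lam0 = math.log(2) / control_median
    lam = np.where(treated, lam0 * hr, lam0)
    t = rng.exponential(1.0 / lam)
    event = (t <= horizon).astype(int)
    time = np.minimum(t, horizon)
    return pd.DataFrame({"treated": treated.astype(int), "time": time, "event": event})


def generate_tracerx_standin(
    n: int = 521,
    beta: Tuple[float, float, float] = (-3.0, 1.2, 0.4),
    sigma: float = 0.5,
    seed: int = 0,
    lusc_fraction: float = 0.3,
) -> pd.DataFrame:
    """Training table for the shedding regression.

    A synthetic stand-in for the early-stage multi-region cohort used to
    train the published shedding model (whose patient-level data are
    gated): rows follow the stated log-linear law exactly, so fitted
    coefficients are placeholders for the real ones, not estimates of
    them.
    """
    if n < 10:
        raise ValueError("need at least 10 training rows")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    size = np.exp(rng.normal(math.log(35.0), 0.5, size=n))  # mm
    lusc = rng.random(n) < lusc_fraction
    mu = beta[0] + beta[1] * np.log10(size) + beta[2] * lusc
    log_msaf = mu + sigma * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "tumor_size": size,
            "histology": np.where(lusc, "LUSC", "NON_LUSC"),
            "msaf": 10.0 ** log_msaf,
        }
    )


def generate_cohort(cfg: SimConfig, seed: int = 0) -> Cohort:
    """Generate one full synthetic cohort. Deterministic given ``seed``."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    a, b = cfg.allocation_ratio

    clinical: List[PatientRecord] = []
    tissue: Dict[str, TissueProfile] = {}
    plasma_c1: Dict[str, List[PlasmaCall]] = {}
    plasma_c3: Dict[str, List[PlasmaCall]] = {}
    pbmc: Dict[str, List[PlasmaCall]] = {}
    peptides: Dict[str, List[NeoPeptide]] = {}
    truth_rows = []
    used_keys: set = set()

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        arm = Arm.ICI_CHEMO if rng.random() < a / (a + b) else Arm.CHEMO
        lusc = rng.random() < cfg.lusc_fraction
        histology = Histology.LUSC if lusc else Histology.NON_LUSC
        smoking = Smoking.EVER if rng.random() < cfg.smoker_fraction else Smoking.NEVER
        size = float(np.exp(rng.normal(cfg.tumor_size_log_mean, cfg.tumor_size_log_sd)))
        pd_l1 = float(rng.choice([0.0, 1.0, 5.0, 25.0, 50.0, 80.0]))

        shedder = rng.random() >= cfg.nonshedder_fraction
        if shedder:
            mu = (
                cfg.shedding_beta[0]
                + cfg.shedding_beta[1] * math.log10(size)
                + cfg.shedding_beta[2] * lusc
            )
            msaf = min(10.0 ** (mu + cfg.shedding_sigma * rng.standard_normal()), 0.4)
        else:
            msaf = 0.0

        # tissue profile
        n_tracked = max(1, int(rng.poisson(cfg.tracked_mean)))
        genes = [ _TUMOR_GENES[g] for g in rng.integers(0, len(_TUMOR_GENES), n_tracked) ]
        variants = [_random_variant(rng, g, used_keys) for g in genes]
        nonsyn = int(rng.poisson(180 if shedder else 110))
        segments, ploidy = _segments_for_patient(rng, shedder)
        tissue[pid] = TissueProfile(
            patient_id=pid,
            variants=frozenset(variants),
            nonsyn_count=nonsyn,
            purity=float(np.clip(rng.beta(6, 3), 0.15, 1.0)),
            ploidy=ploidy,
            segments=segments,
        )
        peptides[pid] = _peptides_for_patient(rng, nonsyn, shedder)

        # tracked allele fractions: max is MSAF by construction
        if shedder and n_tracked > 1:
            rel = rng.beta(2, 3, size=n_tracked - 1)
            afs = np.concatenate([[msaf], msaf * rel])
        else:
            afs = np.full(n_tracked, msaf)

        sample_c1 = f"{pid}_C1D1"
        calls_c1 = _sample_reads(
            rng, variants, afs, cfg.plasma_depth, sample_c1, Compartment.PLASMA
        )

        # CHIP: shared identity in plasma and (usually) PBMC
        chip_variants: List[Variant] = []
        chip_afs: List[float] = []
        pbmc_calls: List[PlasmaCall] = []
        if rng.random() < cfg.chip_rate:
            n_chip = int(rng.integers(1, 3))
            for _ in range(n_chip):
                gene = _CH_GENES[rng.integers(len(_CH_GENES))]
                v = _random_variant(rng, gene, used_keys)
                af = 10.0 ** rng.normal(cfg.chip_log10_af_mean, cfg.chip_log10_af_sd)
                chip_variants.append(v)
                chip_afs.append(af)
                calls_c1.extend(
                    _sample_reads(
                        rng, [v], [af], cfg.plasma_depth, sample_c1, Compartment.PLASMA
                    )
                )
                if rng.random() < cfg.chip_pbmc_detect_prob:
                    pbmc_calls.extend(
                        _sample_reads(
                            rng, [v], [af], cfg.pbmc_depth, f"{pid}_PBMC",
                            Compartment.PBMC,
                        )
                    )
        pbmc[pid] = pbmc_calls
        plasma_c1[pid] = calls_c1

        # true baseline informed status: a shedder whose top tracked AF is
        # at or above the tracked read threshold's expectation
        detectable = shedder and msaf * cfg.plasma_depth >= defaults.TRACKED_MIN_READS
        true_status = Status.POSITIVE if detectable else Status.NEGATIVE

        # survival with arm x status interaction
        pos = true_status == Status.POSITIVE
        hr_pfs = cfg.hr_pfs_pos if pos else cfg.hr_pfs_neg
        hr_os = cfg.hr_os_pos if pos else cfg.hr_os_neg
        lam_pfs = math.log(2) / cfg.chemo_median_pfs * (hr_pfs if arm == Arm.ICI_CHEMO else 1.0)
        lam_os = math.log(2) / cfg.chemo_median_os * (hr_os if arm == Arm.ICI_CHEMO else 1.0)
        t_pfs = float(rng.exponential(1.0 / lam_pfs))
        t_os = float(rng.exponential(1.0 / lam_os))
        pfs_time, pfs_event = min(t_pfs, cfg.pfs_horizon), int(t_pfs <= cfg.pfs_horizon)
        os_time, os_event = min(t_os, cfg.os_horizon), int(t_os <= cfg.os_horizon)

        # on-treatment sample
        available = rng.random() < cfg.c3d1_availability
        cleared = False
        turned = False
        c3_status = Status.MISSING
        if available:
            sample_c3 = f"{pid}_C3D1"
            calls_c3: List[PlasmaCall] = []
            if pos:
                cleared = rng.random() < cfg.clearance_prob[arm.value]
                if not cleared:
                    shrink = 10.0 ** rng.normal(-0.3, 0.25)
                    calls_c3 = _sample_reads(
                        rng, variants, np.minimum(afs * shrink, 1.0),
                        cfg.plasma_depth, sample_c3, Compartment.PLASMA,
                    )
            else:
                turned = rng.random() < cfg.turn_positive_prob
                if turned:
                    af_new = 10.0 ** rng.normal(-2.5, 0.3)
                    calls_c3 = _sample_reads(
                        rng, variants[:1], [af_new], cfg.plasma_depth,
                        sample_c3, Compartment.PLASMA,
                    )
            # CHIP persists at both timepoints
            for v, af in zip(chip_variants, chip_afs):
                calls_c3.extend(
                    _sample_reads(
                        rng, [v], [af], cfg.plasma_depth, sample_c3,
                        Compartment.PLASMA,
                    )
                )
            plasma_c3[pid] = calls_c3
            tracked_keys = {v.key for v in variants}
            detected_c3 = any(
                c.variant.key in tracked_keys
                and c.alt_reads >= defaults.TRACKED_MIN_READS
                for c in calls_c3
            )
            c3_status = Status.POSITIVE if detected_c3 else Status.NEGATIVE

        # radiographic response, loosely coupled to on-treatment status
        if pos and cleared:
            resp_p = (0.6, 0.3, 0.1)
        elif pos:
            resp_p = (0.2, 0.4, 0.4)
        else:
            resp_p = (0.3, 0.5, 0.2)
        response = str(rng.choice(["PR", "SD", "PD"], p=resp_p))

        clinical.append(
            PatientRecord(
                patient_id=pid, arm=arm, histology=histology, smoking=smoking,
                tumor_size=size, pd_l1_tc=pd_l1,
                pfs_time=pfs_time, pfs_event=pfs_event,
                os_time=os_time, os_event=os_event,
                ctdna_baseline=true_status, ctdna_c3d1=c3_status,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid, "arm": arm.value, "histology": histology.value,
                "smoking": smoking.value, "tumor_size": size, "shedder": shedder,
                "true_msaf": msaf, "n_tracked": n_tracked,
                "has_chip": bool(chip_variants),
                "true_status": true_status.value, "c3d1_available": available,
                "cleared": cleared, "turned_positive": turned,
                "response": response,
            }
        )

    return Cohort(
        config=cfg, seed=seed, clinical=clinical, tissue=tissue,
        plasma_c1d1=plasma_c1, plasma_c3d1=plasma_c3, pbmc=pbmc,
        peptides=peptides, truth=pd.DataFrame(truth_rows),
    )


def _call_pair(
    cohort: Cohort, pid: str, tracked_min_reads: int = defaults.TRACKED_MIN_READS
) -> Tuple[Status, Status]:
    """(informed, naive) baseline status via the standard filter chain."""
    filtered = apply_filters(cohort.plasma_c1d1[pid], cohort.pbmc[pid], FilterConfig())
    informed = call_tumor_informed(
        cohort.tissue[pid], filtered.somatic_all_reads, tracked_min_reads=tracked_min_reads
    )
    naive = call_tumor_naive(filtered.somatic)
    return informed.status, naive.status


def _set_tracked_calls(
    cohort: Cohort, pid: str, alt_read_counts: Sequence[int]
) -> None:
    """Replace a patient's baseline tracked plasma calls with calls at the
    given read counts (non-tracked calls, e.g. CHIP, are kept)."""
    depth = cohort.config.plasma_depth
    tracked = sorted(cohort.tissue[pid].variants, key=lambda v: v.key)
    sample_id = f"{pid}_C1D1"
    kept = [
        c
        for c in cohort.plasma_c1d1[pid]
        if c.variant.key not in {v.key for v in tracked}
    ]
    new_calls = [
        PlasmaCall(
            variant=v, alt_reads=reads, depth=depth,
            sample_id=sample_id, compartment=Compartment.PLASMA,
        )
        for v, reads in zip(tracked, alt_read_counts)
        if reads >= 1
    ]
    cohort.plasma_c1d1[pid] = new_calls + kept


def _update_truth_status(cohort: Cohort, pid: str, status: Status) -> None:
    idx = cohort.truth.index[cohort.truth["patient_id"] == pid]
    cohort.truth.loc[idx, "true_status"] = status.value
    for rec in cohort.clinical:
        if rec.patient_id == pid:
            rec.ctdna_baseline = status


def inject_discordance(
    cohort: Cohort, n_low_af: int, n_chip_only: int, seed: int = 0
) -> Cohort:
    """Return a cohort with exactly ``n_low_af`` informed-only and
    ``n_chip_only`` naive-only discordant baseline samples.

    Informed-only positives are built by pinning a patient's tracked
    plasma reads into the window that is detectable for tracking but
    below both the de novo read threshold and the 0.5% naive LOD.
    Naive-only positives get plasma-only calls in CH-associated genes at
    >= 0.5% that appear in neither tissue nor PBMC (undetected clonal
    hematopoiesis). Patients already discordant beyond the requested
    counts are normalized back to concordance, so the requested 2x2
    margin holds exactly.
    """
    cohort = copy.deepcopy(cohort)
    cfg = cohort.config
    if n_low_af + n_chip_only > cfg.n_patients:
        raise ValueError("requested discordance exceeds cohort size")
    rng = np.random.default_rng(seed)
    used_keys = {
        v.key for profile in cohort.tissue.values() for v in profile.variants
    }

    status_pairs = {pid: _call_pair(cohort, pid) for pid in cohort.tissue}
    informed_only = [p for p, (i, n) in status_pairs.items()
                     if i == Status.POSITIVE and n == Status.NEGATIVE]
    naive_only = [p for p, (i, n) in status_pairs.items()
                  if i == Status.NEGATIVE and n == Status.POSITIVE]
    conc_pos = [p for p, (i, n) in status_pairs.items()
                if i == Status.POSITIVE and n == Status.POSITIVE]
    conc_neg = [p for p, (i, n) in status_pairs.items()
                if i == Status.NEGATIVE and n == Status.NEGATIVE]

    # normalize natural informed-only positives beyond the target back to
    # concordant-positive by lifting their tracked AFs above the naive LOD
    while len(informed_only) > n_low_af:
        pid = informed_only.pop()
        n_tracked = len(cohort.tissue[pid].variants)
        reads = [int(0.02 * cfg.plasma_depth)] + [
            int(0.005 * cfg.plasma_depth) for _ in range(n_tracked - 1)
        ]
        _set_tracked_calls(cohort, pid, reads)
        conc_pos.append(pid)
    # build additional informed-only positives from concordant-positives
    deficit = n_low_af - len(informed_only)
    if deficit > len(conc_pos):
        raise ValueError("not enough eligible patients for low-AF injection")
    for _ in range(deficit):
        pid = conc_pos.pop()
        n_tracked = len(cohort.tissue[pid].variants)
        # detectable for tracking (>=3 reads) yet below the 8-read de novo
        # threshold and far below 0.5% AF
        reads = [int(rng.integers(3, 8))] + [
            int(rng.integers(0, 3)) for _ in range(n_tracked - 1)
        ]
        _set_tracked_calls(cohort, pid, reads)
        _update_truth_status(cohort, pid, Status.POSITIVE)
        informed_only.append(pid)

    # normalize natural naive-only positives back to concordant-negative
    while len(naive_only) > n_chip_only:
        pid = naive_only.pop()
        filtered = apply_filters(
            cohort.plasma_c1d1[pid], cohort.pbmc[pid], FilterConfig()
        )
        offending = {c.variant.key for c in filtered.somatic if c.af >= defaults.NAIVE_LOD}
        cohort.plasma_c1d1[pid] = [
            c for c in cohort.plasma_c1d1[pid] if c.variant.key not in offending
        ]
        conc_neg.append(pid)
    deficit = n_chip_only - len(naive_only)
    if deficit > len(conc_neg):
        raise ValueError("not enough eligible patients for CH-only injection")
    for _ in range(deficit):
        pid = conc_neg.pop()
        gene = _CH_GENES[rng.integers(len(_CH_GENES))]
        v = _random_variant(rng, gene, used_keys)
        af = float(10.0 ** rng.uniform(-2.2, -1.6))  # 0.6%..2.5%
        alt = max(int(round(af * cfg.plasma_depth)), defaults.MIN_SNV_READS)
        cohort.plasma_c1d1[pid] = cohort.plasma_c1d1[pid] + [
            PlasmaCall(
                variant=v, alt_reads=alt, depth=cfg.plasma_depth,
                sample_id=f"{pid}_C1D1", compartment=Compartment.PLASMA,
            )
        ]
        naive_only.append(pid)
    return cohort


def config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["allocation_ratio"] = list(cfg.allocation_ratio)
    d["shedding_beta"] = list(cfg.shedding_beta)
    return d
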