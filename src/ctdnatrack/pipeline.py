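"""End-to-end orchestration: simulate (or load) a cohort, run every
analysis stage in fixed order, and write one TSV per stage plus a run
manifest.

Stage order: filter -> call -> concordance -> detection models ->
dynamics -> genomic indices -> survival. Each stage is a pure function of
its inputs and the configuration, so a rerun with the same seed and
config reproduces every deterministic output bit for bit; the manifest
records the config snapshot, seed, software version, per-stage row
counts, and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd

from . import __version__, defaults
from .cohort_io import write_clinical_table, write_segment_table, write_variant_table
from .ctdna_calling import (
    call_tumor_informed,
    call_tumor_naive,
    classify_concordance,
    concordance_summary,
    cohort_rates,
)
from .detection_models import (
    LodSpec,
    classify_negative,
    fit_shedding_model,
    min_detectable_af,
    predict_msaf_interval,
)
from .dynamics import classify_dynamics, on_treatment_group
from .genomic_indices import (
    compute_hrd_loh,
    compute_loh_fraction,
    compute_wgii,
    count_neoantigen_binders,
)
from .outcome_stats import interaction_fit
from .synthetic_cohort import (
    CHROM_LENGTHS,
    Cohort,
    SimConfig,
    config_dict,
    generate_cohort,
    generate_tracerx_standin,
)
from .types import Arm, Status
from .variant_filtering import FilterConfig, apply_filters


@dataclasses.dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    timestamp: str
    row_counts: Dict[str, int]
    input_checksums: Dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: Cohort, out_dir: Union[str, os.PathLike]) -> Dict[str, Path]:
    """Emit every module input format for a generated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    write_clinical_table(cohort.clinical, out / "clinical.tsv")
    paths["clinical"] = out / "clinical.tsv"

    tissue_rows = []
    for pid, profile in sorted(cohort.tissue.items()):
        for v in sorted(profile.variants, key=lambda v: v.key):
            tissue_rows.append(
                {"patient_id": pid, "chrom": v.chrom, "pos": v.pos,
                 "ref": v.ref, "alt": v.alt, "gene": v.gene or ""}
            )
    pd.DataFrame(tissue_rows).to_csv(out / "tissue_variants.tsv", sep="\t", index=False)
    paths["tissue"] = out / "tissue_variants.tsv"

    for name, table in (
        ("plasma_c1d1", cohort.plasma_c1d1),
        ("plasma_c3d1", cohort.plasma_c3d1),
        ("pbmc", cohort.pbmc),
    ):
        calls = [c for pid in sorted(table) for c in table[pid]]
        write_variant_table(calls, out / f"{name}.tsv")
        paths[name] = out / f"{name}.tsv"

    write_segment_table(
        {pid: profile.segments for pid, profile in sorted(cohort.tissue.items())},
        out / "segments.tsv",
    )
    paths["segments"] = out / "segments.tsv"

    pep_rows = [
        {"patient_id": pid, "peptide": p.peptide, "allele": p.allele,
         "percentile_rank": p.percentile_rank}
        for pid in sorted(cohort.peptides)
        for p in cohort.peptides[pid]
    ]
    pd.DataFrame(pep_rows).to_csv(out / "peptides.tsv", sep="\t", index=False)
    paths["peptides"] = out / "peptides.tsv"

    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    return paths


def run_pipeline(
    config: Optional[SimConfig] = None,
    out_dir: Union[str, os.PathLike] = "ctdna_run",
    seed: int = 0,
    tracked_min_reads: int = defaults.TRACKED_MIN_READS,
    cohort: Optional[Cohort] = None,
) -> Path:
    """Simulate (unless a cohort is supplied) and run every stage.

    Returns the output directory; raises naming the failing stage on any
    error.
    """
    cfg = config or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row_counts: Dict[str, int] = {}

    stage = "simulate"
    try:
        if cohort is None:
            cohort = generate_cohort(cfg, seed=seed)
        input_paths = write_cohort(cohort, out / "inputs")
        row_counts["patients"] = len(cohort.clinical)

        # ---- filter + call -------------------------------------------------
        stage = "filter/call"
        fcfg = FilterConfig()
        call_rows = []
        informed_results = {}
        naive_results = {}
        for pid in sorted(cohort.tissue):
            filtered = apply_filters(cohort.plasma_c1d1[pid], cohort.pbmc[pid], fcfg)
            informed = call_tumor_informed(
                cohort.tissue[pid], filtered.somatic_all_reads, tracked_min_reads
            )
            naive = call_tumor_naive(filtered.somatic)
            informed_results[pid] = informed
            naive_results[pid] = naive
            call_rows.append(
                {
                    "patient_id": pid,
                    "n_plasma_calls": len(cohort.plasma_c1d1[pid]),
                    "removed_support": filtered.removed_support,
                    "excluded_pbmc": len(filtered.excluded_pbmc),
                    "informed_status": informed.status.value,
                    "informed_msaf": informed.msaf,
                    "naive_status": naive.status.value,
                    "naive_msaf": naive.msaf,
                }
            )
        calls_df = pd.DataFrame(call_rows)
        calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
        row_counts["calls"] = len(calls_df)

        rates = cohort_rates(
            list(informed_results.values()) + list(naive_results.values())
        )
        rates.to_csv(out / "positivity.tsv", sep="\t", index=False)

        # ---- concordance ---------------------------------------------------
        stage = "concordance"
        categories = [
            classify_concordance(informed_results[pid], naive_results[pid])
            for pid in sorted(cohort.tissue)
        ]
        summary = concordance_summary(categories)
        pd.DataFrame([summary]).to_csv(out / "concordance.tsv", sep="\t", index=False)
        row_counts["concordance"] = int(summary["n"])

        # ---- detection models ---------------------------------------------
        stage = "detection_models"
        lod = min_detectable_af(
            LodSpec(depth=cfg.plasma_depth, min_reads=defaults.MIN_SNV_READS)
        )
        train = generate_tracerx_standin(seed=seed + 1)
        model = fit_shedding_model(train)
        (out / "shedding_model.json").write_text(model.to_json())
        shed_rows = []
        for rec in cohort.clinical:
            if informed_results[rec.patient_id].status != Status.NEGATIVE:
                continue
            point, lower, upper = predict_msaf_interval(
                model, rec.tumor_size, rec.histology
            )
            shed_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "predicted_msaf": point,
                    "lower95": lower,
                    "upper95": upper,
                    "class": classify_negative(
                        model, rec.tumor_size, rec.histology
                    ).value,
                }
            )
        shed_df = pd.DataFrame(shed_rows)
        shed_df.to_csv(out / "negative_classification.tsv", sep="\t", index=False)
        row_counts["informed_negative"] = len(shed_df)

        # ---- dynamics ------------------------------------------------------
        stage = "dynamics"
        dyn_rows = []
        for pid in sorted(cohort.tissue):
            c3 = cohort.plasma_c3d1.get(pid)
            if c3 is None:
                c3_status = Status.MISSING
            else:
                filtered_c3 = apply_filters(c3, cohort.pbmc[pid], fcfg)
                c3_status = call_tumor_informed(
                    cohort.tissue[pid], filtered_c3.somatic_all_reads, tracked_min_reads
                ).status
            dyn = classify_dynamics(informed_results[pid].status, c3_status)
            dyn_rows.append(
                {
                    "patient_id": pid,
                    "baseline": informed_results[pid].status.value,
                    "c3d1": c3_status.value,
                    "dynamics": dyn.value,
                    "on_tx_group": on_treatment_group(dyn).value,
                }
            )
        dyn_df = pd.DataFrame(dyn_rows)
        dyn_df.to_csv(out / "dynamics.tsv", sep="\t", index=False)
        row_counts["dynamics_evaluable"] = int(
            (dyn_df["dynamics"] != "NOT_EVALUABLE").sum()
        )

        # ---- genomic indices ----------------------------------------------
        stage = "genomic_indices"
        idx_rows = []
        for pid, profile in sorted(cohort.tissue.items()):
            binders, strong, weak = count_neoantigen_binders(cohort.peptides[pid])
            idx_rows.append(
                {
                    "patient_id": pid,
                    "tmb": profile.nonsyn_count,
                    "neoantigen_binders": binders,
                    "strong_binders": strong,
                    "weak_binders": weak,
                    "wgii": compute_wgii(profile.segments, profile.ploidy),
                    "ploidy": profile.ploidy,
                    "loh_fraction": compute_loh_fraction(profile.segments),
                    "hrd_loh": compute_hrd_loh(profile.segments, CHROM_LENGTHS),
                    "informed_status": informed_results[pid].status.value,
                }
            )
        idx_df = pd.DataFrame(idx_rows)
        idx_df.to_csv(out / "indices.tsv", sep="\t", index=False)
        row_counts["indices"] = len(idx_df)

        # ---- survival ------------------------------------------------------
        stage = "survival"
        surv = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in cohort.clinical],
                "treated": [int(r.arm == Arm.ICI_CHEMO) for r in cohort.clinical],
                "biomarker": [
                    int(informed_results[r.patient_id].status == Status.POSITIVE)
                    for r in cohort.clinical
                ],
                "pfs_time": [r.pfs_time for r in cohort.clinical],
                "pfs_event": [r.pfs_event for r in cohort.clinical],
                "os_time": [r.os_time for r in cohort.clinical],
                "os_event": [r.os_event for r in cohort.clinical],
            }
        )
        surv_rows = []
        for endpoint in ("pfs", "os"):
            fit = interaction_fit(
                surv, f"{endpoint}_time", f"{endpoint}_event",
                "biomarker", "treated", endpoint=endpoint.upper(),
            )
            for stratum, sf in (
                ("ctDNA+", fit.hr_in_positive),
                ("ctDNA-", fit.hr_in_negative),
            ):
                surv_rows.append(
                    {
                        "endpoint": endpoint.upper(),
                        "stratum": stratum,
                        "hr": sf.hr,
                        "ci_low": sf.ci_low,
                        "ci_high": sf.ci_high,
                        "p": sf.p,
                        "n": sf.n,
                        "events": sf.events,
                        "p_interaction": fit.p_interaction,
                    }
                )
        surv_df = pd.DataFrame(surv_rows)
        surv_df.to_csv(out / "survival.tsv", sep="\t", index=False)
        row_counts["survival_fits"] = len(surv_df)

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config={**config_dict(cfg), "tracked_min_reads": tracked_min_reads,
                "binomial_lod_8_reads": lod},
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        row_counts=row_counts,
        input_checksums={k: _sha256(p) for k, p in sorted(input_paths.items())},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return out
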