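"""Longitudinal ctDNA status between baseline (C1D1) and on-treatment
(C3D1) samples.

Clearance is the switch from tumor-informed positive at baseline to
negative on treatment (no tissue-tracked mutation detected at C3D1). The
four determinate classes collapse into an on-treatment two-group split:
persistent-positive and turn-positive form the on-treatment positive
group; clearance and persistent-negative form the on-treatment negative
group. A missing timepoint makes the patient non-evaluable — never
imputed.
"""

from __future__ import annotations

import enum
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .outcome_stats import logrank_test
from .types import Status


class DynamicsClass(str, enum.Enum):
    CLEARANCE = "CLEARANCE"
    PERSISTENT_POSITIVE = "PERSISTENT_POSITIVE"
    TURN_POSITIVE = "TURN_POSITIVE"
    PERSISTENT_NEGATIVE = "PERSISTENT_NEGATIVE"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class OnTreatmentGroup(str, enum.Enum):
    ON_TX_POSITIVE = "ON_TX_POSITIVE"
    ON_TX_NEGATIVE = "ON_TX_NEGATIVE"
    NOT_EVALUABLE = "NOT_EVALUABLE"


#: Radiographic response labels used for stratification (complete
#: responses are collapsed into PR on ingest).
RESPONSE_LABELS = ("PR", "SD", "PD")


def classify_dynamics(
    baseline: Union[Status, str], c3d1: Union[Status, str]
) -> DynamicsClass:
    """Total function on the 3x3 (baseline, on-treatment) status grid."""
    baseline, c3d1 = Status(baseline), Status(c3d1)
    if Status.MISSING in (baseline, c3d1):
        return DynamicsClass.NOT_EVALUABLE
    if baseline == Status.POSITIVE:
        return (
            DynamicsClass.PERSISTENT_POSITIVE
            if c3d1 == Status.POSITIVE
            else DynamicsClass.CLEARANCE
        )
    return (
        DynamicsClass.TURN_POSITIVE
        if c3d1 == Status.POSITIVE
        else DynamicsClass.PERSISTENT_NEGATIVE
    )


_GROUPING = {
    DynamicsClass.PERSISTENT_POSITIVE: OnTreatmentGroup.ON_TX_POSITIVE,
    DynamicsClass.TURN_POSITIVE: OnTreatmentGroup.ON_TX_POSITIVE,
    DynamicsClass.CLEARANCE: OnTreatmentGroup.ON_TX_NEGATIVE,
    DynamicsClass.PERSISTENT_NEGATIVE: OnTreatmentGroup.ON_TX_NEGATIVE,
    DynamicsClass.NOT_EVALUABLE: OnTreatmentGroup.NOT_EVALUABLE,
}


def on_treatment_group(dyn: Union[DynamicsClass, str]) -> OnTreatmentGroup:
    return _GROUPING[DynamicsClass(dyn)]


def normalize_response(label: str) -> str:
    """Restrict to {PR, SD, PD}; CR is collapsed into PR."""
    label = str(label).upper()
    if label == "CR":
        return "PR"
    if label not in RESPONSE_LABELS:
        raise ValueError(f"unknown response label {label!r}")
    return label


def stratified_survival_by_dynamics(
    records: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "on_tx_group",
    response_col: str = "response",
    response_strata: Sequence[str] = RESPONSE_LABELS,
    min_events: int = 2,
) -> pd.DataFrame:
    """Log-rank comparison of on-treatment ctDNA+ vs ctDNA- within each
    radiographic response stratum.

    Strata in which either group has fewer than ``min_events`` events are
    flagged (``tested=False``) instead of tested. Non-evaluable patients
    are dropped.
    """
    df = records.copy()
    df[response_col] = df[response_col].map(normalize_response)
    df = df[df[group_col] != OnTreatmentGroup.NOT_EVALUABLE.value]
    rows = []
    for stratum in response_strata:
        sub = df[df[response_col] == stratum]
        pos = sub[sub[group_col] == OnTreatmentGroup.ON_TX_POSITIVE.value]
        neg = sub[sub[group_col] == OnTreatmentGroup.ON_TX_NEGATIVE.value]
        row: Mapping[str, Optional[float]] = {
            "response": stratum,
            "n_pos": len(pos),
            "n_neg": len(neg),
            "events_pos": int(pos[event_col].sum()) if len(pos) else 0,
            "events_neg": int(neg[event_col].sum()) if len(neg) else 0,
        }
        row = dict(row)
        if (
            len(pos) == 0
            or len(neg) == 0
            or row["events_pos"] < min_events
            or row["events_neg"] < min_events
        ):
            row.update({"statistic": None, "p": None, "tested": False})
        else:
            stat, p = logrank_test(
                pos[time_col], pos[event_col], neg[time_col], neg[event_col]
            )
            row.update({"statistic": stat, "p": p, "tested": True})
        rows.append(row)
    return pd.DataFrame(rows)
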