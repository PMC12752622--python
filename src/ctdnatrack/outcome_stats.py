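"""Survival and group-comparison statistics.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
Cox proportional-hazards fits use the statsmodels partial-likelihood
implementation (Efron tie handling by default, Breslow available). The
predictive layer is the interaction fit: one pooled Cox model with terms
for the biomarker, the treatment arm, and their product, from which the
within-stratum treatment hazard ratios are read off as linear
combinations and the differential treatment effect is the Wald (or
likelihood-ratio) test of the product coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests


@dataclass
class SurvivalFit:
    name: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    endpoint: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence bounds must bracket the hazard ratio")
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class InteractionFit:
    hr_in_positive: SurvivalFit
    hr_in_negative: SurvivalFit
    p_interaction: float
    interaction_coef: float
    test: str = "wald"


@dataclass
class KMEstimate:
    table: pd.DataFrame  # columns: time, survival
    median: Optional[float]

    def survival_at(self, t: float) -> float:
        below = self.table[self.table["time"] <= t]
        return 1.0 if below.empty else float(below["survival"].iloc[-1])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Product-limit survival estimate with the median survival time
    (earliest t with S(t) <= 0.5; ``None`` when never reached)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.survival_function_.reset_index()
    table.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = None
    return KMEstimate(table=table, median=median)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> Tuple[float, float]:
    """Two-group log-rank test: (1-df chi-square statistic, two-sided p)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.sum(events_a) + np.sum(events_b) == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def _check_design(df: pd.DataFrame, covariates: Sequence[str], event_col: str) -> None:
    if df[event_col].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    ties: str = "efron",
    endpoint: Optional[str] = None,
) -> Dict[str, SurvivalFit]:
    """Cox proportional hazards via partial-likelihood maximization.

    Returns one :class:`SurvivalFit` per covariate, with the Wald 95%
    interval and p-value. Non-convergence or separation surfaces as a
    diagnostic error rather than silent garbage.
    """
    _check_design(df, covariates, event_col)
    model = PHReg(
        np.asarray(df[duration_col], float),
        np.asarray(df[list(covariates)], float),
        status=np.asarray(df[event_col], int),
        ties=ties,
    )
    try:
        res = model.fit(tol=1e-8, disp=False)
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise RuntimeError(
            "Cox fit produced non-finite estimates (possible complete separation)"
        )
    z = stats.norm.ppf(0.975)
    out = {}
    for i, cov in enumerate(covariates):
        b, se = params[i], bse[i]
        out[cov] = SurvivalFit(
            name=cov,
            hr=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)),
            ci_high=float(np.exp(b + z * se)),
            p=float(2 * stats.norm.sf(abs(b / se))),
            n=len(df),
            events=int(df[event_col].sum()),
            endpoint=endpoint,
        )
    return out


def _wald_fit(
    name: str,
    coef: float,
    se: float,
    n: int,
    events: int,
    endpoint: Optional[str],
) -> SurvivalFit:
    z = stats.norm.ppf(0.975)
    return SurvivalFit(
        name=name,
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p=float(2 * stats.norm.sf(abs(coef / se))),
        n=n,
        events=events,
        endpoint=endpoint,
    )


def interaction_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    biomarker_col: str,
    arm_col: str,
    ties: str = "efron",
    test: str = "wald",
    endpoint: Optional[str] = None,
) -> InteractionFit:
    """Pooled Cox model with biomarker, arm, and their product.

    The treatment HR in the biomarker-negative stratum is exp(b_arm); in
    the positive stratum exp(b_arm + b_interaction), with its variance
    from the coefficient covariance. ``test`` selects the Wald test on the
    product coefficient (default) or the likelihood-ratio test against
    the model without it.
    """
    bio = np.asarray(df[biomarker_col], float)
    arm = np.asarray(df[arm_col], float)
    if len(np.unique(bio)) < 2:
        raise ValueError("biomarker is constant; interaction is undefined")
    if len(np.unique(arm)) < 2:
        raise ValueError("treatment arm is constant; interaction is undefined")
    for b in (0, 1):
        stratum = df[bio == b]
        if stratum[event_col].sum() < 1:
            raise ValueError(f"biomarker=={b} stratum has no events")
    time = np.asarray(df[duration_col], float)
    status = np.asarray(df[event_col], int)
    X = np.column_stack([bio, arm, bio * arm])
    res = PHReg(time, X, status=status, ties=ties).fit(tol=1e-8, disp=False)
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    b_arm, b_int = params[1], params[2]
    se_arm = float(np.sqrt(cov[1, 1]))
    se_pos = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]))
    se_int = float(np.sqrt(cov[2, 2]))

    if test == "wald":
        p_int = float(2 * stats.norm.sf(abs(b_int / se_int)))
    elif test == "lrt":
        res0 = PHReg(time, X[:, :2], status=status, ties=ties).fit(
            tol=1e-8, disp=False
        )
        lr = 2 * (res.model.loglike(res.params) - res0.model.loglike(res0.params))
        p_int = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        raise ValueError(f"unknown interaction test {test!r}")

    n_pos, n_neg = int((bio == 1).sum()), int((bio == 0).sum())
    ev_pos = int(status[bio == 1].sum())
    ev_neg = int(status[bio == 0].sum())
    return InteractionFit(
        hr_in_positive=_wald_fit(
            "treatment|biomarker+", b_arm + b_int, se_pos, n_pos, ev_pos, endpoint
        ),
        hr_in_negative=_wald_fit(
            "treatment|biomarker-", b_arm, se_arm, n_neg, ev_neg, endpoint
        ),
        p_interaction=p_int,
        interaction_coef=float(b_int),
        test=test,
    )


def subgroup_forest(
    df: pd.DataFrame,
    subgroup_defs: Mapping[str, pd.Series],
    duration_col: str,
    event_col: str,
    arm_col: str,
    min_events: int = 5,
    exclusive: bool = False,
    endpoint: Optional[str] = None,
) -> pd.DataFrame:
    """Per-subgroup treatment hazard ratios for a forest plot.

    ``subgroup_defs`` maps labels to boolean masks over ``df``. With
    ``exclusive=True`` overlapping masks raise. Subgroups with fewer than
    ``min_events`` events are flagged, not fitted.
    """
    if exclusive:
        stacked = np.vstack([np.asarray(m, bool) for m in subgroup_defs.values()])
        if (stacked.sum(axis=0) > 1).any():
            raise ValueError("subgroups declared exclusive but masks overlap")
    rows = []
    for label, mask in subgroup_defs.items():
        sub = df[np.asarray(mask, bool)]
        events = int(sub[event_col].sum())
        row = {"subgroup": label, "n": len(sub), "events": events}
        if events < min_events or sub[arm_col].nunique() < 2:
            row.update(
                {"hr": None, "ci_low": None, "ci_high": None, "p": None, "tested": False}
            )
        else:
            fit = cox_fit(
                sub, duration_col, event_col, [arm_col], endpoint=endpoint
            )[arm_col]
            row.update(
                {
                    "hr": fit.hr,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "p": fit.p,
                    "tested": True,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def group_compare(
    a: Union[Sequence[float], Sequence[Sequence[int]]],
    b: Optional[Sequence[float]] = None,
    kind: str = "mann_whitney",
) -> Tuple[float, float]:
    """Two-sided group comparison.

    ``mann_whitney`` takes two continuous samples. ``chi_square``,
    ``fisher`` and ``auto`` take a 2x2 contingency table as ``a``; under
    ``auto`` the chi-square test is replaced by Fisher's exact test when
    any expected cell count falls below 5.
    """
    if kind == "mann_whitney":
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be non-empty")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    table = np.asarray(a, float)
    if table.ndim != 2:
        raise ValueError("categorical comparison expects a contingency table")
    if kind == "auto":
        expected = stats.contingency.expected_freq(table)
        kind = "fisher" if (expected < 5).any() else "chi_square"
    if kind == "chi_square":
        # Pearson statistic without Yates correction
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    if kind == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(table)
        return float(odds), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving on
    the input indices."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
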