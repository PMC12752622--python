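"""Detection-theory models.

Two components:

* an exact binomial limit-of-detection analysis — the smallest allele
  fraction ``p`` at which a variant supported by at least ``min_reads``
  reads out of ``depth`` is detected with the required confidence,
  ``P(X >= k) >= confidence`` for ``X ~ Binomial(depth, p)`` — and its
  inverse, the read threshold implied by a printed LOD;
* a log-linear shedding regression, ``log10(MSAF) ~ log10(tumor size) +
  histology``, whose 95% *prediction* interval for a new tumor classifies
  ctDNA-negative patients: a lower bound below the 0.1% threshold means the
  tumor could plausibly shed below the assay floor (potential technical
  negative), a lower bound at or above it marks a biological non-shedder.

The prediction interval (not the narrower mean-response interval) is used
because the classification concerns an individual new patient.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import defaults
from .types import Histology


@dataclass(frozen=True)
class LodSpec:
    depth: int = defaults.PLASMA_DEPTH
    min_reads: int = defaults.MIN_SNV_READS
    confidence: float = defaults.CONFIDENCE

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.min_reads > self.depth:
            raise ValueError("min_reads cannot exceed depth")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")


def detection_probability(p: float, depth: int, min_reads: int) -> float:
    """P(X >= min_reads) for X ~ Binomial(depth, p) — exact, no normal
    approximation."""
    if min_reads <= 0:
        return 1.0
    return float(stats.binom.sf(min_reads - 1, depth, p))


def min_detectable_af(spec: LodSpec, rtol: float = 1e-6) -> float:
    """Smallest allele fraction detected with the specified confidence.

    Solves ``P(X >= min_reads) = confidence`` by bisection (the survival
    function is strictly increasing in ``p``) to relative tolerance
    ``rtol``. ``min_reads == 0`` detects everything and returns 0 with a
    warning.
    """
    if spec.min_reads == 0:
        warnings.warn("min_reads=0: detection always succeeds; LOD is 0")
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if detection_probability(mid, spec.depth, spec.min_reads) >= spec.confidence:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def implied_min_reads(
    depth: int, target_lod: float, confidence: float = defaults.CONFIDENCE
) -> int:
    """Smallest read threshold ``k`` whose binomial LOD reaches
    ``target_lod``.

    Calibrates the unstated detection rule behind a printed LOD: the
    returned ``k`` satisfies ``min_detectable_af(depth, k) >= target_lod``
    while ``k - 1`` does not.
    """
    if not 0 < target_lod < 1:
        raise ValueError(f"target LOD must be in (0, 1), got {target_lod}")
    # LOD is monotone increasing in k, so binary search over k.
    lo, hi = 1, depth
    if min_detectable_af(LodSpec(depth, hi, confidence)) < target_lod:
        raise ValueError(
            f"target LOD {target_lod} unreachable with k <= depth ({depth})"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if min_detectable_af(LodSpec(depth, mid, confidence)) >= target_lod:
            hi = mid
        else:
            lo = mid + 1
    return lo


class NegativeClass(str, enum.Enum):
    TECHNICAL_NEGATIVE = "TECHNICAL_NEGATIVE"
    NON_SHEDDER = "NON_SHEDDER"


@dataclass
class SheddingModel:
    """Fitted log-linear shedding model with prediction-interval machinery.

    ``beta`` is (intercept, log10-size slope, LUSC indicator effect) on the
    log10 MSAF scale; ``xtx_inv`` is the scaled inverse cross-product
    matrix (covariance of beta divided by sigma^2), which together with
    ``sigma`` and ``df_resid`` is sufficient to produce a 95% prediction
    interval for a new observation.
    """

    beta: np.ndarray
    sigma: float
    df_resid: float
    xtx_inv: np.ndarray
    n_train: int
    has_histology: bool = True
    threshold: float = defaults.SHEDDER_THRESHOLD

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.xtx_inv = np.asarray(self.xtx_inv, dtype=float)
        if self.sigma < 0:
            raise ValueError("residual SD must be non-negative")
        if self.threshold <= 0:
            raise ValueError("classification threshold must be positive")

    @property
    def beta_intercept(self) -> float:
        return float(self.beta[0])

    @property
    def beta_log10size(self) -> float:
        return float(self.beta[1])

    @property
    def beta_histology(self) -> float:
        return float(self.beta[2]) if self.has_histology else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "sigma": self.sigma,
                "df_resid": self.df_resid,
                "xtx_inv": self.xtx_inv.tolist(),
                "n_train": self.n_train,
                "has_histology": self.has_histology,
                "threshold": self.threshold,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SheddingModel":
        d = json.loads(text)
        return cls(
            beta=np.asarray(d["beta"]),
            sigma=d["sigma"],
            df_resid=d["df_resid"],
            xtx_inv=np.asarray(d["xtx_inv"]),
            n_train=d["n_train"],
            has_histology=d["has_histology"],
            threshold=d["threshold"],
        )


def _is_lusc(histology: Union[Histology, str]) -> float:
    if isinstance(histology, Histology):
        return float(histology == Histology.LUSC)
    return float(str(histology).upper() == "LUSC")


def fit_shedding_model(
    train: Union[pd.DataFrame, Sequence[Tuple[float, str, float]]],
    threshold: float = defaults.SHEDDER_THRESHOLD,
) -> SheddingModel:
    """Ordinary least squares of log10(MSAF) on log10(tumor size) and a
    squamous-histology indicator.

    ``train`` is a DataFrame with columns ``tumor_size``, ``histology``,
    ``msaf`` or an iterable of (size, histology, msaf) tuples. All sizes
    and MSAF values must be strictly positive (log-transformable); a
    design with a single histology level is fitted without the indicator,
    with a warning.
    """
    if not isinstance(train, pd.DataFrame):
        train = pd.DataFrame(train, columns=["tumor_size", "histology", "msaf"])
    if len(train) < 10:
        raise ValueError(f"need >= 10 training rows, got {len(train)}")
    size = np.asarray(train["tumor_size"], dtype=float)
    msaf = np.asarray(train["msaf"], dtype=float)
    bad = np.nonzero((size <= 0) | (msaf <= 0))[0]
    if bad.size:
        raise ValueError(
            "non-positive tumor size or MSAF in training rows "
            f"{(bad + 1).tolist()} (log transform undefined)"
        )
    lusc = np.array([_is_lusc(h) for h in train["histology"]])
    y = np.log10(msaf)
    has_histology = len(np.unique(lusc)) > 1
    if has_histology:
        X = np.column_stack([np.ones_like(size), np.log10(size), lusc])
    else:
        warnings.warn(
            "single histology level in training data; fitting without the indicator"
        )
        X = np.column_stack([np.ones_like(size), np.log10(size)])
    res = sm.OLS(y, X).fit()
    sigma = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
    xtx_inv = np.asarray(res.normalized_cov_params)
    return SheddingModel(
        beta=np.asarray(res.params),
        sigma=sigma,
        df_resid=float(res.df_resid),
        xtx_inv=xtx_inv,
        n_train=len(train),
        has_histology=has_histology,
        threshold=threshold,
    )


def predict_msaf_interval(
    model: SheddingModel,
    tumor_size: float,
    histology: Union[Histology, str],
    alpha: float = 0.05,
) -> Tuple[float, float, float]:
    """Point prediction and 95% prediction interval for a NEW tumor's
    MSAF, on the MSAF scale.

    The interval is formed on the log10 scale as
    ``x'beta +/- t(df) * sigma * sqrt(1 + x' (X'X)^-1 x)`` and
    exponentiated, so it covers an individual new observation rather than
    the mean response.
    """
    if model is None:
        raise ValueError("model is not fitted")
    if tumor_size <= 0:
        raise ValueError("tumor size must be positive")
    if model.has_histology:
        x = np.array([1.0, np.log10(tumor_size), _is_lusc(histology)])
    else:
        x = np.array([1.0, np.log10(tumor_size)])
    point_log = float(x @ model.beta)
    if model.sigma == 0 or model.df_resid <= 0:
        point = 10.0 ** point_log
        return point, point, point
    se_pred = model.sigma * float(np.sqrt(1.0 + x @ model.xtx_inv @ x))
    tcrit = stats.t.ppf(1 - alpha / 2, model.df_resid)
    lower = 10.0 ** (point_log - tcrit * se_pred)
    upper = 10.0 ** (point_log + tcrit * se_pred)
    return 10.0 ** point_log, lower, upper


def classify_negative(
    model: SheddingModel,
    tumor_size: float,
    histology: Union[Histology, str],
    threshold: Optional[float] = None,
) -> NegativeClass:
    """Classify an informed-negative patient.

    Lower 95% prediction bound strictly below the threshold (default 0.1%)
    means the tumor could shed below the assay floor: a potential
    TECHNICAL_NEGATIVE. At or above the threshold the tumor should have
    been detectable, so the negativity is biological: NON_SHEDDER.
    """
    thr = model.threshold if threshold is None else threshold
    _, lower, _ = predict_msaf_interval(model, tumor_size, histology)
    if lower < thr:
        return NegativeClass.TECHNICAL_NEGATIVE
    return NegativeClass.NON_SHEDDER
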