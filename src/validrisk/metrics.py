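"""Closed-form conversions among single-risk-score discrimination metrics.

The model: a standardized risk score Z ~ N(0, 1) with disease incidence
increasing exponentially in Z, so log(incidence) = mu + delta * Z. The
risk gradient delta = log(OPERA) — the log odds ratio per (adjusted)
standard deviation of the score — is simultaneously

* the difference between cases and controls in mean standardized score
  (a Cohen's-D analogue),
* the standard deviation of log(incidence), so delta**2 is the variance
  in risk attributable to the score.

All seven discrimination metrics handled here are deterministic, strictly
monotone functions of delta, so any one of them fixes all the others:

======== =============================================================
metric   closed form in delta
======== =============================================================
auc      Phi(delta / sqrt(2))        (equal-variance binormal model)
opera    exp(delta)
variance delta**2
frr_mz   exp(delta**2)               (familial risk ratio at pair r = 1)
iqrr     Phi(delta - q) / Phi(-q - delta),  q = Phi^-1(3/4)
uqrr     Phi(delta - q) / (1/4)
======== =============================================================

IQRR is the mean incidence in the top quartile of the score distribution
over the mean incidence in the bottom quartile; UQRR is top-quartile mean
incidence over the population-average incidence (bounded above by 4).
Both follow from E[exp(delta*Z) ; Z in quartile] =
exp(delta**2/2) * Phi(+-delta -+ q), with the exp(delta**2/2) factor
cancelling in each ratio.

Everything is on the natural-log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .errors import DomainError, NumericalError

__all__ = [
    "Q75",
    "RiskGradient",
    "DiscriminationProfile",
    "RocCurve",
    "METRICS",
    "delta_from_opera",
    "auc_from_delta",
    "delta_from_auc",
    "variance_from_delta",
    "delta_from_variance",
    "iqrr_from_delta",
    "delta_from_iqrr",
    "uqrr_from_delta",
    "delta_from_uqrr",
    "frr_mz_from_delta",
    "delta_from_frr_mz",
    "profile_from",
    "table1",
    "table1_frame",
    "roc_points",
]

#: Upper-quartile boundary of the standard normal, Phi^-1(0.75).
Q75: float = float(ndtri(0.75))

_SQRT2 = math.sqrt(2.0)

#: Canonical metric names, in the column order used for tabular output.
METRICS = ("auc", "opera", "delta", "variance", "frr_mz", "iqrr", "uqrr")


@dataclass(frozen=True)
class RiskGradient:
    """A standardized risk score's strength delta = log(OPERA).

    Parameters
    ----------
    delta
        Non-negative risk gradient in natural-log odds-ratio units per
        standard deviation of the adjusted, standardized score.
    flipped
        True when the gradient was constructed from a protective input
        (OPERA < 1 or AUC < 0.5) and normalized to the positive
        orientation. Direction is a labelling convention; the magnitude
        carries all the discrimination information.
    """

    delta: float
    flipped: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta) or self.delta < 0:
            raise DomainError(
                f"delta must be a finite non-negative real, got {self.delta!r}; "
                "construct protective scores via from_opera/from_auc, which "
                "normalize the sign and record the flip"
            )

    def __float__(self) -> float:
        return float(self.delta)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_opera(cls, opera: float) -> "RiskGradient":
        return delta_from_opera(opera)

    @classmethod
    def from_auc(cls, auc: float) -> "RiskGradient":
        return delta_from_auc(auc)

    @classmethod
    def from_variance(cls, variance: float) -> "RiskGradient":
        return cls(delta_from_variance(variance))

    @classmethod
    def from_frr_mz(cls, frr_mz: float) -> "RiskGradient":
        return cls(delta_from_frr_mz(frr_mz))

    # -- derived metrics ----------------------------------------------
    @property
    def opera(self) -> float:
        return math.exp(self.delta)

    @property
    def auc(self) -> float:
        return auc_from_delta(self.delta)

    @property
    def variance(self) -> float:
        """Variance in log(incidence) explained by the score, delta**2."""
        return variance_from_delta(self.delta)

    @property
    def frr_mz(self) -> float:
        return frr_mz_from_delta(self.delta)

    @property
    def iqrr(self) -> float:
        return iqrr_from_delta(self.delta)

    @property
    def uqrr(self) -> float:
        return uqrr_from_delta(self.delta)

    def profile(self) -> "DiscriminationProfile":
        return DiscriminationProfile.from_delta(self.delta)


@dataclass(frozen=True)
class DiscriminationProfile:
    """One mutually consistent row of all seven discrimination metrics."""

    auc: float
    opera: float
    delta: float
    variance: float
    frr_mz: float
    iqrr: float
    uqrr: float

    @classmethod
    def from_delta(cls, delta: float) -> "DiscriminationProfile":
        d = float(delta)
        if d < 0:
            raise DomainError(f"delta must be >= 0, got {d}")
        return cls(
            auc=auc_from_delta(d),
            opera=math.exp(d),
            delta=d,
            variance=variance_from_delta(d),
            frr_mz=frr_mz_from_delta(d),
            iqrr=iqrr_from_delta(d),
            uqrr=uqrr_from_delta(d),
        )

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


@dataclass(frozen=True)
class RocCurve:
    """A binormal equal-variance ROC curve, TPR = Phi(delta + Phi^-1(FPR))."""

    fpr: np.ndarray
    tpr: np.ndarray
    delta: float

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (FPR, TPR) pairs."""
        return np.column_stack([self.fpr, self.tpr])

    def auc(self) -> float:
        """Trapezoidal area under the stored grid."""
        return float(np.trapezoid(self.tpr, self.fpr))


# ---------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------

def delta_from_opera(opera: float) -> RiskGradient:
    """Risk gradient delta = log(OPERA).

    Protective scores (OPERA < 1) are flipped to the positive orientation
    with the flip recorded on the returned :class:`RiskGradient`.
    """
    if not (opera > 0) or not math.isfinite(opera):
        raise DomainError(
            f"OPERA must be a positive finite ratio, got {opera!r}"
        )
    d = math.log(opera)
    if d < 0:
        return RiskGradient(-d, flipped=True)
    return RiskGradient(d)


def auc_from_delta(delta: float) -> float:
    """Area under the ROC curve, Phi(delta / sqrt(2)).

    Under the equal-variance binormal model case and control scores are
    N(delta, 1) and N(0, 1); the probability that a random case outscores
    a random control is Phi(delta / sqrt(2)).
    """
    d = float(delta)
    if d < 0:
        raise DomainError(f"delta must be >= 0, got {d}")
    return float(ndtr(d / _SQRT2))


def delta_from_auc(auc: float) -> RiskGradient:
    """Inverse of :func:`auc_from_delta`: delta = sqrt(2) * Phi^-1(AUC).

    AUC in (0, 0.5) denotes a protective orientation and is accepted with
    a warning and a recorded sign flip; AUC outside (0, 1) is rejected.
    """
    a = float(auc)
    if not (0.0 < a < 1.0):
        raise DomainError(
            f"AUC must lie in [0.5, 1) (values in (0, 0.5) are flipped), got {a!r}"
        )
    if a < 0.5:
        warnings.warn(
            f"AUC {a} < 0.5: interpreting as a protective score and "
            "flipping to the positive orientation",
            stacklevel=2,
        )
        return RiskGradient(_SQRT2 * float(ndtri(1.0 - a)), flipped=True)
    return RiskGradient(_SQRT2 * float(ndtri(a)))


def variance_from_delta(delta: float) -> float:
    """Variance in log(incidence) attributable to the score: delta**2."""
    return float(delta) ** 2


def delta_from_variance(variance: float) -> float:
    if variance < 0:
        raise DomainError(f"variance must be >= 0, got {variance!r}")
    return math.sqrt(variance)


def frr_mz_from_delta(delta: float) -> float:
    """Familial risk ratio generated in pairs with score correlation 1."""
    return math.exp(float(delta) ** 2)


def delta_from_frr_mz(frr_mz: float) -> float:
    if not (frr_mz >= 1):
        raise DomainError(
            f"FRR_MZ must be >= 1 (familial protection is not modelled), got {frr_mz!r}"
        )
    return math.sqrt(math.log(frr_mz))


def iqrr_from_delta(delta: float) -> float:
    """Interquartile risk ratio: top-quartile over bottom-quartile mean incidence.

    Closed form Phi(delta - q) / Phi(-q - delta) with q = Phi^-1(0.75);
    the common exp(delta**2 / 2) factor of the two quartile-conditional
    mean incidences cancels.
    """
    d = float(delta)
    if d < 0:
        raise DomainError(f"delta must be >= 0, got {d}")
    return float(ndtr(d - Q75) / ndtr(-Q75 - d))


def delta_from_iqrr(iqrr: float) -> float:
    """Invert :func:`iqrr_from_delta` by bracketed root-finding.

    IQRR is strictly increasing in delta, so a monotone bisection-type
    solve (Brent) on an expanding bracket is exact up to tolerance.
    """
    v = float(iqrr)
    if not (v >= 1) or not math.isfinite(v):
        raise DomainError(f"IQRR must be a finite ratio >= 1, got {iqrr!r}")
    if v == 1.0:
        return 0.0
    lo, hi = 0.0, 1.0
    while iqrr_from_delta(hi) < v:
        hi *= 2.0
        if hi > 1e3:  # iqrr overflows double long before this
            raise NumericalError(
                f"IQRR inversion bracket expansion failed for {iqrr!r} "
                f"(bracket [0, {hi}])"
            )
    return float(brentq(lambda d: iqrr_from_delta(d) - v, lo, hi, xtol=1e-14, rtol=8.9e-16))


def uqrr_from_delta(delta: float) -> float:
    """Upper-quartile-to-population-average risk ratio, Phi(delta - q) / 0.25.

    Top-quartile mean incidence over population mean incidence; the
    exp(delta**2 / 2) factors cancel, leaving a ratio that rises from 1
    at delta = 0 towards the mass bound 1 / 0.25 = 4.
    """
    d = float(delta)
    if d < 0:
        raise DomainError(f"delta must be >= 0, got {d}")
    return float(ndtr(d - Q75) / 0.25)


def delta_from_uqrr(uqrr: float) -> float:
    """Closed-form inverse of :func:`uqrr_from_delta`: q + Phi^-1(uqrr / 4)."""
    v = float(uqrr)
    if not (1.0 <= v < 4.0):
        raise DomainError(
            f"UQRR must lie in [1, 4) (4 is the top-quartile mass bound), got {uqrr!r}"
        )
    return Q75 + float(ndtri(v / 4.0))


_FROM_METRIC = {
    "auc": lambda v: delta_from_auc(v).delta,
    "opera": lambda v: delta_from_opera(v).delta,
    "delta": lambda v: abs(float(v)),
    "variance": delta_from_variance,
    "frr_mz": delta_from_frr_mz,
    "iqrr": delta_from_iqrr,
    "uqrr": delta_from_uqrr,
}


def profile_from(metric_name: str, value: float) -> DiscriminationProfile:
    """Build the full seven-metric profile from any single metric value.

    Every metric is strictly increasing in delta, so the profile is
    uniquely determined. ``metric_name`` must be one of
    ``auc, opera, delta, variance, frr_mz, iqrr, uqrr``.
    """
    try:
        to_delta = _FROM_METRIC[metric_name]
    except KeyError:
        raise DomainError(
            f"unknown metric {metric_name!r}; choose one of {', '.join(METRICS)}"
        ) from None
    return DiscriminationProfile.from_delta(to_delta(value))


_DEFAULT_AUC_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


def table1(auc_grid=None) -> list[DiscriminationProfile]:
    """Cross-tabulate all seven metrics over a grid of AUC values.

    The default grid 0.50, 0.55, ..., 0.95 spans the practically relevant
    range densely enough for interpolation.
    """
    grid = _DEFAULT_AUC_GRID if auc_grid is None else auc_grid
    return [profile_from("auc", a) for a in grid]


def table1_frame(auc_grid=None):
    """:func:`table1` as a pandas DataFrame with the canonical columns."""
    import pandas as pd

    return pd.DataFrame([p.as_dict() for p in table1(auc_grid)], columns=list(METRICS))


def roc_points(delta: float, n_points: int = 1001) -> RocCurve:
    """Binormal ROC curve TPR = Phi(delta + Phi^-1(FPR)) on a uniform FPR grid.

    The endpoints (0,0) and (1,1) are exact (Phi^-1 hits -inf/+inf there
    and Phi maps them back to 0/1).
    """
    d = float(delta)
    if d < 0:
        raise DomainError(f"delta must be >= 0, got {d}")
    if int(n_points) < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points!r}")
    fpr = np.linspace(0.0, 1.0, int(n_points))
    with np.errstate(divide="ignore"):
        tpr = ndtr(d + ndtri(fpr))
    tpr[0], tpr[-1] = 0.0, 1.0
    return RocCurve(fpr=fpr, tpr=np.asarray(tpr, dtype=float), delta=d)
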