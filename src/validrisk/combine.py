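"""Combining several risk scores into one combined risk gradient.

Under the linear-Gaussian log-incidence model

    log(incidence) = mu + sum_i delta_i * Z_i,   Z ~ MVN(0, R),

the combined standardized score delta . Z / ||delta||_R has gradient

    delta_combined = sqrt(delta' R delta),

where the delta_i are the *joint* (mutually adjusted) coefficients and R
is the score correlation matrix. With independent scores (R = I) this is
the Pythagorean rule sqrt(sum delta_i**2): combined variance is the sum
of the component variances.

When users supply *marginal* gradients (each score's OPERA fitted
alone), marginal = R @ joint under the same model, so
:func:`marginal_to_joint` (R^-1 @ marginal) converts before combining;
positive correlation then attenuates the combination, like the third
side of a less-than-right-angled triangle.

The reconstruction is validated against the Monte-Carlo case-control
oracle in :mod:`validrisk.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, NumericalError
from .metrics import RiskGradient

__all__ = [
    "ScoreSet",
    "combine_independent",
    "combine_correlated",
    "combine_marginal",
    "marginal_to_joint",
    "joint_to_marginal",
    "validate_correlation",
]

_PSD_TOL = 1e-10


def _as_deltas(deltas: Sequence[float]) -> np.ndarray:
    arr = np.asarray([float(d) for d in deltas], dtype=float)
    if arr.size == 0:
        raise DomainError("at least one risk gradient is required")
    if np.any(arr < 0):
        raise DomainError(f"risk gradients must be >= 0, got {arr.tolist()}")
    return arr


def validate_correlation(correlation, n: int) -> np.ndarray:
    """Check a score correlation matrix: square, symmetric, unit diagonal, PSD."""
    r = np.asarray(correlation, dtype=float)
    if r.shape != (n, n):
        raise DomainError(f"correlation matrix must be {n}x{n}, got shape {r.shape}")
    if not np.allclose(r, r.T, atol=1e-12):
        raise DomainError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-12):
        raise DomainError("correlation matrix must have a unit diagonal")
    if np.linalg.eigvalsh(r).min() < -_PSD_TOL:
        raise DomainError("correlation matrix must be positive semi-definite")
    return r


@dataclass(frozen=True)
class ScoreSet:
    """A set of joint risk gradients with an optional score correlation matrix.

    ``deltas`` are the mutually adjusted (joint) coefficients of the
    log-incidence model; ``correlation`` defaults to the identity
    (independent scores).
    """

    deltas: tuple
    correlation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arr = _as_deltas(self.deltas)
        object.__setattr__(self, "deltas", tuple(arr.tolist()))
        if self.correlation is not None:
            object.__setattr__(
                self, "correlation", validate_correlation(self.correlation, arr.size)
            )

    @property
    def R(self) -> np.ndarray:
        if self.correlation is None:
            return np.eye(len(self.deltas))
        return self.correlation


def combine_independent(deltas: Sequence[float]) -> RiskGradient:
    """Combined gradient of independent scores: sqrt(sum of delta_i**2)."""
    arr = _as_deltas([float(d) for d in deltas])
    return RiskGradient(float(np.sqrt(np.sum(arr**2))))


def combine_correlated(score_set: ScoreSet) -> RiskGradient:
    """Combined gradient sqrt(delta' R delta) for joint coefficients.

    Reduces exactly to :func:`combine_independent` at R = identity.
    Perfectly collinear scores (rho = 1) add their joint coefficients.
    """
    delta = np.asarray(score_set.deltas)
    r = score_set.R
    quad = float(delta @ r @ delta)
    # numerical guard: quad >= 0 for PSD R, clip round-off
    return RiskGradient(float(np.sqrt(max(quad, 0.0))))


def marginal_to_joint(marginal_deltas: Sequence[float], correlation) -> np.ndarray:
    """Convert separately fitted (marginal) gradients to joint coefficients.

    Under the linear-Gaussian model marginal = R @ joint, so
    joint = R^-1 @ marginal. A singular R means the scores are linearly
    redundant and the joint coefficients are not identified.
    """
    m = np.asarray([float(d) for d in marginal_deltas], dtype=float)
    r = validate_correlation(correlation, m.size)
    cond = np.linalg.cond(r)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            "score correlation matrix is singular or near-singular "
            f"(condition number {cond:.3g}); joint coefficients are not "
            "identified — drop or merge redundant scores, or apply ridge "
            "regularization explicitly before calling"
        )
    return np.linalg.solve(r, m)


def joint_to_marginal(joint_deltas: Sequence[float], correlation) -> np.ndarray:
    """Forward map: marginal gradients R @ joint implied by joint coefficients."""
    j = np.asarray([float(d) for d in joint_deltas], dtype=float)
    r = validate_correlation(correlation, j.size)
    return r @ j


def combine_marginal(marginal_deltas: Sequence[float], correlation) -> RiskGradient:
    """Combined gradient from marginal (separately fitted) gradients.

    Converts to joint coefficients first; for positive marginals the
    result is non-increasing in the pairwise correlation, reflecting the
    attenuation from double-counted risk information.
    """
    joint = marginal_to_joint(marginal_deltas, correlation)
    r = validate_correlation(correlation, joint.size)
    quad = float(joint @ r @ joint)
    return RiskGradient(float(np.sqrt(max(quad, 0.0))))
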