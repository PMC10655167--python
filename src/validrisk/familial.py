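"""Familial risk ratios to variance components on the log-incidence scale.

The central identity is the unifying equation

    familial odds ratio = exp(r * delta**2)

for a risk score with gradient delta shared between relatives whose
scores correlate r (1 for monozygotic twins, 1/2 for dizygotic twins and
other first-degree relatives under a purely additive genetic model).
For diseases the familial odds ratio approximates the familial risk
ratio (FRR), so log(FRR_rel) / r is the variance in log(incidence) the
pair shares, and log(FRR_MZ) is the total familial variance.

On that covariance scale the classic twin decomposition is linear:
cov_MZ = A + C and cov_DZ = A/2 + C for an additive genetic component A
and a shared-environment component C (the equal-environments
assumption), giving the moment estimators A = 2 (cov_MZ - cov_DZ) and
C = 2 cov_DZ - cov_MZ. The maximum AUC obtainable by measuring every
familial cause is Phi(sqrt(cov_MZ / 2)).

:class:`TwinStudyModel` wraps the decomposition of an age-stratified
table of MZ/DZ familial risk ratios in a statsmodels-style
model-fit-results workflow; the individual conversions are plain
functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.special import ndtr

from .errors import DomainError, ModelViolationError
from .metrics import RiskGradient, auc_from_delta

__all__ = [
    "RelativePairClass",
    "MZ",
    "DZ",
    "FIRST_DEGREE",
    "SECOND_DEGREE",
    "VarianceComponents",
    "AgeStratumEstimate",
    "familial_or_from_delta",
    "delta_from_frr",
    "auc_max_from_frr",
    "covariance_from_frr",
    "falconer_decompose",
    "dz_correlation",
    "familial_split",
    "genetic_auc_max",
    "decompose_age_strata",
    "nordic_twin_breast",
    "TwinStudyModel",
    "TwinStudyResults",
]


@dataclass(frozen=True)
class RelativePairClass:
    """A relative-pair type and its additive-genetic score correlation.

    ``kinship_r`` is twice the kinship coefficient: the expected
    correlation between the pair's additive genetic scores (1 for MZ
    twins, 1/2 for DZ twins/full siblings/parent-offspring, 1/4 for
    second-degree relatives).
    """

    label: str
    kinship_r: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.kinship_r <= 1.0):
            raise DomainError(
                f"kinship_r must lie in [0, 1], got {self.kinship_r!r}"
            )


MZ = RelativePairClass("MZ", 1.0)
DZ = RelativePairClass("DZ", 0.5)
FIRST_DEGREE = RelativePairClass("first-degree", 0.5)
SECOND_DEGREE = RelativePairClass("second-degree", 0.25)


@dataclass(frozen=True)
class VarianceComponents:
    """Additive genetic (A) and shared-environment (C) variance in log(incidence)."""

    A: float
    C: float
    clamped: bool = False

    @property
    def total_familial(self) -> float:
        return self.A + self.C

    @property
    def genetic_share(self) -> float:
        """A / (A + C), the genetic fraction of familial variance."""
        if self.total_familial <= 0:
            raise DomainError("genetic share undefined when A + C = 0")
        return self.A / self.total_familial


@dataclass(frozen=True)
class AgeStratumEstimate:
    """Decomposition of one age band's MZ/DZ familial risk ratios."""

    age_band: str
    frr_mz: float
    frr_dz: float
    cov_mz: float
    cov_dz: float
    components: VarianceComponents
    auc_max: float

    def as_dict(self) -> dict:
        return {
            "age_band": self.age_band,
            "frr_mz": self.frr_mz,
            "frr_dz": self.frr_dz,
            "cov_mz": self.cov_mz,
            "cov_dz": self.cov_dz,
            "A": self.components.A,
            "C": self.components.C,
            "auc_max": self.auc_max,
        }


# ---------------------------------------------------------------------
# unifying equation and its inverses
# ---------------------------------------------------------------------

def _check_r(r: float, allow_zero: bool) -> float:
    r = float(r)
    lo = 0.0
    if not (lo <= r <= 1.0) or (not allow_zero and r == 0.0):
        bound = "[0, 1]" if allow_zero else "(0, 1]"
        raise DomainError(f"pair correlation r must lie in {bound}, got {r!r}")
    return r


def familial_or_from_delta(delta: float, r: float) -> float:
    """Familial odds ratio exp(r * delta**2) generated by a shared score."""
    r = _check_r(r, allow_zero=True)
    return math.exp(r * float(delta) ** 2)


def delta_from_frr(frr: float, r: float) -> RiskGradient:
    """Risk gradient implied by a familial risk ratio: sqrt(log(FRR) / r)."""
    r = _check_r(r, allow_zero=False)
    if not (frr >= 1):
        raise DomainError(
            f"FRR must be >= 1 (familial protection is not modelled), got {frr!r}"
        )
    return RiskGradient(math.sqrt(math.log(frr) / r))


def auc_max_from_frr(frr: float, r: float) -> float:
    """Maximum AUC achievable by measuring the familial causes behind an FRR.

    Phi(sqrt(log(FRR) / (2 r))); with r = 1/2 (first-degree relatives,
    fully genetic familial risk) this reduces to Phi(sqrt(log(FRR))).
    """
    return auc_from_delta(delta_from_frr(frr, r).delta)


def covariance_from_frr(frr: float) -> float:
    """Pair covariance in log(incidence) implied by an FRR: log(FRR).

    For MZ pairs (r = 1) this is the total familial variance.
    """
    if not (frr >= 1):
        raise DomainError(
            f"FRR must be >= 1 (familial protection is not modelled), got {frr!r}"
        )
    return math.log(frr)


# ---------------------------------------------------------------------
# twin decomposition
# ---------------------------------------------------------------------

def falconer_decompose(cov_mz: float, cov_dz: float, clamp: bool = False) -> VarianceComponents:
    """Moment decomposition of MZ/DZ covariances into A and C.

    A = 2 (cov_MZ - cov_DZ), C = 2 cov_DZ - cov_MZ. A negative raw C
    (cov_DZ < cov_MZ / 2) is outside the additive-plus-shared-environment
    family; with ``clamp`` it is truncated to C = 0, A = cov_MZ and
    flagged, otherwise it raises. Silent clamping is not offered because
    it biases A upward.
    """
    cm, cd = float(cov_mz), float(cov_dz)
    if cm < 0 or cd < 0:
        raise DomainError(f"covariances must be >= 0, got ({cm}, {cd})")
    if cd > cm:
        raise ModelViolationError(
            f"cov_DZ = {cd} exceeds cov_MZ = {cm}: DZ pairs more similar than "
            "MZ pairs is outside the A + C model family"
        )
    a = 2.0 * (cm - cd)
    c = 2.0 * cd - cm
    if c < 0:
        if not clamp:
            raise ModelViolationError(
                f"raw C = {c:.6g} < 0 (2 cov_DZ < cov_MZ); pass clamp=True to "
                "truncate to C = 0, A = cov_MZ"
            )
        return VarianceComponents(A=cm, C=0.0, clamped=True)
    return VarianceComponents(A=a, C=c)


def dz_correlation(components: VarianceComponents) -> float:
    """Expected DZ/sibling pair correlation (A/2 + C) / (A + C).

    Ranges from 1/2 (purely additive genetic familial variance) to 1
    (purely shared environment).
    """
    total = components.total_familial
    if total <= 0:
        raise DomainError(
            "DZ correlation undefined for A + C = 0 (no familial variance)"
        )
    return (0.5 * components.A + components.C) / total


def familial_split(delta: float, r_mz: float) -> tuple[float, float]:
    """Split a measured score's variance delta**2 into familial and
    non-familial parts (r_MZ * delta**2, (1 - r_MZ) * delta**2).

    ``r_mz`` is the score's correlation within MZ pairs; the parts sum to
    delta**2 exactly.
    """
    r_mz = _check_r(r_mz, allow_zero=True)
    var = float(delta) ** 2
    familial = r_mz * var
    return familial, var - familial


def genetic_auc_max(A: float) -> float:
    """AUC from measuring only the additive genetic variance: Phi(sqrt(A / 2))."""
    if A < 0:
        raise DomainError(f"A must be >= 0, got {A!r}")
    return float(ndtr(math.sqrt(A / 2.0)))


def decompose_age_strata(
    rows: Iterable[tuple[str, float, float]], clamp: bool = False
) -> list[AgeStratumEstimate]:
    """Decompose (age_band, FRR_MZ, FRR_DZ) rows into per-stratum estimates.

    Covariances are taken as natural logs of the FRRs; A, C come from
    :func:`falconer_decompose` and the familial AUC ceiling from
    Phi(sqrt(cov_MZ / 2)).
    """
    out = []
    for age_band, frr_mz, frr_dz in rows:
        cov_mz = covariance_from_frr(frr_mz)
        cov_dz = covariance_from_frr(frr_dz)
        comps = falconer_decompose(cov_mz, cov_dz, clamp=clamp)
        out.append(
            AgeStratumEstimate(
                age_band=str(age_band),
                frr_mz=float(frr_mz),
                frr_dz=float(frr_dz),
                cov_mz=cov_mz,
                cov_dz=cov_dz,
                components=comps,
                auc_max=float(ndtr(math.sqrt(cov_mz / 2.0))),
            )
        )
    return out


def nordic_twin_breast() -> pd.DataFrame:
    """Packaged age-stratified MZ/DZ familial risk ratios for female breast
    cancer from the Nordic twin cohorts (columns age_band, frr_mz, frr_dz)."""
    from importlib.resources import files

    with (files("validrisk.data") / "nordic_twin_breast.csv").open("r") as fh:
        return pd.read_csv(fh, dtype={"age_band": str})


class TwinStudyModel:
    """Classic twin (A + C) decomposition of age-stratified familial risk ratios.

    Parameters
    ----------
    strata
        DataFrame with columns ``age_band``, ``frr_mz``, ``frr_dz`` — one
        row per age band, each FRR >= 1 and FRR_MZ >= FRR_DZ for an
        unclamped fit.

    Examples
    --------
    >>> model = TwinStudyModel.from_dataframe(nordic_twin_breast())
    >>> res = model.fit()
    >>> round(res.strata[0].components.A, 2)
    1.04
    """

    def __init__(self, strata: pd.DataFrame):
        required = {"age_band", "frr_mz", "frr_dz"}
        missing = required - set(strata.columns)
        if missing:
            raise DomainError(
                f"strata table missing column(s): {', '.join(sorted(missing))}"
            )
        self.strata = strata.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "TwinStudyModel":
        return cls(frame)

    @classmethod
    def from_records(cls, rows: Sequence[tuple[str, float, float]]) -> "TwinStudyModel":
        return cls(pd.DataFrame(rows, columns=["age_band", "frr_mz", "frr_dz"]))

    @classmethod
    def from_csv(cls, path) -> "TwinStudyModel":
        from .io import read_strata_csv

        return cls.from_records(read_strata_csv(path))

    def fit(self, clamp: bool = False) -> "TwinStudyResults":
        rows = list(
            self.strata[["age_band", "frr_mz", "frr_dz"]].itertuples(index=False, name=None)
        )
        return TwinStudyResults(self, decompose_age_strata(rows, clamp=clamp))


class TwinStudyResults:
    """Fitted per-stratum variance components with summary utilities."""

    def __init__(self, model: TwinStudyModel, strata: list[AgeStratumEstimate]):
        self.model = model
        self.strata = strata

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_dict() for s in self.strata])

    @property
    def mean_genetic_share(self) -> float:
        """Mean of A / (A + C) across strata."""
        shares = [s.components.genetic_share for s in self.strata]
        return sum(shares) / len(shares)

    def dz_correlations(self) -> list[float]:
        return [dz_correlation(s.components) for s in self.strata]

    def summary(self) -> str:
        lines = [
            "Twin decomposition of familial risk (log-incidence scale)",
            "=" * 76,
            f"{'age band':<10}{'FRR_MZ':>8}{'FRR_DZ':>8}{'cov_MZ':>9}"
            f"{'cov_DZ':>9}{'A':>8}{'C':>8}{'A/(A+C)':>9}{'AUC_max':>9}",
            "-" * 76,
        ]
        for s in self.strata:
            lines.append(
                f"{s.age_band:<10}{s.frr_mz:>8.2f}{s.frr_dz:>8.2f}"
                f"{s.cov_mz:>9.3f}{s.cov_dz:>9.3f}"
                f"{s.components.A:>8.3f}{s.components.C:>8.3f}"
                f"{s.components.genetic_share:>9.3f}{s.auc_max:>9.3f}"
            )
        lines.append("-" * 76)
        lines.append(
            f"mean genetic share of familial variance: {self.mean_genetic_share:.3f}"
        )
        if any(s.components.clamped for s in self.strata):
            lines.append("note: one or more strata clamped at C = 0")
        return "\n".join(lines)
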