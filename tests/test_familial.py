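"""Unifying equation, twin decomposition and the age-stratified model."""

import math

import numpy as np
import pandas as pd
import pytest

from validrisk import familial, metrics
from validrisk.errors import DomainError, ModelViolationError

from conftest import TABLE2_PRINTED


# ---------------------------------------------------------------------
# unifying equation
# ---------------------------------------------------------------------

def test_familial_or_closed_form():
    assert familial.familial_or_from_delta(1.19, 1.0) == pytest.approx(4.12, abs=0.005)
    assert familial.familial_or_from_delta(2.5, 0.0) == 1.0
    # first-degree FRR of 2 corresponds to delta ~ 1.18
    assert familial.familial_or_from_delta(math.sqrt(math.log(2) / 0.5), 0.5) == pytest.approx(2.0)


def test_unifying_round_trip():
    rng = np.random.default_rng(3)
    for d, r in zip(rng.uniform(0, 3, 200), rng.uniform(0.05, 1.0, 200)):
        frr = familial.familial_or_from_delta(d, r)
        assert familial.delta_from_frr(frr, r).delta == pytest.approx(d, abs=1e-12)


def test_delta_from_frr_examples():
    assert familial.delta_from_frr(2.0, 0.5).delta == pytest.approx(1.1774, abs=1e-4)
    assert familial.delta_from_frr(1.0, 0.7).delta == 0.0
    assert familial.delta_from_frr(5.91, 1.0).delta == pytest.approx(
        math.sqrt(math.log(5.91))
    )


def test_delta_from_frr_domain():
    with pytest.raises(DomainError, match=">= 1"):
        familial.delta_from_frr(0.8, 0.5)
    with pytest.raises(DomainError, match=r"\(0, 1\]"):
        familial.delta_from_frr(2.0, 0.0)
    with pytest.raises(DomainError):
        familial.familial_or_from_delta(1.0, 1.2)


def test_auc_max_worked_example():
    """A first-degree FRR of 2, fully genetic, caps the achievable AUC at 0.80."""
    assert familial.auc_max_from_frr(2.0, 0.5) == pytest.approx(0.80, abs=0.005)
    assert familial.auc_max_from_frr(1.0, 0.5) == 0.5
    assert familial.auc_max_from_frr(5.91, 1.0) == pytest.approx(0.83, abs=0.005)


def test_covariance_from_frr():
    assert familial.covariance_from_frr(5.91) == pytest.approx(1.78, abs=0.005)
    assert familial.covariance_from_frr(2.50) == pytest.approx(0.92, abs=0.005)
    assert familial.covariance_from_frr(1.0) == 0.0


def test_cross_module_consistency():
    """AUC ceiling from an MZ FRR equals the metric-module AUC of sqrt(log FRR)."""
    for frr in [1.5, 2.0, 4.12, 5.91]:
        assert familial.auc_max_from_frr(frr, 1.0) == metrics.auc_from_delta(
            math.sqrt(math.log(frr))
        )


# ---------------------------------------------------------------------
# Falconer decomposition
# ---------------------------------------------------------------------

def test_falconer_printed_stratum():
    comps = familial.falconer_decompose(math.log(5.91), math.log(3.51))
    assert comps.A == pytest.approx(1.04, abs=0.005)
    assert comps.C == pytest.approx(0.735, abs=0.005)
    assert not comps.clamped


def test_falconer_conservation():
    rng = np.random.default_rng(5)
    for _ in range(100):
        cm = rng.uniform(0.1, 2.0)
        cd = rng.uniform(cm / 2, cm)  # inside the A + C family
        comps = familial.falconer_decompose(cm, cd)
        assert comps.A + comps.C == pytest.approx(cm, abs=1e-12)
        assert 0.5 * comps.A + comps.C == pytest.approx(cd, abs=1e-12)


def test_falconer_pure_additive_boundary():
    comps = familial.falconer_decompose(1.4, 0.7)
    assert comps.A == pytest.approx(1.4) and comps.C == pytest.approx(0.0, abs=1e-15)


def test_falconer_negative_c_policy():
    with pytest.raises(ModelViolationError, match="clamp"):
        familial.falconer_decompose(1.0, 0.3)
    comps = familial.falconer_decompose(1.0, 0.3, clamp=True)
    assert comps.clamped and comps.A == 1.0 and comps.C == 0.0


def test_falconer_dz_exceeds_mz_rejected():
    with pytest.raises(ModelViolationError, match="cov_DZ"):
        familial.falconer_decompose(0.5, 0.9)


def test_dz_correlation():
    assert familial.dz_correlation(familial.VarianceComponents(1.3, 0.0)) == 0.5
    assert familial.dz_correlation(familial.VarianceComponents(0.0, 0.9)) == 1.0
    comps = familial.VarianceComponents(1.04, 0.74)
    r = familial.dz_correlation(comps)
    assert r == pytest.approx((0.52 + 0.74) / 1.78, abs=1e-12)
    # recomposition: exp(r * cov_MZ) recovers the printed DZ FRR
    assert math.exp(r * (comps.A + comps.C)) == pytest.approx(3.51, abs=0.02)
    with pytest.raises(DomainError):
        familial.dz_correlation(familial.VarianceComponents(0.0, 0.0))


def test_familial_split():
    d = math.log(1.5)
    fam, nonfam = familial.familial_split(d, 0.6)
    assert fam == pytest.approx(0.10, abs=0.005)
    assert nonfam == pytest.approx(0.066, abs=0.005)
    assert fam + nonfam == d * d  # exact partition
    assert familial.familial_split(d, 1.0) == (d * d, 0.0)
    assert familial.familial_split(d, 0.0) == (0.0, d * d)


# ---------------------------------------------------------------------
# age-stratified twin model
# ---------------------------------------------------------------------

def test_table2_golden(table2_printed):
    """Covariances, A, C and the AUC ceiling reproduce the published twin
    decomposition within +-0.015 when computed from unrounded log-FRRs."""
    res = familial.TwinStudyModel.from_dataframe(familial.nordic_twin_breast()).fit()
    assert len(res.strata) == 4
    for s, (band, frr_mz, frr_dz, cov_mz, cov_dz, a, c, auc_max) in zip(
        res.strata, table2_printed
    ):
        assert s.frr_mz == frr_mz and s.frr_dz == frr_dz
        assert s.cov_mz == pytest.approx(cov_mz, abs=0.015)
        assert s.cov_dz == pytest.approx(cov_dz, abs=0.015)
        assert s.components.A == pytest.approx(a, abs=0.015)
        assert s.components.C == pytest.approx(c, abs=0.015)
        assert s.auc_max == pytest.approx(auc_max, abs=0.015)


def test_mean_genetic_share_about_two_thirds():
    """Across age strata roughly two-thirds of familial variance is genetic."""
    res = familial.TwinStudyModel.from_dataframe(familial.nordic_twin_breast()).fit()
    assert 0.58 <= res.mean_genetic_share <= 0.75


def test_decompose_age_strata_null_row():
    (est,) = familial.decompose_age_strata([("any", 1.0, 1.0)], clamp=True)
    assert est.components.A == 0.0 and est.components.C == 0.0
    assert est.auc_max == 0.5


def test_twin_model_summary_and_frame():
    res = familial.TwinStudyModel.from_dataframe(familial.nordic_twin_breast()).fit()
    text = res.summary()
    assert "A/(A+C)" in text and "<50" in text
    frame = res.frame()
    assert list(frame.columns) == [
        "age_band", "frr_mz", "frr_dz", "cov_mz", "cov_dz", "A", "C", "auc_max",
    ]
    assert frame.shape == (4, 8)
    assert all(0.5 <= r <= 1.0 for r in res.dz_correlations())


def test_twin_model_missing_column():
    with pytest.raises(DomainError, match="frr_dz"):
        familial.TwinStudyModel(pd.DataFrame({"age_band": ["a"], "frr_mz": [2.0]}))


def test_genetic_only_auc_variant():
    """The genetic-only ceiling Phi(sqrt(A/2)) is below the familial ceiling."""
    res = familial.TwinStudyModel.from_dataframe(familial.nordic_twin_breast()).fit()
    for s in res.strata:
        g = familial.genetic_auc_max(s.components.A)
        assert 0.5 < g < s.auc_max
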