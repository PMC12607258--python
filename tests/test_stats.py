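"""Adjusted differences and risk associations: oracles and invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bonemicro.phantoms import CovariateModel, OutcomeModel, make_cohort
from bonemicro.stats import CollinearityError, adjusted_difference, risk_association


def test_identical_groups_null_estimate():
    tbl, _ = make_cohort(40, 40, {}, seed=3)
    r = adjusted_difference(tbl, "outcome")
    assert abs(r.estimate) < 3 * r.std_error
    assert r.p_value > 0.05


def test_ols_matches_normal_equations():
    """6-subject table: group coefficient equals the closed-form solution."""
    t6 = pd.DataFrame(
        {
            "group": ["case"] * 3 + ["control"] * 3,
            "cluster_id": list("abcabc"),
            "age": [50.0, 60.0, 70.0, 55.0, 60.0, 65.0],
            "y": [1.0, 0.8, 0.5, 1.2, 1.0, 0.9],
        }
    )
    r = adjusted_difference(t6, "y", covariates=("age",), error_structure="iid")
    X = np.column_stack([np.ones(6), (t6.group == "case").astype(float), t6.age])
    beta = np.linalg.solve(X.T @ X, X.T @ t6.y)
    assert r.estimate == pytest.approx(beta[1], abs=1e-10)


def test_gee_reduces_to_ols_when_clusters_uncorrelated():
    """With no within-cluster correlation the GEE estimate matches OLS."""
    tbl, _ = make_cohort(50, 50, {"y": -0.06}, seed=11)
    gee = adjusted_difference(tbl, "y", error_structure="exchangeable_cluster")
    ols = adjusted_difference(tbl, "y", error_structure="iid")
    assert gee.estimate == pytest.approx(ols.estimate, abs=0.01)
    assert abs(gee.model["working_correlation"]) < 0.3


def test_ci_contract():
    tbl, _ = make_cohort(30, 30, {"y": 0.1}, seed=4)
    r = adjusted_difference(tbl, "y")
    assert r.ci_low == pytest.approx(r.estimate - 1.96 * r.std_error)
    assert r.ci_high == pytest.approx(r.estimate + 1.96 * r.std_error)


def test_coverage_with_confounded_age():
    """95% CI covers the injected effect in >= 90% of replicates despite
    age confounding (quick 40-seed version of the calibration study)."""
    cov = CovariateModel(age_offset_a=5.0)
    om = OutcomeModel(age_slope=-0.02, noise_sd=0.1)
    hits = 0
    for seed in range(40):
        tbl, _ = make_cohort(60, 30, {"y": -0.06}, covariate_model=cov, outcome_model=om, seed=seed)
        r = adjusted_difference(tbl, "y")
        hits += r.ci_low <= -0.06 <= r.ci_high
    assert hits >= 33  # ~90% nominal with binomial slack


def test_collinear_design_rejected():
    tbl, _ = make_cohort(10, 10, {"y": 0.0}, seed=0)
    tbl["age2"] = tbl["age"]
    with pytest.raises(CollinearityError, match="age"):
        adjusted_difference(tbl, "y", covariates=("age", "age2"))


def test_singleton_clusters_fall_back_to_iid():
    tbl, _ = make_cohort(10, 10, {"y": 0.0}, seed=0)
    tbl["cluster_id"] = [f"u{i}" for i in range(len(tbl))]
    with pytest.warns(UserWarning, match="iid"):
        r = adjusted_difference(tbl, "y")
    assert r.model["error_structure"] == "iid"


def test_missing_outcomes_dropped_listwise():
    tbl, _ = make_cohort(20, 20, {"y": 0.0}, seed=1)
    tbl.loc[tbl.index[:3], "y"] = np.nan
    with pytest.warns(UserWarning, match="dropped 3"):
        r = adjusted_difference(tbl, "y")
    assert r.n_used == len(tbl) - 3


class TestRiskAssociation:
    @staticmethod
    def _mediation_table(n=300, seed=7):
        rng = np.random.default_rng(seed)
        ages = rng.normal(22.3, 4.4, n)
        # HbA1c correlated with AGEs; outcome depends on AGEs only
        hba = 8.0 + 0.5 * 0.9 / 4.4 * (ages - 22.3) + rng.normal(0, 0.75, n)
        y = 2.0 - 0.05 * ages + rng.normal(0, 0.2, n)
        return pd.DataFrame(
            {
                "group": "case",
                "cluster_id": [f"c{i}" for i in range(n)],
                "age": rng.normal(60, 7, n),
                "sex": rng.choice(["F", "M"], n),
                "menopause": rng.integers(0, 2, n),
                "weight": rng.normal(81, 17, n),
                "height": rng.normal(169, 9, n),
                "mean_hba1c": hba,
                "skin_ages": ages,
                "y": y,
            }
        )

    def test_null_exposure_centred_on_zero(self):
        # exposure stream must be independent of the cohort generator's
        # stream (a shared seed would make age an affine function of it)
        rng = np.random.default_rng(987654)
        ests = []
        for seed in range(40):
            tbl, _ = make_cohort(40, 2, {}, seed=seed)
            tbl = tbl[tbl.group == "case"].copy()
            tbl["exposure"] = rng.normal(size=len(tbl))
            r = risk_association(tbl, "outcome", "exposure", covariates=("age",))
            ests.append(r.estimate)
        assert abs(np.mean(ests)) < 2 * np.std(ests) / np.sqrt(len(ests)) + 0.01

    def test_attenuation_when_mediator_added(self):
        tbl = self._mediation_table()
        m1 = risk_association(tbl, "y", "mean_hba1c")
        m2 = risk_association(tbl, "y", "mean_hba1c", co_exposures=("skin_ages",))
        assert abs(m2.estimate) < abs(m1.estimate)

    def test_per_unit_rescaling_exact(self):
        tbl = self._mediation_table()
        r1 = risk_association(tbl, "y", "skin_ages")
        r5 = risk_association(tbl, "y", "skin_ages", per_units=5.0)
        assert r5.estimate == pytest.approx(5 * r1.estimate, abs=1e-12)
        assert r5.std_error == pytest.approx(5 * r1.std_error, abs=1e-12)
        rneg = risk_association(tbl, "y", "skin_ages", per_units=-20.0)
        assert rneg.estimate == pytest.approx(-20 * r1.estimate, abs=1e-12)
        assert rneg.std_error == pytest.approx(20 * r1.std_error, abs=1e-12)
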