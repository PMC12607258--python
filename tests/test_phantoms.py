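"""Generator contracts: determinism, separation, ground-truth consistency."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from bonemicro.phantoms import (
    CovariateModel,
    OutcomeModel,
    PhantomSpec,
    PlacementError,
    make_cohort,
    make_cortical_phantom,
    make_intensity_volume,
    make_trabecular_phantom,
)


def test_empty_request_empty_phantom():
    mask, gt = make_trabecular_phantom(PhantomSpec(n_plates=0, n_rods=0))
    assert mask.voxel_count == 0
    assert gt.n_elements == 0


def test_same_seed_bit_identical():
    spec = PhantomSpec(n_plates=4, n_rods=5, seed=17, gaussian_noise_sd=0.1, blur_sigma_vox=0.6)
    m1, g1 = make_trabecular_phantom(spec)
    m2, g2 = make_trabecular_phantom(spec)
    assert (m1.data == m2.data).all()
    assert (g1.label_grid == g2.label_grid).all()
    v1 = make_intensity_volume(m1, spec)
    v2 = make_intensity_volume(m2, spec)
    assert (v1.data == v2.data).all()


def test_ground_truth_matches_emitted_mask():
    spec = PhantomSpec(n_plates=5, n_rods=7, seed=3)
    mask, gt = make_trabecular_phantom(spec)
    assert gt.element_voxel_count.sum() == mask.voxel_count
    assert ((gt.label_grid > 0) == mask.data).all()
    counts = np.bincount(gt.label_grid.ravel())[1:]
    assert (counts == gt.element_voxel_count).all()


def test_min_separation_enforced():
    spec = PhantomSpec(n_plates=4, n_rods=5, min_separation_vox=3, seed=8)
    mask, gt = make_trabecular_phantom(spec)
    # dilating any single element by half the separation must not touch others
    for eid in range(1, gt.n_elements + 1):
        one = gt.label_grid == eid
        grown = ndimage.binary_dilation(one, iterations=2)
        assert not (grown & (gt.label_grid > 0) & ~one).any()


def test_placement_failure_raises():
    spec = PhantomSpec(shape=(24, 24, 24), n_plates=30, n_rods=0, plate_dims_vox=(16, 16, 2), seed=0)
    with pytest.raises(PlacementError):
        make_trabecular_phantom(spec)


def test_too_large_element_raises():
    spec = PhantomSpec(shape=(20, 20, 20), n_plates=1, n_rods=0, plate_dims_vox=(30, 30, 2))
    with pytest.raises(PlacementError):
        make_trabecular_phantom(spec)


def test_plate_to_rod_conversion_shifts_composition():
    base = PhantomSpec(n_plates=6, n_rods=2, seed=5, plate_to_rod_conversion_prob=0.0)
    conv = PhantomSpec(n_plates=6, n_rods=2, seed=5, plate_to_rod_conversion_prob=1.0)
    _, g0 = make_trabecular_phantom(base)
    _, g1 = make_trabecular_phantom(conv)
    assert g0.count("plate") == 6
    assert g1.count("plate") == 0 and g1.count("rod") == 8


def test_cortical_depths_and_porosity():
    spec = PhantomSpec(
        kind="cortical", shape=(96, 96, 32), n_tube_canals=3,
        pore_depth_fracs=(0.25, 0.5, 0.75), seed=6,
    )
    mask, gt = make_cortical_phantom(spec)
    assert gt.expected_layer == ["endosteal", "midcortical", "periosteal"]
    pore_vox = (gt.label_grid > 0).sum()
    shell_vox = mask.voxel_count + pore_vox
    assert gt.notes["porosity"] == pytest.approx(pore_vox / shell_vox, abs=1e-12)


def test_cortical_invalid_geometry_rejected():
    with pytest.raises(ValueError, match="radius"):
        PhantomSpec(kind="cortical", outer_radius_vox=20, inner_radius_vox=24)
    with pytest.raises(ValueError, match="fit"):
        PhantomSpec(kind="cortical", shape=(60, 60, 20), outer_radius_vox=40, inner_radius_vox=20)


class TestCohort:
    def test_null_cohort_zero_true_effect(self):
        tbl, truth = make_cohort(5, 5, {}, seed=0)
        assert truth["outcome"]["conditional_effect"] == 0.0
        assert len(tbl) == 10
        assert set(tbl["group"]) == {"case", "control"}

    def test_reproducible_under_seed(self):
        t1, _ = make_cohort(6, 4, {"y": -0.06}, seed=9)
        t2, _ = make_cohort(6, 4, {"y": -0.06}, seed=9)
        assert t1.drop(columns=[]).equals(t2)

    def test_injected_effect_recovered_across_seeds(self):
        """Cohort-mean case-control difference centres on the injection."""
        diffs = []
        om = OutcomeModel(age_slope=0.0, noise_sd=0.1)
        for seed in range(50):
            tbl, _ = make_cohort(60, 30, {"y": -0.06}, outcome_model=om, seed=seed)
            diffs.append(tbl[tbl.group == "case"].y.mean() - tbl[tbl.group == "control"].y.mean())
        mc_se = np.std(diffs) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(-0.06, abs=4 * mc_se)

    def test_confounding_recorded_in_truth(self):
        cov = CovariateModel(age_offset_a=5.0)
        om = OutcomeModel(age_slope=-0.02)
        _, truth = make_cohort(10, 10, {"y": -0.06}, covariate_model=cov, outcome_model=om, seed=1)
        assert truth["y"]["conditional_effect"] == -0.06
        assert truth["y"]["expected_marginal_effect"] == pytest.approx(-0.16)

    def test_degenerate_confounding_rejected(self):
        cov = CovariateModel(age_offset_a=5.0, age_sd=0.0)
        with pytest.raises(ValueError, match="variance"):
            make_cohort(5, 5, {"y": 0.1}, covariate_model=cov, seed=0)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_cohort(1, 5, {}, seed=0)

    def test_phantom_mode_applies_knobs_to_cases_only(self):
        trab = PhantomSpec(kind="trabecular", plate_to_rod_conversion_prob=0.0)
        cort = PhantomSpec(kind="cortical")
        tbl, _ = make_cohort(
            3, 3,
            {"trabecular.plate_to_rod_conversion_prob": 0.5,
             "cortical.pore_enlargement_factor_by_layer": {"midcortical": 0.4}},
            seed=2, mode="phantom",
            phantom_spec={"trabecular": trab, "cortical": cort},
        )
        for _, row in tbl.iterrows():
            p = row["trabecular_spec"].plate_to_rod_conversion_prob
            f = row["cortical_spec"].pore_enlargement_factor_by_layer
            if row["group"] == "case":
                assert p == 0.5 and f.get("midcortical") == pytest.approx(1.4)
            else:
                assert p == 0.0 and f == {}
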