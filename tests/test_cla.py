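"""Cortical laminar analysis: partition geometry, assignment, additivity."""

from __future__ import annotations

import numpy as np
import pytest

from bonemicro.cla import LAYERS, cla_analyze, laminar_partition
from bonemicro.cortical_seg import segment_cortex
from bonemicro.cps import cps_analyze_with_elements
from bonemicro.phantoms import PhantomSpec, make_cortical_phantom
from bonemicro.volume_io import BinaryMask


@pytest.fixture(scope="module")
def three_depth_canals():
    spec = PhantomSpec(
        kind="cortical",
        shape=(96, 96, 48),
        outer_radius_vox=40,
        inner_radius_vox=24,
        n_tube_canals=3,
        pore_depth_fracs=(1 / 6, 1 / 2, 5 / 6),
        pore_radius_vox=2.0,
        seed=2,
    )
    mask, gt = make_cortical_phantom(spec)
    masks = segment_cortex(mask)
    _, pore_em = cps_analyze_with_elements(masks)
    return spec, masks, pore_em, gt


def test_layer_boundaries_of_annulus():
    """Inner radius 24, outer 40: boundaries near radii 29.3 and 34.7."""
    spec = PhantomSpec(kind="cortical", shape=(96, 96, 16), n_tube_canals=0, seed=0)
    mask, _ = make_cortical_phantom(spec)
    masks = segment_cortex(mask)
    layer = laminar_partition(masks)[:, :, 8]
    g = np.mgrid[0:96, 0:96]
    rr = np.sqrt((g[0] - 47.5) ** 2 + (g[1] - 47.5) ** 2)
    r1 = 24 + 16 / 3.0
    r2 = 24 + 32 / 3.0
    for code, r_lo, r_hi in [(1, 24, r1), (2, r1, r2), (3, r2, 40)]:
        sel = layer == code
        assert rr[sel].min() >= r_lo - 1.0
        assert rr[sel].max() <= r_hi + 1.0


def test_every_compartment_voxel_gets_one_layer(three_depth_canals):
    _, masks, _, _ = three_depth_canals
    layer = laminar_partition(masks)
    comp = masks.compartment_mask.data
    assert ((layer > 0) == comp).all()


def test_rotation_preserves_layer_volumes(three_depth_canals):
    _, masks, _, _ = three_depth_canals
    layer = laminar_partition(masks)
    rot_bone = BinaryMask(np.rot90(masks.cortex_mask.data, axes=(0, 1)).copy(), 0.0607)
    layer_r = laminar_partition(segment_cortex(rot_bone))
    for code in (1, 2, 3):
        assert (layer == code).sum() == (layer_r == code).sum()


def test_depth_controlled_canals_assigned_to_expected_layers(three_depth_canals):
    _, masks, pore_em, gt = three_depth_canals
    r = cla_analyze(masks, pore_em)
    assert [r.layer(n).total_pore_number for n in LAYERS] == [1, 1, 1]
    assert gt.expected_layer == ["endosteal", "midcortical", "periosteal"]


def test_layer_sums_reproduce_entire_compartment(three_depth_canals):
    _, masks, pore_em, _ = three_depth_canals
    r = cla_analyze(masks, pore_em)
    assert sum(r.layer(n).total_pore_number for n in LAYERS) == r.entire.total_pore_number
    assert sum(r.layer(n).total_pore_area_mm2 for n in LAYERS) == pytest.approx(
        r.entire.total_pore_area_mm2, abs=1e-9
    )
    assert sum(r.layer(n).layer_area_mm2 for n in LAYERS) == pytest.approx(
        r.entire.layer_area_mm2, abs=1e-9
    )


def test_avg_pore_size_matches_disc_area(three_depth_canals):
    spec, masks, pore_em, _ = three_depth_canals
    r = cla_analyze(masks, pore_em)
    disc = np.pi * (spec.pore_radius_vox * spec.spacing_mm) ** 2
    assert r.entire.avg_pore_size_mm2 == pytest.approx(disc, rel=0.2)


def test_normalized_measures_invariant_to_voxel_rescaling(three_depth_canals):
    """The same geometry at a different voxel size: normalized pore area
    is unchanged (areas scale together)."""
    spec, masks, pore_em, _ = three_depth_canals
    r1 = cla_analyze(masks, pore_em)
    mask2 = BinaryMask(masks.cortex_mask.data, 2 * spec.spacing_mm)
    masks2 = segment_cortex(mask2)
    _, pe2 = cps_analyze_with_elements(masks2)
    r2 = cla_analyze(masks2, pe2)
    assert r2.entire.normalized_pore_area == pytest.approx(
        r1.entire.normalized_pore_area, rel=1e-9
    )
    assert r2.entire.total_pore_area_mm2 == pytest.approx(
        4 * r1.entire.total_pore_area_mm2, rel=1e-9
    )


def test_no_pores_zeros_and_missing_avg():
    spec = PhantomSpec(kind="cortical", shape=(96, 96, 16), n_tube_canals=0, seed=0)
    mask, _ = make_cortical_phantom(spec)
    masks = segment_cortex(mask)
    _, pore_em = cps_analyze_with_elements(masks)
    r = cla_analyze(masks, pore_em)
    assert r.entire.total_pore_number == 0
    assert r.entire.total_pore_area_mm2 == 0.0
    assert r.entire.avg_pore_size_mm2 is None


def test_solid_cylinder_uses_centroid_surrogate():
    g = np.mgrid[0:64, 0:64]
    rr = np.sqrt((g[0] - 31.5) ** 2 + (g[1] - 31.5) ** 2)
    solid = BinaryMask(np.repeat((rr <= 25)[:, :, None], 10, axis=2))
    masks = segment_cortex(solid)
    with pytest.warns(UserWarning, match="medullary"):
        layer = laminar_partition(masks)
    assert ((layer > 0) == masks.compartment_mask.data).all()


def test_mid_peri_enlargement_raises_only_those_layers():
    """Pore enlargement confined to mid/periosteal layers must not move
    the endosteal average pore size."""
    def run(factors):
        spec = PhantomSpec(
            kind="cortical", shape=(96, 96, 48), n_tube_canals=3,
            pore_depth_fracs=(1 / 6, 1 / 2, 5 / 6), pore_radius_vox=1.8,
            pore_enlargement_factor_by_layer=factors, seed=4,
        )
        mask, _ = make_cortical_phantom(spec)
        masks = segment_cortex(mask)
        _, pe = cps_analyze_with_elements(masks)
        return cla_analyze(masks, pe)

    base = run({})
    degraded = run({"midcortical": 1.5, "periosteal": 1.5})
    assert degraded.midcortical.avg_pore_size_mm2 > base.midcortical.avg_pore_size_mm2
    assert degraded.periosteal.avg_pore_size_mm2 > base.periosteal.avg_pore_size_mm2
    assert degraded.endosteal.avg_pore_size_mm2 == pytest.approx(
        base.endosteal.avg_pore_size_mm2, rel=0.05
    )
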