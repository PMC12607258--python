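"""Individual trabecula segmentation (ITS) morphometry.

From a plate/rod decomposition of the trabecular compartment this module
computes the standard ITS parameter set: plate and rod bone volume
fractions (pBV/TV, rBV/TV), axial bone volume fraction (aBV/TV), tissue
fractions (pBV/BV, rBV/BV), the plate-rod ratio, plate/rod number
densities (pTb.N, rTb.N; cube root of count over bulk volume), volume-
weighted mean plate thickness and rod diameter (pTb.Th, rTb.Th), mean
plate surface area, mean rod length, and plate-plate / plate-rod /
rod-rod junction densities.

Units: fractions dimensionless; number densities 1/mm; thicknesses and
lengths mm; areas mm^2; junction densities 1/mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton_core import ElementMap, junction_pair_counts
from .volume_io import BinaryMask

__all__ = ["ITSResult", "its_parameters"]

#: default half-angle (degrees) around the longitudinal axis within which
#: an element counts as axially aligned
DEFAULT_AXIAL_ANGLE_DEG = 30.0


@dataclass
class ITSResult:
    """Per-volume ITS parameters (Table-style record)."""

    bv_tv: float
    p_bv_tv: float
    r_bv_tv: float
    pr_bv_ratio: float | None  # None when there are no rods
    a_bv_tv: float
    p_bv_bv: float | None  # None when BV = 0
    r_bv_bv: float | None
    p_tb_n: float  # 1/mm
    r_tb_n: float  # 1/mm
    p_tb_th_mm: float | None
    r_tb_th_mm: float | None
    p_tb_s_mm2: float | None  # mean plate surface area
    r_tb_l_mm: float | None  # mean rod length
    pp_junc_d: float  # 1/mm^3
    pr_junc_d: float
    rr_junc_d: float
    bulk_volume_mm3: float
    n_plates: int = 0
    n_rods: int = 0
    metadata: dict = field(default_factory=dict)


def its_parameters(
    em: ElementMap,
    trabecular_mask: BinaryMask,
    axial_angle_deg: float = DEFAULT_AXIAL_ANGLE_DEG,
) -> ITSResult:
    """Compute ITS parameters from an element decomposition.

    ``trabecular_mask`` defines the bulk (total) volume TV; the element
    map must decompose the bone within it.  Element means are volume
    weighted.  An element is axially aligned when its principal axis is
    within ``axial_angle_deg`` of the longitudinal axis.
    """
    bulk_vox = trabecular_mask.voxel_count
    if bulk_vox == 0:
        raise ValueError("trabecular_mask is empty: bulk volume must be positive")
    vox_vol = em.voxel_volume_mm3
    bulk_mm3 = bulk_vox * vox_vol

    vols = em.element_volume_mm3()
    is_plate = em.element_is_surface
    is_rod = ~is_plate
    bv_mm3 = float(vols.sum())
    p_bv = float(vols[is_plate].sum())
    r_bv = float(vols[is_rod].sum())

    axis = np.zeros(3)
    axis[em.axis_longitudinal] = 1.0
    cos_lim = np.cos(np.deg2rad(axial_angle_deg))
    if em.n_elements:
        cosines = np.abs(em.element_orientation @ axis)
        axial = cosines >= cos_lim
        a_bv = float(vols[axial].sum())
    else:
        a_bv = 0.0

    n_plates = int(is_plate.sum())
    n_rods = int(is_rod.sum())

    def _wmean(values: np.ndarray, sel: np.ndarray) -> float | None:
        v = values[sel]
        w = vols[sel]
        good = np.isfinite(v)
        if not good.any() or w[good].sum() == 0:
            return None
        return float(np.average(v[good], weights=w[good]))

    pairs = junction_pair_counts(em)

    bv_tv = bv_mm3 / bulk_mm3
    return ITSResult(
        bv_tv=bv_tv,
        p_bv_tv=p_bv / bulk_mm3,
        r_bv_tv=r_bv / bulk_mm3,
        pr_bv_ratio=(p_bv / r_bv) if r_bv > 0 else None,
        a_bv_tv=a_bv / bulk_mm3,
        p_bv_bv=(p_bv / bv_mm3) if bv_mm3 > 0 else None,
        r_bv_bv=(r_bv / bv_mm3) if bv_mm3 > 0 else None,
        p_tb_n=float((n_plates / bulk_mm3) ** (1.0 / 3.0)),
        r_tb_n=float((n_rods / bulk_mm3) ** (1.0 / 3.0)),
        p_tb_th_mm=_wmean(em.element_thickness_mm, is_plate),
        r_tb_th_mm=_wmean(em.element_thickness_mm, is_rod),
        p_tb_s_mm2=_wmean(em.element_surface_area_mm2, is_plate),
        r_tb_l_mm=_wmean(em.element_length_mm, is_rod),
        pp_junc_d=pairs["surface-surface"] / bulk_mm3,
        pr_junc_d=pairs["surface-curve"] / bulk_mm3,
        rr_junc_d=pairs["curve-curve"] / bulk_mm3,
        bulk_volume_mm3=bulk_mm3,
        n_plates=n_plates,
        n_rods=n_rods,
        metadata={
            "axial_angle_deg": axial_angle_deg,
            "element_means": "volume-weighted",
            "n_island_elements": em.n_island_elements,
        },
    )
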