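"""Cortical laminar analysis (CLA).

The cortical compartment is partitioned into three equal-width concentric
layers — endosteal, midcortical, periosteal — by normalized transmural
depth: for each compartment voxel, d = D_endo / (D_endo + D_peri), where
D_endo and D_peri are in-plane Euclidean distances to the endosteal
(marrow) region and to the space outside the periosteal contour.  Layer
boundaries sit at d = 1/3 and 2/3, which guarantees three equal-width
bands regardless of local cortical thickness.

Each pore element is assigned to the layer containing its voxel centroid
(a pore spanning layers counts once).  Per layer the analysis reports the
per-slice mean total pore area (mm^2), the pore count, the average pore
cross-sectional size (mm^2), and the area- and count- densities
normalized by the layer's own cross-sectional area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cortical_seg import CorticalMasks
from .skeleton_core import ElementMap

__all__ = ["LayerStats", "CLAResult", "LAYERS", "laminar_partition", "cla_analyze"]

LAYERS = ("endosteal", "midcortical", "periosteal")
_LAYER_CODE = {name: i + 1 for i, name in enumerate(LAYERS)}


@dataclass
class LayerStats:
    """Pore statistics of one cortical layer (or the entire compartment)."""

    total_pore_area_mm2: float
    total_pore_number: int
    avg_pore_size_mm2: float | None  # None when the layer holds no pores
    normalized_pore_area: float  # mm^2 / mm^2
    normalized_pore_number: float  # 1 / mm^2
    layer_area_mm2: float


@dataclass
class CLAResult:
    """Per-layer and entire-compartment laminar pore statistics."""

    endosteal: LayerStats
    midcortical: LayerStats
    periosteal: LayerStats
    entire: LayerStats
    metadata: dict = field(default_factory=dict)

    def layer(self, name: str) -> LayerStats:
        return getattr(self, name)


def laminar_partition(masks: CorticalMasks) -> np.ndarray:
    """Label every compartment voxel with its layer (1=endosteal,
    2=midcortical, 3=periosteal; 0 outside the compartment).

    Distances are computed in-plane (per transverse slice), matching the
    annular geometry of cortical cross-sections.  When the endosteal mask
    is empty (solid section), depth is measured from the slice centroid
    of the periosteal region as a medullary-axis surrogate.
    """
    comp = masks.compartment_mask.data
    axis = masks.compartment_mask.axis_longitudinal
    endo = masks.endosteal_mask.data
    peri = masks.periosteal_mask.data
    labels = np.zeros(comp.shape, np.int8)

    comp_m = np.moveaxis(comp, axis, 0)
    endo_m = np.moveaxis(endo, axis, 0)
    peri_m = np.moveaxis(peri, axis, 0)
    out_m = np.moveaxis(labels, axis, 0)

    warned = False
    for k in range(comp_m.shape[0]):
        c = comp_m[k]
        if not c.any():
            continue
        e = endo_m[k]
        if not e.any():
            if not warned:
                warnings.warn(
                    "empty endosteal mask: measuring depth from the medullary "
                    "axis surrogate (periosteal centroid)",
                    stacklevel=2,
                )
                warned = True
            e = np.zeros_like(c)
            cx, cy = ndimage.center_of_mass(peri_m[k] if peri_m[k].any() else c)
            e[int(round(cx)), int(round(cy))] = True
        # distance of every pixel to the endosteal region / to the exterior
        d_endo = ndimage.distance_transform_edt(~e)
        d_peri = ndimage.distance_transform_edt(peri_m[k])
        denom = d_endo + d_peri
        with np.errstate(invalid="ignore", divide="ignore"):
            depth = np.where(denom > 0, d_endo / denom, 0.5)
        lay = np.where(depth < 1.0 / 3.0, 1, np.where(depth < 2.0 / 3.0, 2, 3)).astype(np.int8)
        out_m[k] = np.where(c, lay, 0)
    return labels


def _layer_stats(
    pore_sel: np.ndarray,
    label_grid: np.ndarray,
    region: np.ndarray,
    slice_ids: np.ndarray,
    axis: int,
    voxel_area_mm2: float,
    n_slices: int,
) -> LayerStats:
    """Statistics for the pores selected by ``pore_sel`` within ``region``."""
    pore_ids = np.flatnonzero(pore_sel) + 1
    pore_vox = np.isin(label_grid, pore_ids) if len(pore_ids) else np.zeros_like(region)
    total_area = pore_vox.sum() * voxel_area_mm2 / n_slices

    if len(pore_ids):
        sizes = []
        for pid in pore_ids:
            vox = label_grid == pid
            spans = np.unique(np.nonzero(np.moveaxis(vox, axis, 0))[0]).size
            sizes.append(vox.sum() * voxel_area_mm2 / max(spans, 1))
        avg_size = float(np.mean(sizes))
    else:
        avg_size = None

    layer_area = region.sum() * voxel_area_mm2 / n_slices
    return LayerStats(
        total_pore_area_mm2=float(total_area),
        total_pore_number=int(len(pore_ids)),
        avg_pore_size_mm2=avg_size,
        normalized_pore_area=float(total_area / layer_area) if layer_area > 0 else 0.0,
        normalized_pore_number=float(len(pore_ids) / layer_area) if layer_area > 0 else 0.0,
        layer_area_mm2=float(layer_area),
    )


def cla_analyze(masks: CorticalMasks, pore_elements: ElementMap) -> CLAResult:
    """Laminar pore statistics from the pore element map.

    Pore elements are assigned whole to the layer containing their voxel
    centroid.  Per-slice areas are averaged over the slices that contain
    compartment; the same slice set is used for every layer so that the
    per-layer pore numbers and areas sum exactly to the entire-compartment
    values.
    """
    layer_grid = laminar_partition(masks)
    axis = masks.compartment_mask.axis_longitudinal
    spacing = masks.compartment_mask.spacing_mm
    voxel_area = spacing**2
    label_grid = pore_elements.label_grid

    comp_m = np.moveaxis(masks.compartment_mask.data, axis, 0)
    slice_ids = np.flatnonzero(comp_m.any(axis=(1, 2)))
    n_slices = max(len(slice_ids), 1)

    n_elem = pore_elements.n_elements
    pore_layer = np.zeros(n_elem, int)  # layer code per pore element
    for eid in range(1, n_elem + 1):
        coords = np.argwhere(label_grid == eid)
        if not len(coords):
            continue
        centroid = coords.mean(axis=0)
        idx = tuple(int(round(c)) for c in centroid)
        code = layer_grid[idx]
        if code == 0:
            # centroid voxel fell outside the compartment (concave pore):
            # use the layer of the nearest labelled pore voxel
            codes = layer_grid[tuple(coords.T)]
            codes = codes[codes > 0]
            code = np.bincount(codes).argmax() if len(codes) else 2
        pore_layer[eid - 1] = code

    stats = {}
    for name in LAYERS:
        code = _LAYER_CODE[name]
        stats[name] = _layer_stats(
            pore_layer == code,
            label_grid,
            layer_grid == code,
            slice_ids,
            axis,
            voxel_area,
            n_slices,
        )
    entire = _layer_stats(
        pore_layer > 0,
        label_grid,
        layer_grid > 0,
        slice_ids,
        axis,
        voxel_area,
        n_slices,
    )
    return CLAResult(
        endosteal=stats["endosteal"],
        midcortical=stats["midcortical"],
        periosteal=stats["periosteal"],
        entire=entire,
        metadata={
            "total_pore_area": "per-slice mean over slices containing compartment",
            "n_slices": int(n_slices),
        },
    )
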