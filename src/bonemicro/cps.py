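"""Cortical pore skeletonization (CPS).

The intracortical pore space — the inverse of the segmented bone,
restricted to the cortical compartment — is decomposed with exactly the
same skeletonization/classification machinery as the trabecular network.
Curve-skeleton pores are tube-like (osteonal Haversian canals); surface-
skeleton pores are slab-like (wide merged canals that concentrate local
stress).  Junction clusters of the pore skeleton are counted by the
types of the pores they join (tube-tube, slab-tube).

A branched canal splits into separate tube elements at each junction, so
a Y-shaped canal counts as three tubes joined by one tube-tube junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cortical_seg import CorticalMasks
from .skeleton_core import ElementMap, decompose, junction_pair_counts

__all__ = ["CPSResult", "cps_analyze", "cps_analyze_with_elements"]


@dataclass
class CPSResult:
    """Cortical pore network parameters."""

    n_slab_pores: int
    n_tube_pores: int
    n_tube_tube_junctions: int
    n_slab_tube_junctions: int
    slabs_over_tubes: float | None  # None when there are no tubes
    slab_vol_over_tube_vol: float | None
    mean_slab_volume_mm3: float | None
    mean_tube_volume_mm3: float | None
    total_pore_volume_mm3: float
    metadata: dict = field(default_factory=dict)


def cps_analyze_with_elements(masks: CorticalMasks) -> tuple[CPSResult, ElementMap]:
    """Run CPS and also return the pore element map (needed by the laminar
    analysis, which assigns each pore element to a cortical layer)."""
    pores = masks.pore_mask
    em = decompose(pores)
    vols = em.element_volume_mm3()
    is_slab = em.element_is_surface
    n_slab = int(is_slab.sum())
    n_tube = int((~is_slab).sum())
    slab_vol = float(vols[is_slab].sum())
    tube_vol = float(vols[~is_slab].sum())
    pairs = junction_pair_counts(em)

    result = CPSResult(
        n_slab_pores=n_slab,
        n_tube_pores=n_tube,
        n_tube_tube_junctions=pairs["curve-curve"],
        n_slab_tube_junctions=pairs["surface-curve"],
        slabs_over_tubes=(n_slab / n_tube) if n_tube else None,
        slab_vol_over_tube_vol=(slab_vol / tube_vol) if tube_vol > 0 else None,
        mean_slab_volume_mm3=(slab_vol / n_slab) if n_slab else None,
        mean_tube_volume_mm3=(tube_vol / n_tube) if n_tube else None,
        total_pore_volume_mm3=float(pores.volume_mm3),
        metadata={"n_island_elements": em.n_island_elements},
    )
    # conservation: element volumes account for the whole pore space
    assert abs(slab_vol + tube_vol - result.total_pore_volume_mm3) < 1e-9 * max(
        result.total_pore_volume_mm3, 1.0
    ), "pore element volumes do not sum to the pore volume"
    return result, em


def cps_analyze(masks: CorticalMasks) -> CPSResult:
    """Cortical pore skeletonization of the pore space within the
    compartment; an empty pore mask yields an all-zero result."""
    result, _ = cps_analyze_with_elements(masks)
    return result
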