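"""Shared fixtures: small phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from bonemicro.phantoms import PhantomSpec, make_cortical_phantom, make_trabecular_phantom
from bonemicro.volume_io import BinaryMask


@pytest.fixture(scope="session")
def trab_phantom():
    """5 separated plates + 7 separated rods with ground truth."""
    spec = PhantomSpec(
        kind="trabecular",
        shape=(96, 96, 96),
        n_plates=5,
        n_rods=7,
        plate_dims_vox=(16, 16, 2),
        rod_radius_vox=1.6,
        rod_length_vox=30,
        seed=3,
    )
    mask, gt = make_trabecular_phantom(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def annulus_5canals():
    """Cortical shell with 5 straight axial canals."""
    spec = PhantomSpec(
        kind="cortical",
        shape=(96, 96, 48),
        outer_radius_vox=40,
        inner_radius_vox=24,
        n_tube_canals=5,
        pore_radius_vox=2.0,
        pore_depth_fracs=(0.2, 0.35, 0.5, 0.65, 0.8),
        seed=1,
    )
    mask, gt = make_cortical_phantom(spec)
    return spec, mask, gt


@pytest.fixture()
def plate_and_rod_mask():
    """One transverse plate + one axial rod, not touching."""
    vol = np.zeros((60, 60, 60), bool)
    vol[10:30, 10:30, 10:12] = True
    g = np.indices((60, 60, 60))
    vol |= ((g[0] - 45) ** 2 + (g[1] - 45) ** 2 <= 2.0**2) & (g[2] >= 10) & (g[2] < 50)
    return BinaryMask(vol, spacing_mm=0.0607)
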