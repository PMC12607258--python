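"""Synthetic bone phantoms with analytic ground truth.

Real HR-pQCT scans of the distal radius/tibia are not redistributable, so
every stage of the pipeline is exercised on constructed voxel phantoms:

* trabecular networks of separable plate-like (box) and rod-like
  (cylinder) elements with controllable counts, dimensions, orientations
  and separation;
* hollow cortical shells (annular cylinders) containing axially oriented
  tube-like canals, planar slab-like voids and Y-branched canals at
  controllable transmural depths;
* two-level intensity volumes (background/bone) with optional blur and
  Gaussian noise for testing binarization;
* two-cohort studies with realistic covariates and injected group
  effects, either as outcome tables (closed-form linear model) or as
  per-subject phantom specifications for end-to-end runs.

Phantom elements are axis-aligned primitives so that counts, volumes,
orientations and depths have closed-form expectations.  All randomness
derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import BinaryMask, ImageVolume, DEFAULT_SPACING_MM

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PlacementError",
    "make_phantom",
    "make_trabecular_phantom",
    "make_cortical_phantom",
    "make_intensity_volume",
    "CovariateModel",
    "OutcomeModel",
    "make_cohort",
]


class PlacementError(RuntimeError):
    """Requested elements cannot be placed under the separation constraint."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Only the fields relevant to ``kind`` are consulted.  Radii, lengths
    and dimensions are in voxels; ``spacing_mm`` converts to physical
    units downstream.
    """

    kind: str = "trabecular"  # trabecular | cortical | two_level_intensity
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = DEFAULT_SPACING_MM
    seed: int = 0

    # trabecular
    n_plates: int = 5
    n_rods: int = 7
    plate_dims_vox: tuple[int, int, int] = (16, 16, 2)  # in-plane a, b, thickness
    rod_radius_vox: float = 1.6
    rod_length_vox: int = 30
    orientation_mode: str = "random"  # axial | transverse | random
    min_separation_vox: int = 3
    plate_to_rod_conversion_prob: float = 0.0

    # cortical
    outer_radius_vox: float = 40.0
    inner_radius_vox: float = 24.0
    n_tube_canals: int = 5
    n_slab_voids: int = 0
    n_branched_canals: int = 0
    n_coalesced_pairs: int = 0  # adjacent canal pairs merged by a planar web
    pore_depth_fracs: tuple[float, ...] | None = None  # normalized transmural depths
    pore_radius_vox: float = 2.0
    pore_enlargement_factor_by_layer: dict = field(default_factory=dict)

    # intensity synthesis
    intensity_levels: tuple[float, float] = (0.0, 1.0)
    blur_sigma_vox: float = 0.0
    gaussian_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("trabecular", "cortical", "two_level_intensity"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (0.0 <= self.plate_to_rod_conversion_prob <= 1.0):
            raise ValueError("plate_to_rod_conversion_prob must be in [0, 1]")
        if self.kind == "cortical":
            if self.outer_radius_vox <= self.inner_radius_vox:
                raise ValueError("outer radius must exceed inner radius")
            if 2 * self.outer_radius_vox + 2 > min(self.shape[0], self.shape[1]):
                raise ValueError("cortical shell does not fit inside the grid")


@dataclass
class PhantomGroundTruth:
    """Analytic ground truth of a generated phantom."""

    label_grid: np.ndarray  # int32 element ids, 0 background
    element_type: list  # per element: "plate"/"rod" or "tube"/"slab"/"branched_tube"
    element_voxel_count: np.ndarray
    element_orientation: np.ndarray  # (K, 3) unit vectors
    element_thickness_vox: np.ndarray  # plate thickness / rod diameter
    element_depth_frac: np.ndarray | None = None  # cortical pores only
    expected_layer: list | None = None  # cortical pores only
    notes: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.element_type)

    def count(self, *types: str) -> int:
        return sum(1 for t in self.element_type if t in types)


# ---------------------------------------------------------------------------
# placement helpers


def _try_place(occupied: np.ndarray, box: np.ndarray, lo: np.ndarray, sep: int) -> bool:
    """True when `box` placed at offset `lo` keeps `sep` voxels of clearance
    from everything already in `occupied`."""
    pad_lo = np.maximum(lo - sep, 0)
    pad_hi = np.minimum(lo + np.array(box.shape) + sep, occupied.shape)
    region = occupied[tuple(slice(a, b) for a, b in zip(pad_lo, pad_hi))]
    if not region.any():
        return True
    # dilate the candidate into the clearance zone and test overlap
    sub = np.zeros(pad_hi - pad_lo, bool)
    inner = tuple(slice(a - b, a - b + s) for a, b, s in zip(lo, pad_lo, box.shape))
    sub[inner] = box
    grown = ndimage.binary_dilation(sub, iterations=sep) if sep > 0 else sub
    return not (grown & region).any()


def _stamp(grid: np.ndarray, box: np.ndarray, lo: np.ndarray, value: int) -> None:
    sl = tuple(slice(a, a + s) for a, s in zip(lo, box.shape))
    grid[sl] = np.where(box, value, grid[sl])


def _rod_box(radius: float, length: int, axis: int) -> np.ndarray:
    d = int(np.ceil(2 * radius + 1))
    cx = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    disk = (yy - cx) ** 2 + (xx - cx) ** 2 <= radius**2
    box = np.repeat(disk[..., None], length, axis=2)
    return np.moveaxis(box, 2, axis)


def _plate_box(dims: tuple[int, int, int], normal_axis: int) -> np.ndarray:
    a, b, t = dims
    box = np.ones((a, b, t), bool)
    return np.moveaxis(box, 2, normal_axis)


# ---------------------------------------------------------------------------
# trabecular phantoms


def make_trabecular_phantom(spec: PhantomSpec) -> tuple[BinaryMask, PhantomGroundTruth]:
    """Plate/rod network with >= ``min_separation_vox`` clearance between
    elements; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    long_axis = 2
    shape = tuple(spec.shape)
    labels = np.zeros(shape, np.int32)
    occupied = np.zeros(shape, bool)

    element_type: list[str] = []
    orientations: list[np.ndarray] = []
    thicknesses: list[float] = []
    counts: list[int] = []

    plan = ["plate"] * spec.n_plates + ["rod"] * spec.n_rods
    for i, planned in enumerate(plan):
        kind = planned
        if planned == "plate" and rng.random() < spec.plate_to_rod_conversion_prob:
            kind = "rod"  # degradation: a plate-like trabecula becomes rod-like
        if kind == "plate":
            if spec.orientation_mode == "axial":
                normal = int(rng.integers(0, 2))  # normal transverse -> plate contains z
            elif spec.orientation_mode == "transverse":
                normal = long_axis
            else:
                normal = int(rng.integers(0, 3))
            box = _plate_box(spec.plate_dims_vox, normal)
            axis_vec = np.zeros(3)
            # principal axis: the longest in-plane direction
            in_plane = [a for a in range(3) if a != normal]
            axis_vec[in_plane[0]] = 1.0
            thickness = float(spec.plate_dims_vox[2])
        else:
            if spec.orientation_mode == "axial":
                axis = long_axis
            elif spec.orientation_mode == "transverse":
                axis = int(rng.integers(0, 2))
            else:
                axis = int(rng.integers(0, 3))
            box = _rod_box(spec.rod_radius_vox, spec.rod_length_vox, axis)
            axis_vec = np.eye(3)[axis]
            thickness = 2.0 * spec.rod_radius_vox

        placed = False
        for _attempt in range(200):
            margin = 1
            hi = np.array(shape) - np.array(box.shape) - margin
            if (hi < margin).any():
                raise PlacementError(
                    f"element {i} of size {box.shape} does not fit in grid {shape}"
                )
            lo = np.array([int(rng.integers(margin, h + 1)) for h in hi])
            if _try_place(occupied, box, lo, spec.min_separation_vox):
                _stamp(labels, box, lo, i + 1)
                _stamp(occupied, box, lo, 1)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place element {i + 1}/{len(plan)} with "
                f"min_separation_vox={spec.min_separation_vox} after 200 attempts; "
                "reduce counts or element sizes"
            )
        element_type.append(kind)
        orientations.append(axis_vec)
        thicknesses.append(thickness)
        counts.append(int(box.sum()))

    mask = BinaryMask(labels > 0, spec.spacing_mm, long_axis)
    gt = PhantomGroundTruth(
        label_grid=labels,
        element_type=element_type,
        element_voxel_count=np.array(counts, int),
        element_orientation=np.array(orientations).reshape(-1, 3),
        element_thickness_vox=np.array(thicknesses),
        notes={"seed": spec.seed, "kind": "trabecular"},
    )
    return mask, gt


# ---------------------------------------------------------------------------
# cortical phantoms


def make_cortical_phantom(spec: PhantomSpec) -> tuple[BinaryMask, PhantomGroundTruth]:
    """Annular cortical shell with axial tube canals, planar slab voids and
    Y-branched canals at controlled transmural depths.

    Pores keep >= 2 voxels of clearance from both cortical surfaces so the
    pore finder never discards them as surface concavities, and >=
    ``min_separation_vox`` clearance from one another.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    yy, xx = np.mgrid[0:nx, 0:ny]
    rr = np.sqrt((xx.T - cy) ** 2 + (yy.T - cx) ** 2).T  # in-plane radius
    rr = np.sqrt((np.mgrid[0:nx, 0:ny][0] - cx) ** 2 + (np.mgrid[0:nx, 0:ny][1] - cy) ** 2)
    shell2d = (rr <= spec.outer_radius_vox) & (rr >= spec.inner_radius_vox)
    bone = np.repeat(shell2d[:, :, None], nz, axis=2)

    r_in, r_out = spec.inner_radius_vox, spec.outer_radius_vox
    wall = r_out - r_in

    pores = np.zeros(spec.shape, np.int32)
    element_type: list[str] = []
    orientations: list[np.ndarray] = []
    thicknesses: list[float] = []
    depths: list[float] = []
    layers: list[str] = []
    counts: list[int] = []

    n_total = (
        spec.n_tube_canals
        + spec.n_slab_voids
        + spec.n_branched_canals
        + spec.n_coalesced_pairs
    )
    depth_list = list(spec.pore_depth_fracs) if spec.pore_depth_fracs else None

    def pore_radius(depth_frac: float) -> float:
        layer = _depth_to_layer(depth_frac)
        return spec.pore_radius_vox * float(
            spec.pore_enlargement_factor_by_layer.get(layer, 1.0)
        )

    def next_depth(k: int) -> float:
        if depth_list:
            return depth_list[k % len(depth_list)]
        return float(rng.uniform(0.2, 0.8))

    eid = 0
    angles_used: list[float] = []
    # evenly spaced angular slots with a random rotation and small jitter:
    # guarantees angular separation for any feasible pore count
    if n_total > 0:
        slot = 2 * np.pi / n_total
        base_angle = float(rng.uniform(0, 2 * np.pi))
        jitter = rng.uniform(-0.15, 0.15, n_total) * slot
        angle_slots = [base_angle + k * slot + jitter[k] for k in range(n_total)]
        if n_total > 2 * np.pi * r_in / (4 * spec.pore_radius_vox + 2 * spec.min_separation_vox):
            raise PlacementError(
                f"{n_total} pores cannot keep {spec.min_separation_vox}-voxel "
                "separation on this shell; enlarge the shell or reduce pores"
            )

    def place_angle() -> float:
        theta = angle_slots[len(angles_used)]
        angles_used.append(theta)
        return theta

    zz = np.arange(nz)
    for k in range(spec.n_tube_canals):
        depth = next_depth(eid)
        rad = pore_radius(depth)
        theta = place_angle()
        rc = r_in + depth * wall
        rc = float(np.clip(rc, r_in + rad + 2.5, r_out - rad - 2.5))
        px, py = cx + rc * np.cos(theta), cy + rc * np.sin(theta)
        disk = (np.mgrid[0:nx, 0:ny][0] - px) ** 2 + (np.mgrid[0:nx, 0:ny][1] - py) ** 2 <= rad**2
        canal = np.repeat(disk[:, :, None], nz, axis=2)
        eid += 1
        pores[canal] = eid
        element_type.append("tube")
        orientations.append(np.array([0.0, 0.0, 1.0]))
        thicknesses.append(2 * rad)
        actual_depth = (rc - r_in) / wall
        depths.append(actual_depth)
        layers.append(_depth_to_layer(actual_depth))
        counts.append(int(canal.sum()))

    for k in range(spec.n_slab_voids):
        depth = next_depth(eid)
        theta = place_angle()
        rc = r_in + depth * wall
        # axis-aligned planar void: radial thickness 2, tangential and axial
        # extent ~ 60% of the wall; snap theta to an axis for closed form
        theta = float(np.round(theta / (np.pi / 2)) * (np.pi / 2))
        if any(abs(theta - a) < 0.3 for a in angles_used[:-1]):
            theta += np.pi / 2
        ext_t = max(int(0.5 * wall), 6)
        ext_z = max(int(0.4 * nz), 8)
        rc = float(np.clip(rc, r_in + 3.5, r_out - 3.5))
        px, py = cx + rc * np.cos(theta), cy + rc * np.sin(theta)
        tangential = 0 if abs(np.sin(theta)) > 0.5 else 1  # axis orthogonal to radial dir
        dims = [2, 2, ext_z]
        dims[tangential] = ext_t
        lo = np.array(
            [
                int(round(px - dims[0] / 2)),
                int(round(py - dims[1] / 2)),
                int((nz - ext_z) // 2),
            ]
        )
        box = np.ones(dims, bool)
        eid += 1
        _stamp(pores, box, lo, eid)
        element_type.append("slab")
        tvec = np.zeros(3)
        tvec[2] = 1.0 if ext_z >= ext_t else 0.0
        if ext_z < ext_t:
            tvec[tangential] = 1.0
        orientations.append(tvec)
        thicknesses.append(2.0)
        actual_depth = (rc - r_in) / wall
        depths.append(actual_depth)
        layers.append(_depth_to_layer(actual_depth))
        counts.append(int(box.sum()))

    for k in range(spec.n_branched_canals):
        depth = next_depth(eid)
        # slim geometry (radius <= 1.5, fast tangential separation): the
        # trunk and branch separate quickly so their meeting is a clean
        # curve junction rather than a slab-like wedge
        rad = min(pore_radius(depth), 1.5)
        theta = place_angle()
        rc = r_in + depth * wall
        rc = float(np.clip(rc, r_in + rad + 2.5, r_out - rad - 2.5))
        px, py = cx + rc * np.cos(theta), cy + rc * np.sin(theta)
        gx, gy = np.mgrid[0:nx, 0:ny]
        disk = (gx - px) ** 2 + (gy - py) ** 2 <= rad**2
        canal = np.repeat(disk[:, :, None], nz, axis=2)
        # branch leaving mid-height: 2 voxels tangential per axial voxel
        zmid = nz // 2
        tdir = np.array([-np.sin(theta), np.cos(theta)])
        branch = np.zeros(spec.shape, bool)
        t_room = np.sqrt(max((r_out - rad - 2.5) ** 2 - rc**2, 4.0))
        blen = int(min(t_room / 2.0, 8))
        for s in range(1, blen + 1):
            bx, by, bz = px + 2.0 * tdir[0] * s, py + 2.0 * tdir[1] * s, zmid + s
            if bz >= nz - 2:
                break
            d2 = (gx - bx) ** 2 + (gy - by) ** 2
            branch[:, :, int(bz)] |= d2 <= rad**2
        eid += 1
        pores[canal | branch] = eid
        element_type.append("branched_tube")
        orientations.append(np.array([0.0, 0.0, 1.0]))
        thicknesses.append(2 * rad)
        actual_depth = (rc - r_in) / wall
        depths.append(actual_depth)
        layers.append(_depth_to_layer(actual_depth))
        counts.append(int((canal | branch).sum()))

    for k in range(spec.n_coalesced_pairs):
        # two close canals merged by a planar web: the degraded-bone motif
        # where neighbouring osteonal canals coalesce into a slab-like void
        depth = next_depth(eid)
        rad = pore_radius(depth)
        theta = place_angle()
        rc = r_in + depth * wall
        rc = float(np.clip(rc, r_in + rad + 2.5, r_out - rad - 2.5))
        gap = 3.0 * rad + 2.0
        dtheta = gap / (2.0 * rc)
        gx, gy = np.mgrid[0:nx, 0:ny]
        pair = np.zeros(spec.shape, bool)
        centers = []
        for sgn in (-1.0, 1.0):
            px, py = cx + rc * np.cos(theta + sgn * dtheta), cy + rc * np.sin(theta + sgn * dtheta)
            centers.append((px, py))
            disk = (gx - px) ** 2 + (gy - py) ** 2 <= rad**2
            pair |= np.repeat(disk[:, :, None], nz, axis=2)
        # connecting web: within 1 voxel of the segment between the centers,
        # over the central 40% of the height
        (x0, y0), (x1, y1) = centers
        seg = np.array([x1 - x0, y1 - y0])
        seg_len2 = float(seg @ seg)
        t = np.clip(((gx - x0) * seg[0] + (gy - y0) * seg[1]) / seg_len2, 0, 1)
        dist2 = (gx - (x0 + t * seg[0])) ** 2 + (gy - (y0 + t * seg[1])) ** 2
        web2d = dist2 <= 1.0**2
        z0, z1 = int(0.3 * nz), int(0.7 * nz)
        web = np.zeros(spec.shape, bool)
        web[:, :, z0:z1] = web2d[:, :, None]
        eid += 1
        pores[pair | web] = eid
        element_type.append("coalesced_pair")
        orientations.append(np.array([0.0, 0.0, 1.0]))
        thicknesses.append(2 * rad)
        actual_depth = (rc - r_in) / wall
        depths.append(actual_depth)
        layers.append(_depth_to_layer(actual_depth))
        counts.append(int((pair | web).sum()))

    pores_in_bone = (pores > 0) & bone
    bone_final = bone & ~(pores > 0)
    labels = np.where(pores_in_bone, pores, 0).astype(np.int32)
    # recount after clipping to the shell
    for e in range(1, eid + 1):
        counts[e - 1] = int((labels == e).sum())

    mask = BinaryMask(bone_final, spec.spacing_mm, 2)
    gt = PhantomGroundTruth(
        label_grid=labels,
        element_type=element_type,
        element_voxel_count=np.array(counts, int),
        element_orientation=np.array(orientations).reshape(-1, 3),
        element_thickness_vox=np.array(thicknesses),
        element_depth_frac=np.array(depths),
        expected_layer=layers,
        notes={
            "seed": spec.seed,
            "kind": "cortical",
            "inner_radius_vox": r_in,
            "outer_radius_vox": r_out,
            "porosity": float(labels.astype(bool).sum())
            / float(bone.sum()),
        },
    )
    return mask, gt


def _depth_to_layer(depth_frac: float) -> str:
    if depth_frac < 1.0 / 3.0:
        return "endosteal"
    if depth_frac < 2.0 / 3.0:
        return "midcortical"
    return "periosteal"


# ---------------------------------------------------------------------------
# intensity synthesis


def make_intensity_volume(mask: BinaryMask, spec: PhantomSpec) -> ImageVolume:
    """Two-level intensity volume from a binary phantom: background/bone
    levels, optional Gaussian blur (partial-volume surrogate) and additive
    Gaussian noise; deterministic under ``spec.seed``."""
    lo, hi = spec.intensity_levels
    img = np.where(mask.data, hi, lo).astype(np.float64)
    if spec.blur_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_vox)
    if spec.gaussian_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        img = img + rng.normal(0.0, spec.gaussian_noise_sd, img.shape)
    return ImageVolume(img, mask.spacing_mm, mask.axis_longitudinal)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask, PhantomGroundTruth]:
    """Generate a phantom of the requested kind.

    Returns the intensity volume, the ground-truth binary mask and the
    analytic ground truth.  For ``kind='two_level_intensity'`` the
    structural part defaults to a trabecular network.
    """
    if spec.kind == "cortical":
        mask, gt = make_cortical_phantom(spec)
    else:
        mask, gt = make_trabecular_phantom(spec)
    vol = make_intensity_volume(mask, spec)
    return vol, mask, gt


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CovariateModel:
    """Covariate distributions for synthetic two-group cohorts.

    Defaults mirror a middle-aged study population: age ~ N(60, 7.5) yr,
    ~55% female, menopause in ~70% of females, height/weight normal, and
    optional group-A offsets to inject confounding.
    """

    age_mean: float = 60.0
    age_sd: float = 7.5
    female_prob: float = 0.55
    menopause_prob_female: float = 0.7
    height_mean_cm: float = 169.0
    height_sd_cm: float = 9.5
    weight_mean_kg: float = 81.0
    weight_sd_kg: float = 17.5
    vitd_mean: float = 36.0
    vitd_sd: float = 14.0
    osteo_med_prob: float = 0.03
    oral_gc_prob: float = 0.05
    hba1c_mean_a: float = 8.0
    hba1c_sd_a: float = 0.9
    hba1c_mean_b: float = 5.5
    hba1c_sd_b: float = 0.3
    ages_mean: float = 22.3
    ages_sd: float = 4.4
    hba1c_ages_corr: float = 0.5
    # confounding: offsets applied to group A (cases)
    age_offset_a: float = 0.0
    weight_offset_a: float = 0.0

    def validate(self) -> None:
        for name in ("age_sd", "height_sd_cm", "weight_sd_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (self.age_offset_a != 0 or self.weight_offset_a != 0) and (
            self.age_sd == 0 or self.weight_sd_kg == 0
        ):
            raise ValueError(
                "confounding requested but the confounded covariate has zero variance"
            )


@dataclass
class OutcomeModel:
    """Linear outcome model for table-mode cohorts.

    outcome = intercept + age_slope*(age-60) + weight_slope*(weight-81)
              + height_slope*(height-169) + sex_shift*female
              + group_effect (group A) + N(0, noise_sd)
    """

    intercept: float = 1.0
    age_slope: float = -0.01
    weight_slope: float = 0.0
    height_slope: float = 0.0
    sex_shift: float = 0.0
    noise_sd: float = 0.15


def _draw_covariates(rng: np.random.Generator, n: int, group: str, cov: CovariateModel) -> pd.DataFrame:
    offs_age = cov.age_offset_a if group == "case" else 0.0
    offs_wt = cov.weight_offset_a if group == "case" else 0.0
    age = rng.normal(cov.age_mean + offs_age, cov.age_sd, n)
    female = rng.random(n) < cov.female_prob
    menopause = female & (rng.random(n) < cov.menopause_prob_female)
    height = rng.normal(cov.height_mean_cm, cov.height_sd_cm, n) - 6.0 * female
    weight = rng.normal(cov.weight_mean_kg + offs_wt, cov.weight_sd_kg, n)
    vitd = rng.normal(cov.vitd_mean, cov.vitd_sd, n)
    osteo = rng.random(n) < cov.osteo_med_prob
    gc = rng.random(n) < cov.oral_gc_prob
    if group == "case":
        hba1c = rng.normal(cov.hba1c_mean_a, cov.hba1c_sd_a, n)
        z = cov.hba1c_ages_corr * (hba1c - cov.hba1c_mean_a) / max(cov.hba1c_sd_a, 1e-9)
        ages = cov.ages_mean + cov.ages_sd * (
            z + np.sqrt(max(1 - cov.hba1c_ages_corr**2, 0.0)) * rng.standard_normal(n)
        )
    else:
        hba1c = rng.normal(cov.hba1c_mean_b, cov.hba1c_sd_b, n)
        ages = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": np.where(female, "F", "M"),
            "menopause": menopause.astype(int),
            "height": height,
            "weight": weight,
            "vitd_25ohd": vitd,
            "osteo_med": osteo.astype(int),
            "oral_gc": gc.astype(int),
            "mean_hba1c": hba1c,
            "skin_ages": ages,
        }
    )


def make_cohort(
    n_a: int,
    n_b: int,
    effect_map: dict | None = None,
    covariate_model: CovariateModel | None = None,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    mode: str = "table",
    phantom_spec: PhantomSpec | None = None,
):
    """Two-group synthetic cohort with known ground truth.

    ``mode='table'`` draws outcomes directly from the linear
    ``OutcomeModel`` with the group effect from ``effect_map`` (parameter
    name -> additive offset in group A); fast enough for Monte-Carlo
    calibration studies.  ``mode='phantom'`` instead attaches a per-subject
    :class:`PhantomSpec` whose generator knobs are shifted by
    ``effect_map`` in group A; run the analyzers on each subject's phantom
    to obtain outcomes.

    Returns ``(table, ground_truth)`` where ``ground_truth`` records the
    true marginal and covariate-conditional group effects.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    effect_map = dict(effect_map or {})
    cov = covariate_model or CovariateModel()
    cov.validate()
    rng = np.random.default_rng(seed)

    tbl_a = _draw_covariates(rng, n_a, "case", cov)
    tbl_b = _draw_covariates(rng, n_b, "control", cov)
    tbl = pd.concat([tbl_a, tbl_b], ignore_index=True)
    tbl.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(tbl))])
    # matched-pair clusters: case i is paired with control i % n_b
    cluster = list(range(n_a)) + [i % n_a for i in range(n_b)]
    tbl["cluster_id"] = [f"C{c:04d}" for c in cluster]

    truth: dict = {"seed": seed, "mode": mode, "effect_map": effect_map}

    if mode == "table":
        om = outcome_model or OutcomeModel()
        female = (tbl["sex"] == "F").to_numpy()
        lin = (
            om.intercept
            + om.age_slope * (tbl["age"].to_numpy() - 60.0)
            + om.weight_slope * (tbl["weight"].to_numpy() - 81.0)
            + om.height_slope * (tbl["height"].to_numpy() - 169.0)
            + om.sex_shift * female
        )
        is_a = (tbl["group"] == "case").to_numpy()
        for outcome, delta in effect_map.items() or {"outcome": 0.0}.items():
            vals = lin + delta * is_a + rng.normal(0.0, om.noise_sd, len(tbl))
            tbl[outcome] = vals
            # conditional (adjusted) effect is delta by construction; the
            # marginal difference also absorbs covariate imbalance
            marginal_bias = om.age_slope * cov.age_offset_a + om.weight_slope * cov.weight_offset_a
            truth[outcome] = {
                "conditional_effect": float(delta),
                "expected_marginal_effect": float(delta + marginal_bias),
            }
        if not effect_map:
            vals = lin + rng.normal(0.0, om.noise_sd, len(tbl))
            tbl["outcome"] = vals
            truth["outcome"] = {"conditional_effect": 0.0, "expected_marginal_effect": 0.0}
        return tbl, truth

    if mode == "phantom":
        bases = {
            "trabecular": (phantom_spec or {}).get("trabecular", PhantomSpec(kind="trabecular"))
            if isinstance(phantom_spec, dict)
            else PhantomSpec(kind="trabecular"),
            "cortical": (phantom_spec or {}).get("cortical", PhantomSpec(kind="cortical"))
            if isinstance(phantom_spec, dict)
            else PhantomSpec(kind="cortical"),
        }
        spec_cols: dict[str, list] = {"trabecular": [], "cortical": []}
        for i in range(len(tbl)):
            for comp, base in bases.items():
                subj_seed = int(rng.integers(0, 2**31 - 1))
                spec_i = replace(base, seed=subj_seed)
                if tbl.loc[i, "group"] == "case":
                    for knob, delta in effect_map.items():
                        prefix, _, name = knob.partition(".")
                        if prefix != comp:
                            continue
                        cur = getattr(spec_i, name)
                        if isinstance(cur, dict):
                            merged = dict(cur)
                            for k, v in delta.items():
                                merged[k] = merged.get(k, 1.0) + v
                            spec_i = replace(spec_i, **{name: merged})
                        elif isinstance(cur, int) and not isinstance(delta, float):
                            spec_i = replace(spec_i, **{name: cur + int(delta)})
                        else:
                            spec_i = replace(spec_i, **{name: float(cur) + float(delta)})
                spec_cols[comp].append(spec_i)
        tbl["trabecular_spec"] = spec_cols["trabecular"]
        tbl["cortical_spec"] = spec_cols["cortical"]
        return tbl, truth

    raise ValueError(f"unknown cohort mode {mode!r}")
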