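"""Segmentation of mineralized bone from grayscale volumes.

Two approaches are provided: a Laplace-Hamming pipeline (frequency-domain
Hamming low-pass, Laplacian edge enhancement, robust normalization and
thresholding), which retains fine trabecular detail, and a standard
density-threshold approach (Gaussian smoothing + global threshold), which
tends to overestimate thick structures and lose the finest ones.  The
original filter constants are not published; the defaults here are
recorded stand-ins and every run can override them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, ImageVolume

__all__ = ["BinarizationConfig", "binarize_laplace_hamming", "binarize_standard", "binarize", "dice"]


@dataclass
class BinarizationConfig:
    """Parameters of both binarization methods.

    hamming_cutoff_frac : low-pass cutoff as a fraction of Nyquist.
    laplace_weight      : blend weight of the Laplacian edge term in [0, 1].
    threshold_frac      : threshold as a fraction of the robust intensity range.
    fixed_threshold     : absolute threshold for the standard method (optional).
    std_smooth_sigma    : Gaussian sigma (voxels) for the standard method.
    min_component_voxels: connected components (26-conn) smaller than this
                          are removed from the mask.
    """

    method: str = "laplace_hamming"
    hamming_cutoff_frac: float = 1.0
    laplace_weight: float = 0.5
    threshold_frac: float = 0.5
    fixed_threshold: float | None = None
    std_smooth_sigma: float = 0.5
    min_component_voxels: int = 27

    def __post_init__(self) -> None:
        for name in ("hamming_cutoff_frac", "threshold_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.laplace_weight <= 1.0):
            raise ValueError(f"laplace_weight must be in [0, 1], got {self.laplace_weight}")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")
        if self.method not in ("laplace_hamming", "standard_threshold"):
            raise ValueError(f"unknown binarization method {self.method!r}")

    def metadata(self) -> dict:
        """Effective configuration, echoed into outputs for reproducibility."""
        return {k: v for k, v in self.__dict__.items()}


def _hamming_lowpass(data: np.ndarray, cutoff_frac: float) -> np.ndarray:
    """Frequency-domain low-pass with a radial Hamming taper.

    The transfer function is H(f) = 0.54 + 0.46 cos(pi f / fc) for radial
    frequency f <= fc (fc = cutoff_frac x Nyquist) and 0 beyond, applied
    via FFT.  This is the smoothing half of the Laplace-Hamming filter.
    """
    freqs = np.meshgrid(*[np.fft.fftfreq(n) for n in data.shape], indexing="ij")
    radial = np.sqrt(sum(f**2 for f in freqs))  # cycles/voxel, Nyquist = 0.5
    fc = cutoff_frac * 0.5
    transfer = np.where(radial <= fc, 0.54 + 0.46 * np.cos(np.pi * radial / np.maximum(fc, 1e-12)), 0.0)
    return np.real(np.fft.ifftn(np.fft.fftn(data) * transfer))


def _robust_normalize(data: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = np.percentile(data, [0.1, 99.9])
    if hi <= lo:
        return np.zeros_like(data), True
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0), False


def _remove_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1 or not mask.any():
        return mask
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labeled]


def binarize_laplace_hamming(vol: ImageVolume, cfg: BinarizationConfig | None = None) -> BinaryMask:
    """Laplace-Hamming binarization.

    Pipeline: Hamming-windowed low-pass -> Laplacian edge enhancement
    blended with the smoothed image -> robust [0, 1] normalization
    (0.1/99.9 percentiles) -> global threshold -> small-object removal.
    A constant input yields an empty mask with a warning.
    """
    cfg = cfg or BinarizationConfig()
    data = np.asarray(vol.data, dtype=np.float64)
    smoothed = _hamming_lowpass(data, cfg.hamming_cutoff_frac)
    # unsharp-style enhancement: subtracting the Laplacian sharpens edges
    enhanced = smoothed - cfg.laplace_weight * ndimage.laplace(smoothed)
    normed, degenerate = _robust_normalize(enhanced)
    if degenerate:
        warnings.warn("constant input: normalization degenerate, returning empty mask", stacklevel=2)
        return BinaryMask(np.zeros(vol.shape, bool), vol.spacing_mm, vol.axis_longitudinal, vol.origin_mm)
    mask = normed >= cfg.threshold_frac
    mask = _remove_small(mask, cfg.min_component_voxels)
    return BinaryMask(mask, vol.spacing_mm, vol.axis_longitudinal, vol.origin_mm)


def binarize_standard(vol: ImageVolume, cfg: BinarizationConfig | None = None) -> BinaryMask:
    """Standard density-threshold binarization: Gaussian smoothing followed
    by a global threshold (absolute ``fixed_threshold`` or
    ``threshold_frac`` of the robust range), then small-object removal."""
    cfg = cfg or BinarizationConfig(method="standard_threshold")
    data = np.asarray(vol.data, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(data, cfg.std_smooth_sigma) if cfg.std_smooth_sigma > 0 else data
    if cfg.fixed_threshold is not None:
        mask = smoothed >= cfg.fixed_threshold
    else:
        normed, degenerate = _robust_normalize(smoothed)
        if degenerate:
            warnings.warn("constant input: normalization degenerate, returning empty mask", stacklevel=2)
            return BinaryMask(np.zeros(vol.shape, bool), vol.spacing_mm, vol.axis_longitudinal, vol.origin_mm)
        mask = normed >= cfg.threshold_frac
    mask = _remove_small(mask, cfg.min_component_voxels)
    return BinaryMask(mask, vol.spacing_mm, vol.axis_longitudinal, vol.origin_mm)


def binarize(vol: ImageVolume, cfg: BinarizationConfig | None = None) -> BinaryMask:
    """Dispatch on ``cfg.method``."""
    cfg = cfg or BinarizationConfig()
    if cfg.method == "laplace_hamming":
        return binarize_laplace_hamming(vol, cfg)
    return binarize_standard(vol, cfg)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap coefficient between two masks (1.0 for two empties)."""
    da = a.data if isinstance(a, BinaryMask) else np.asarray(a, bool)
    db = b.data if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = da.sum() + db.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(da, db).sum() / float(denom)
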