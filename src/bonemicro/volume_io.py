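"""Reading, writing and in-memory containers for 3D bone volumes.

HR-pQCT volumes are isotropic 3D grids (default 60.7 micron voxels).  This
module provides the two in-memory containers used throughout the package
(:class:`ImageVolume` for grayscale data, :class:`BinaryMask` for
segmentations), readers/writers for the standard interchange formats
(NIfTI, MetaImage, TIFF stack), and CSV/JSON serialization of result
records.  The scanner-native AIM format is proprietary and not supported;
convert to NIfTI or MetaImage first.

Conventions: 0-based voxel indices; physical position = origin + index *
spacing; all lengths/areas/volumes reported in mm, mm^2, mm^3.  The limb
long axis defaults to the third array axis and is carried as metadata
rather than assumed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "ValidationError",
    "FormatError",
    "read_volume",
    "write_volume",
    "write_results",
    "read_results",
]

#: HR-pQCT second-generation voxel size in mm (60.7 um), the package default.
DEFAULT_SPACING_MM = 0.0607

#: Relative tolerance under which near-isotropic spacings are collapsed to
#: their mean.
ISOTROPY_RTOL = 1e-6


class ValidationError(ValueError):
    """Input violates a contract (anisotropy, NaN, missing field ...)."""


class FormatError(IOError):
    """File cannot be read as any supported volume format."""


def _validate_geometry(data: np.ndarray, spacing_mm: float, axis_longitudinal: int) -> None:
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValidationError(f"all dimensions must be >= 1, got shape {data.shape}")
    if not (spacing_mm > 0):
        raise ValidationError(f"spacing_mm must be positive, got {spacing_mm}")
    if axis_longitudinal not in (0, 1, 2):
        raise ValidationError(f"axis_longitudinal must be 0, 1 or 2, got {axis_longitudinal}")


@dataclass
class ImageVolume:
    """3D scalar voxel grid with isotropic spacing.

    Parameters
    ----------
    data:
        3D array of attenuation values (arbitrary units).  NaNs are rejected.
    spacing_mm:
        Isotropic voxel edge length in mm.
    axis_longitudinal:
        Index of the array axis aligned with the limb/scanner long axis.
    origin_mm:
        Physical position of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    axis_longitudinal: int = 2
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _validate_geometry(self.data, self.spacing_mm, self.axis_longitudinal)
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValidationError("volume contains NaN or infinite values")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3


@dataclass
class BinaryMask:
    """3D boolean grid sharing geometry with its parent :class:`ImageVolume`."""

    data: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    axis_longitudinal: int = 2
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _validate_geometry(self.data, self.spacing_mm, self.axis_longitudinal)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def like(self, data: np.ndarray) -> "BinaryMask":
        """New mask with this mask's geometry and the given voxel data."""
        return BinaryMask(data, self.spacing_mm, self.axis_longitudinal, self.origin_mm)


_TIFF_SUFFIXES = {".tif", ".tiff"}
_SITK_SUFFIXES = {".nii", ".gz", ".mha", ".mhd"}


def read_volume(
    path: str | Path,
    format_hint: str | None = None,
    spacing_mm: float | None = None,
    axis_longitudinal: int = 2,
) -> ImageVolume:
    """Read a NIfTI, MetaImage or TIFF-stack volume.

    Near-isotropic spacing (relative spread below 1e-6) is collapsed to the
    mean; genuinely anisotropic files are rejected.  For TIFF stacks, which
    carry no reliable 3D spacing, ``spacing_mm`` must be supplied (the
    package default is used otherwise); the slice axis becomes the
    longitudinal axis.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = (format_hint or path.suffix).lower()

    if suffix in _TIFF_SUFFIXES or suffix == "tiff":
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        # slice axis first in the file; move it to the longitudinal axis
        data = np.moveaxis(stack, 0, axis_longitudinal)
        return ImageVolume(
            data,
            spacing_mm=spacing_mm if spacing_mm is not None else DEFAULT_SPACING_MM,
            axis_longitudinal=axis_longitudinal,
        )

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001 - SimpleITK raises RuntimeError
        raise FormatError(f"cannot read {path} as a volume: {exc}") from exc
    spacings = np.asarray(img.GetSpacing(), dtype=float)
    mean_sp = float(spacings.mean())
    if np.any(np.abs(spacings - mean_sp) > ISOTROPY_RTOL * mean_sp):
        raise ValidationError(
            f"anisotropic voxel spacing {tuple(spacings)} mm exceeds relative "
            f"tolerance {ISOTROPY_RTOL}; resample to isotropic voxels first"
        )
    # SimpleITK returns arrays as (z, y, x); restore (x, y, z)
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    if spacing_mm is not None:
        mean_sp = spacing_mm
    return ImageVolume(
        data,
        spacing_mm=mean_sp,
        axis_longitudinal=axis_longitudinal,
        origin_mm=np.asarray(img.GetOrigin(), dtype=float),
    )


def write_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> Path:
    """Write a volume or mask as NIfTI, MetaImage or TIFF stack.

    Integer and boolean data round-trip losslessly.  Boolean masks are
    stored as uint8 (0/1).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FormatError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise ValidationError("refusing to write volume containing NaN/inf")

    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        stack = np.moveaxis(data, vol.axis_longitudinal, 0)
        tifffile.imwrite(path, stack)
        return path

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing((vol.spacing_mm,) * 3)
    img.SetOrigin(tuple(np.asarray(vol.origin_mm, dtype=float)))
    sitk.WriteImage(img, str(path))
    return path


def read_mask(path: str | Path, **kwargs) -> BinaryMask:
    """Read a volume file and interpret nonzero voxels as foreground."""
    vol = read_volume(path, **kwargs)
    return BinaryMask(vol.data != 0, vol.spacing_mm, vol.axis_longitudinal, vol.origin_mm)


# ---------------------------------------------------------------------------
# Result records


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, dict):
        return dict(record)
    raise ValidationError(f"unsupported result record type: {type(record).__name__}")


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for key, value in d.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, prefix=f"{name}."))
        else:
            out[name] = value
    return out


def write_results(record, path: str | Path) -> Path:
    """Serialize a result record (or list of records) to CSV or JSON.

    CSV output has one row per record with columns named exactly as the
    result dataclass fields (nested layer blocks flattened with ``.``);
    JSON output preserves nesting.  Values survive a round-trip at full
    double precision.
    """
    path = Path(path)
    records = record if isinstance(record, (list, tuple)) else [record]
    dicts = [_record_to_dict(r) for r in records]
    for d in dicts:
        missing = [k for k, v in d.items() if v is None and not k.startswith("_")]
        # None marks a legitimately undefined value (e.g. no rods); only
        # complain when the whole record is empty
        if d and all(v is None for v in d.values()):
            raise ValidationError(f"record has no populated fields: {missing}")

    if path.suffix.lower() == ".json":
        payload = dicts[0] if not isinstance(record, (list, tuple)) else dicts
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
        return path

    import pandas as pd

    rows = [_flatten(d) for d in dicts]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_results(path: str | Path, record_type=None):
    """Read back a CSV/JSON result file written by :func:`write_results`.

    Returns dicts (or a list of dicts for multi-row CSV); when
    ``record_type`` is given, flat records are rehydrated into it.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
    else:
        import pandas as pd

        df = pd.read_csv(path)
        payload = df.to_dict(orient="records")
        payload = [_unflatten(r) for r in payload]
        if len(payload) == 1:
            payload = payload[0]
    if record_type is not None:
        if isinstance(payload, list):
            return [record_type(**p) for p in payload]
        return record_type(**payload)
    return payload


def _unflatten(flat: dict) -> dict:
    out: dict = {}
    for key, value in flat.items():
        if isinstance(value, float) and np.isnan(value):
            value = None
        parts = key.split(".")
        node = out
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return out
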