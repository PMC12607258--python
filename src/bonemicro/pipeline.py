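"""Pipeline orchestration: single-volume analysis, cohort batches, and
run configuration with provenance.

``run_analyze`` sequences binarization -> cortical segmentation -> ITS /
CPS / CLA on one volume.  The trabecular compartment is the marrow region
inside the endosteal contour when a cortical shell is present, otherwise
the whole grid.  Stages fail independently: a volume without a cortical
shell still yields ITS results while CPS/CLA report a stage error.

``analyze_cohort`` closes the loop for phantom-mode cohorts: it generates
each subject's trabecular and cortical phantoms and fills the outcome
columns consumed by the stats stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binarize import BinarizationConfig, binarize
from .cla import cla_analyze
from .cortical_seg import segment_cortex
from .cps import cps_analyze_with_elements
from .its import its_parameters
from .phantoms import PhantomSpec, make_cortical_phantom, make_trabecular_phantom
from .skeleton_core import decompose
from .volume_io import BinaryMask, ImageVolume, read_volume, write_results

logger = logging.getLogger("bonemicro")

__all__ = ["RunConfig", "StageError", "AnalysisResult", "run_analyze", "run_batch", "analyze_cohort"]

_KNOWN_BLOCKS = {"io", "binarize", "cortical", "its", "cps", "cla", "phantom", "stats"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    Unknown blocks or keys are rejected so typos cannot silently fall
    back to defaults.  The effective configuration (plus seed and package
    version) is serialized next to every output for provenance.
    """

    io: dict = field(default_factory=dict)
    binarize: dict = field(default_factory=dict)
    cortical: dict = field(default_factory=dict)
    its: dict = field(default_factory=dict)
    cps: dict = field(default_factory=dict)
    cla: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        unknown = set(raw) - _KNOWN_BLOCKS - {"seed", "log_level"}
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        # instantiating the stage configs surfaces unknown keys early
        BinarizationConfig(**self.binarize)
        known_cortical = {"r_close", "min_pore_voxels"}
        if set(self.cortical) - known_cortical:
            raise ValueError(f"unknown [cortical] keys: {sorted(set(self.cortical) - known_cortical)}")
        known_its = {"axial_angle_deg"}
        if set(self.its) - known_its:
            raise ValueError(f"unknown [its] keys: {sorted(set(self.its) - known_its)}")

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class AnalysisResult:
    """Outputs of one volume analysis; failed stages carry an error note."""

    its: object | None = None
    cps: object | None = None
    cla: object | None = None
    masks: object | None = None
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _as_mask(vol: ImageVolume | BinaryMask, cfg: RunConfig) -> BinaryMask:
    if isinstance(vol, BinaryMask):
        return vol
    data = vol.data
    if data.dtype == bool or set(np.unique(data)) <= {0, 1}:
        return BinaryMask(data != 0, vol.spacing_mm, vol.axis_longitudinal, vol.origin_mm)
    return binarize(vol, BinarizationConfig(**cfg.binarize))


def run_analyze(volume: ImageVolume | BinaryMask | str | Path, config: RunConfig | None = None) -> AnalysisResult:
    """Analyze one volume end to end (binarize, cortical, ITS, CPS, CLA).

    Results are deterministic given the configuration.  Stage failures
    are collected in ``result.errors`` keyed by stage name; ITS can
    succeed on volumes without a cortical shell.
    """
    cfg = config or RunConfig()
    if isinstance(volume, (str, Path)):
        volume = read_volume(volume, **cfg.io)
    result = AnalysisResult(provenance=cfg.provenance())

    try:
        bone = _as_mask(volume, cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("binarize", exc) from exc

    masks = None
    try:
        masks = segment_cortex(bone, **cfg.cortical)
        result.masks = masks
    except Exception as exc:  # noqa: BLE001
        result.errors["cortical"] = str(StageError("cortical", exc))

    # trabecular compartment: marrow region when a shell exists, else the whole grid
    if masks is not None and masks.endosteal_mask.voxel_count > 0:
        trab_region = masks.endosteal_mask
    else:
        trab_region = bone.like(np.ones(bone.shape, bool))
    try:
        trab_bone = bone.like(bone.data & trab_region.data)
        em = decompose(trab_bone)
        result.its = its_parameters(em, trab_region, **cfg.its)
    except Exception as exc:  # noqa: BLE001
        result.errors["its"] = str(StageError("its", exc))

    if masks is not None:
        try:
            cps_result, pore_em = cps_analyze_with_elements(masks)
            result.cps = cps_result
            result.cla = cla_analyze(masks, pore_em)
        except Exception as exc:  # noqa: BLE001
            result.errors["cps"] = str(StageError("cps", exc))
    else:
        result.errors.setdefault("cps", "stage 'cps' failed: no cortical masks")
        result.errors.setdefault("cla", "stage 'cla' failed: no cortical masks")
    return result


def run_batch(manifest: pd.DataFrame | str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Analyze every volume of a manifest (CSV with a ``path`` column and
    arbitrary subject metadata).  Failures are logged and excluded; each
    row carries a status field."""
    cfg = config or RunConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    if "path" not in manifest.columns:
        raise ValueError("manifest needs a 'path' column")
    rows = []
    for _, row in manifest.iterrows():
        rec = dict(row)
        try:
            res = run_analyze(row["path"], cfg)
            rec["status"] = "ok"
            if res.its is not None:
                for k, v in dataclasses.asdict(res.its).items():
                    if isinstance(v, (int, float)) or v is None:
                        rec[f"its_{k}"] = v
            if res.cps is not None:
                for k, v in dataclasses.asdict(res.cps).items():
                    if isinstance(v, (int, float)) or v is None:
                        rec[f"cps_{k}"] = v
        except Exception as exc:  # noqa: BLE001
            logger.warning("batch row %s failed: %s", row.get("path"), exc)
            rec["status"] = f"failed: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)


def analyze_subject(trab_spec: PhantomSpec, cort_spec: PhantomSpec, axial_angle_deg: float = 30.0) -> dict:
    """Generate and analyze one subject's phantoms; returns outcome dict."""
    out: dict = {}
    tmask, _ = make_trabecular_phantom(trab_spec)
    em = decompose(tmask)
    bulk = BinaryMask(np.ones(tmask.shape, bool), tmask.spacing_mm, tmask.axis_longitudinal)
    its = its_parameters(em, bulk, axial_angle_deg=axial_angle_deg)
    for k in ("bv_tv", "p_bv_tv", "r_bv_tv", "pr_bv_ratio", "a_bv_tv", "p_bv_bv", "r_bv_bv"):
        out[k] = getattr(its, k)

    cmask, _ = make_cortical_phantom(cort_spec)
    masks = segment_cortex(cmask)
    cps_result, pore_em = cps_analyze_with_elements(masks)
    out["slabs_over_tubes"] = cps_result.slabs_over_tubes
    out["n_tube_tube_junctions"] = cps_result.n_tube_tube_junctions
    out["n_slab_pores"] = cps_result.n_slab_pores
    out["n_tube_pores"] = cps_result.n_tube_pores
    cla = cla_analyze(masks, pore_em)
    for layer in ("endosteal", "midcortical", "periosteal"):
        st = cla.layer(layer)
        out[f"{layer}_avg_pore_size_mm2"] = st.avg_pore_size_mm2
        out[f"{layer}_total_pore_area_mm2"] = st.total_pore_area_mm2
    return out


def analyze_cohort(tbl: pd.DataFrame, axial_angle_deg: float = 30.0) -> pd.DataFrame:
    """Run the full analyzer on every subject of a phantom-mode cohort
    table (adds outcome columns; see :func:`analyze_subject`)."""
    outcomes = []
    for _, row in tbl.iterrows():
        outcomes.append(analyze_subject(row["trabecular_spec"], row["cortical_spec"], axial_angle_deg))
    out_df = pd.DataFrame(outcomes, index=tbl.index)
    return pd.concat([tbl.drop(columns=["trabecular_spec", "cortical_spec"]), out_df], axis=1)


def write_analysis(result: AnalysisResult, out_prefix: str | Path) -> list[Path]:
    """Serialize all results + provenance under a path prefix."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("its", "cps", "cla"):
        rec = getattr(result, name)
        if rec is not None:
            written.append(write_results(rec, out_prefix.with_suffix(f".{name}.json")))
            written.append(write_results(rec, out_prefix.with_suffix(f".{name}.csv")))
    prov = out_prefix.with_suffix(".provenance.json")
    prov.write_text(json.dumps({"config": result.provenance, "errors": result.errors}, indent=2))
    written.append(prov)
    return written
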