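"""Per-voxel topographic index (TI) and its clone-level mean.

For every clone voxel *i* inside the reference neuropil, its fractional
dorsal-ventral position is

    TI_i = d_i / (d_i + v_i)

where ``d_i`` is the distance from the voxel to the dorsal neuropil boundary
and ``v_i`` the distance to the ventral boundary, measured parallel to the
designated D-V axis (both clipped at zero). The clone's TI is the unweighted
arithmetic mean of TI_i over all clone voxels inside the neuropil; 0 means
dorsal extreme, 1 ventral extreme. Clone voxels outside the neuropil mask are
counted and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateBoundaryError, EmptyMaskError, PipelineStageError
from .segmentation import (
    BoundaryProfile,
    LabelMask,
    extract_boundaries,
    segment_channel,
)
from .stack_io import SPATIAL_AXES, ImageStack, read_stack


@dataclass(frozen=True)
class TIConfig:
    """Parameters for the stack -> TI composition.

    ``threshold_method`` applies to both channels unless a per-channel method
    overrides it. Otsu assumes each channel has a sizeable foreground class;
    for a sparse clone channel (a small blob in a large volume) prefer
    ``fraction-of-max``, which is robust to extreme class imbalance.
    """

    clone_channel: str = "clone"
    reference_channel: str = "reference"
    threshold_method: str = "otsu"
    threshold_params: dict = field(default_factory=dict)
    clone_threshold_method: str | None = None
    clone_threshold_params: dict | None = None
    reference_threshold_method: str | None = None
    reference_threshold_params: dict | None = None
    boundary_mode: str = "global"

    def method_for(self, which: str) -> tuple[str, dict]:
        override = getattr(self, f"{which}_threshold_method")
        params = getattr(self, f"{which}_threshold_params")
        if override is not None:
            return override, dict(params or {})
        return self.threshold_method, dict(self.threshold_params)


#: Configuration suited to sparse single-clone channels: Otsu on the dense
#: reference channel, half-maximum threshold on the clone channel.
SPARSE_CLONE_CONFIG = TIConfig(
    clone_threshold_method="fraction-of-max",
    clone_threshold_params={"fraction": 0.5},
)


@dataclass(frozen=True)
class TIResult:
    """TI of one clone: per-voxel values, their mean, and provenance."""

    clone_id: str
    n_voxels_inside: int
    n_voxels_excluded: int
    n_voxels_clipped: int
    ti_per_voxel: np.ndarray
    ti_mean: float
    di_um: np.ndarray
    vi_um: np.ndarray
    mode: str
    provenance: dict = field(default_factory=dict)


def voxel_ti(
    clone_mask: LabelMask,
    neuropil_mask: LabelMask,
    boundaries: BoundaryProfile,
    clone_id: str = "clone",
) -> TIResult:
    """Compute per-voxel TI for every clone voxel inside the neuropil.

    ``boundaries`` must have been extracted from ``neuropil_mask`` (global or
    per-column mode). Distances are axis-parallel along the D-V axis in
    physical units; voxels beyond a boundary are clipped to it (TI_i pinned to
    0 or 1) and counted in ``n_voxels_clipped``.
    """
    if clone_mask.mask.shape != neuropil_mask.mask.shape:
        raise EmptyMaskError("clone and neuropil masks are on different grids")
    inside = clone_mask.mask & neuropil_mask.mask
    n_excluded = int(clone_mask.mask.sum()) - int(inside.sum())
    if not inside.any():
        raise EmptyMaskError("no clone voxels inside the neuropil mask")

    dv = SPATIAL_AXES.index(boundaries.dv_axis)
    idx = np.nonzero(inside)
    coords = idx[dv].astype(float) * boundaries.dv_spacing

    if boundaries.mode == "global":
        d_ext = np.full(coords.shape, float(boundaries.dorsal_extent))
        v_ext = np.full(coords.shape, float(boundaries.ventral_extent))
    else:
        col = tuple(idx[a] for a in range(3) if a != dv)
        d_ext = np.asarray(boundaries.dorsal_extent)[col]
        v_ext = np.asarray(boundaries.ventral_extent)[col]
        if np.isnan(d_ext).any():
            raise EmptyMaskError("clone voxel in a column with no reference signal")

    raw_d = coords - d_ext
    raw_v = v_ext - coords
    di = np.clip(raw_d, 0.0, None)
    vi = np.clip(raw_v, 0.0, None)
    n_clipped = int(np.sum((raw_d < 0) | (raw_v < 0)))
    total = di + vi
    if np.any(total <= 0):
        raise DegenerateBoundaryError(
            "dorsal and ventral extents coincide at a clone voxel; TI undefined"
        )
    ti = di / total
    return TIResult(
        clone_id=clone_id,
        n_voxels_inside=int(inside.sum()),
        n_voxels_excluded=n_excluded,
        n_voxels_clipped=n_clipped,
        ti_per_voxel=ti,
        ti_mean=float(ti.mean()),
        di_um=di,
        vi_um=vi,
        mode=boundaries.mode,
    )


def clone_ti_from_stack(
    stack: ImageStack, config: TIConfig = TIConfig(), clone_id: str = "clone"
) -> TIResult:
    """Segment clone + reference channels, extract boundaries, compute TI.

    Failures carry the name of the stage that raised them. Thresholds and the
    boundary mode used are recorded in the result's provenance.
    """
    try:
        c_method, c_params = config.method_for("clone")
        r_method, r_params = config.method_for("reference")
        clone = segment_channel(stack, config.clone_channel, c_method, **c_params)
        reference = segment_channel(stack, config.reference_channel, r_method, **r_params)
    except Exception as exc:
        raise PipelineStageError("segmentation", exc) from exc
    try:
        boundaries = extract_boundaries(
            reference,
            mode=config.boundary_mode,
            dv_axis=stack.dv_axis,
            dv_spacing=stack.dv_spacing,
        )
    except Exception as exc:
        raise PipelineStageError("boundaries", exc) from exc
    try:
        result = voxel_ti(clone, reference, boundaries, clone_id=clone_id)
    except Exception as exc:
        raise PipelineStageError("topography", exc) from exc
    provenance = {
        "threshold_method_clone": c_method,
        "threshold_method_reference": r_method,
        "threshold_clone": clone.threshold_value,
        "threshold_reference": reference.threshold_value,
        "boundary_mode": config.boundary_mode,
        "dv_axis": stack.dv_axis,
    }
    return replace(result, provenance=provenance)


def batch_ti(
    manifest: pd.DataFrame,
    config: TIConfig = TIConfig(),
    read_kwargs: Mapping | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Compute TI for every stack listed in a manifest.

    ``manifest`` needs columns ``path``, ``clone_id`` and ``group``. Per-file
    failures are collected (path + stage + message) and the run continues; the
    returned table holds one row per successful stack.
    """
    rows: list[dict] = []
    failures: list[dict] = []
    for rec in manifest.to_dict("records"):
        try:
            stack = read_stack(rec["path"], **(read_kwargs or {}))
            res = clone_ti_from_stack(stack, config, clone_id=str(rec["clone_id"]))
        except Exception as exc:  # noqa: BLE001 - per-file failure is recoverable
            failures.append({"path": str(rec["path"]), "error": str(exc)})
            continue
        rows.append(
            {
                "clone_id": res.clone_id,
                "group": rec.get("group", ""),
                "ti_mean": round(res.ti_mean, 4),
                "n_voxels_inside": res.n_voxels_inside,
                "n_voxels_excluded": res.n_voxels_excluded,
                "mode": res.mode,
                "threshold_clone": res.provenance.get("threshold_clone"),
                "threshold_reference": res.provenance.get("threshold_reference"),
                "path": str(rec["path"]),
            }
        )
    return pd.DataFrame(rows), failures


def write_ti_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False)
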