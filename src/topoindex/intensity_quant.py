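"""ROI-based intensity ratio quantifications.

Covers the three normalized-ratio measurements: a signal channel normalized
to a reference channel within the same ROI on a max-intensity projection
(nuclear staining ratios), and region-wide channel ratios over a 3D mask
(synaptic-contact reporter normalized to its expression control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import QuantError
from .segmentation import LabelMask
from .stack_io import SPATIAL_AXES, ImageStack


@dataclass(frozen=True)
class ROI:
    """A labelled region: boolean mask (2D pixel or 3D voxel) plus the channel
    it was drawn from."""

    id: str
    mask: np.ndarray
    definition_channel: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim not in (2, 3):
            raise QuantError(f"ROI mask must be 2D or 3D, got ndim={m.ndim}")
        if not m.any():
            raise QuantError(f"ROI {self.id!r} is empty")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class ROIQuant:
    roi_id: str
    signal_stat: float
    reference_stat: float
    ratio: float
    stat: str
    projection: str


def max_project(stack: ImageStack, axis: str = "z") -> dict[str, np.ndarray]:
    """Max-intensity projection along the depth axis, per channel."""
    if axis not in SPATIAL_AXES:
        raise QuantError(f"axis must be one of {SPATIAL_AXES}, got {axis!r}")
    ax = 1 + SPATIAL_AXES.index(axis)
    proj = stack.voxels.max(axis=ax)
    return {name: proj[i] for i, name in enumerate(stack.channel_names)}


def _stat(values: np.ndarray, stat: str) -> float:
    if stat == "mean":
        return float(values.mean())
    if stat == "sum":
        return float(values.sum())
    raise QuantError(f"unknown statistic {stat!r} (use 'mean' or 'sum')")


def roi_ratio(
    signal: np.ndarray,
    reference: np.ndarray,
    roi: ROI,
    stat: str = "mean",
    projection: str = "none",
) -> ROIQuant:
    """Ratio of a signal-channel statistic to the reference-channel statistic
    over the identical ROI (mean and sum give the same ratio; the choice is
    recorded anyway)."""
    signal = np.asarray(signal)
    reference = np.asarray(reference)
    if signal.shape != reference.shape:
        raise QuantError("signal and reference images are on different grids")
    if roi.mask.shape != signal.shape:
        raise QuantError(
            f"ROI {roi.id!r} shape {roi.mask.shape} does not match image shape {signal.shape}"
        )
    sig = _stat(signal[roi.mask], stat)
    ref = _stat(reference[roi.mask], stat)
    if ref <= 0:
        raise QuantError(f"reference statistic is {ref:g} in ROI {roi.id!r}; ratio undefined")
    return ROIQuant(
        roi_id=roi.id,
        signal_stat=sig,
        reference_stat=ref,
        ratio=sig / ref,
        stat=stat,
        projection=projection,
    )


def grasp_ratio(
    grasp: np.ndarray,
    expression_control: np.ndarray,
    region: LabelMask,
    stat: str = "sum",
) -> ROIQuant:
    """Reconstituted-reporter intensity normalized by its expression control
    over the same 3D region (default: summed intensity)."""
    grasp = np.asarray(grasp)
    control = np.asarray(expression_control)
    if grasp.shape != control.shape or grasp.shape != region.mask.shape:
        raise QuantError("grasp, control and region must share one grid")
    if not region.mask.any():
        raise QuantError("quantification region is empty")
    num = _stat(grasp[region.mask], stat)
    den = _stat(control[region.mask], stat)
    if den <= 0:
        raise QuantError("expression-control statistic is zero; ratio undefined")
    return ROIQuant(
        roi_id=region.channel,
        signal_stat=num,
        reference_stat=den,
        ratio=num / den,
        stat=stat,
        projection="none",
    )


def measure_roi_ratios(
    stack: ImageStack,
    rois: Sequence[ROI],
    signal_channel: str = "signal",
    reference_channel: str = "reference",
    stat: str = "mean",
    projection: str = "max-z",
) -> pd.DataFrame:
    """Quantify every ROI on a stack, optionally on max-z projections.

    2D ROIs require ``projection='max-z'``; 3D ROIs use the raw volumes.
    Returns a tidy table (roi_id, signal_stat, reference_stat, ratio).
    """
    if projection == "max-z":
        proj = max_project(stack, axis="z")
        sig, ref = proj[signal_channel], proj[reference_channel]
    elif projection == "none":
        sig, ref = stack.channel(signal_channel), stack.channel(reference_channel)
    else:
        raise QuantError(f"unknown projection {projection!r}")
    rows = []
    for roi in rois:
        q = roi_ratio(sig, ref, roi, stat=stat, projection=projection)
        rows.append(
            {
                "roi_id": q.roi_id,
                "signal_stat": q.signal_stat,
                "reference_stat": q.reference_stat,
                "ratio": q.ratio,
            }
        )
    return pd.DataFrame(rows)
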