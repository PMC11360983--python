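"""Channel thresholding and dorsal/ventral boundary extraction.

Masks record the thresholding provenance that produced them. Boundaries are
the dorsal-most and ventral-most reference-positive coordinates along the D-V
axis, either as global scalars (default) or independently per (A-P, depth)
column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .errors import DegenerateBoundaryError, EmptyMaskError, SegmentationError
from .stack_io import SPATIAL_AXES, ImageStack


@dataclass(frozen=True)
class LabelMask:
    """Boolean voxel mask for one channel, with thresholding provenance."""

    mask: np.ndarray
    channel: str
    threshold_method: str
    threshold_value: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise SegmentationError(f"mask must be 3D, got ndim={m.ndim}")
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BoundaryProfile:
    """Dorsal/ventral extents of the reference neuropil along the D-V axis.

    In ``global`` mode the extents are scalars (physical coordinates, um). In
    ``per-column`` mode they are 2D arrays over the two non-D-V axes, NaN on
    columns that do not intersect the reference mask.
    """

    mode: str
    dorsal_extent: float | np.ndarray
    ventral_extent: float | np.ndarray
    dv_axis: str
    dv_spacing: float

    @property
    def is_degenerate(self) -> bool:
        """True when the extents coincide everywhere they are defined."""
        if self.mode == "global":
            return bool(self.dorsal_extent >= self.ventral_extent)
        d, v = self.dorsal_extent, self.ventral_extent
        defined = ~np.isnan(np.asarray(d))
        return bool(np.all(np.asarray(d)[defined] >= np.asarray(v)[defined]))


def segment_channel(
    stack: ImageStack,
    channel: str,
    method: str = "otsu",
    *,
    value: float | None = None,
    fraction: float = 0.5,
) -> LabelMask:
    """Threshold one channel into a boolean mask (``intensity > threshold``).

    Methods: ``otsu`` (between-class variance maximization), ``fixed``
    (explicit ``value``), ``fraction-of-max`` (``fraction`` of the channel
    maximum). An empty result mask is an error: it signals failed staining or
    a threshold above all signal.
    """
    img = stack.channel(channel)
    if method == "otsu":
        if np.all(img == img.flat[0]):
            raise SegmentationError(f"channel {channel!r} is constant; Otsu is undefined")
        thr = float(threshold_otsu(img))
    elif method == "fixed":
        if value is None:
            raise SegmentationError("method 'fixed' requires a threshold value")
        thr = float(value)
    elif method == "fraction-of-max":
        if not 0 <= fraction < 1:
            raise SegmentationError("fraction must be in [0, 1)")
        thr = float(fraction) * float(img.max())
    else:
        raise SegmentationError(f"unknown threshold method {method!r}")

    mask = img > thr
    if not mask.any():
        raise SegmentationError(
            f"thresholding channel {channel!r} at {thr:g} ({method}) left no voxels"
        )
    return LabelMask(mask=mask, channel=channel, threshold_method=method, threshold_value=thr)


def extract_boundaries(
    reference_mask: LabelMask,
    mode: str = "global",
    *,
    dv_axis: str = "y",
    dv_spacing: float = 1.0,
) -> BoundaryProfile:
    """Locate the dorsal-most / ventral-most reference signal along D-V.

    ``global``: extents are the min/max D-V coordinate over every reference
    voxel. ``per-column``: the same, computed independently within each
    column of voxels parallel to the D-V axis.
    """
    m = reference_mask.mask
    if not m.any():
        raise EmptyMaskError("reference mask is empty; no boundaries to extract")
    dv = SPATIAL_AXES.index(dv_axis)
    if mode == "global":
        idx = np.nonzero(m)[dv]
        return BoundaryProfile(
            mode="global",
            dorsal_extent=float(idx.min() * dv_spacing),
            ventral_extent=float(idx.max() * dv_spacing),
            dv_axis=dv_axis,
            dv_spacing=float(dv_spacing),
        )
    if mode == "per-column":
        cols = np.moveaxis(m, dv, 0)  # (n_dv, a, b)
        any_col = cols.any(axis=0)
        if not any_col.any():
            raise EmptyMaskError("no column intersects the reference mask")
        n_dv = cols.shape[0]
        first = np.argmax(cols, axis=0).astype(float)
        last = (n_dv - 1 - np.argmax(cols[::-1], axis=0)).astype(float)
        dorsal = np.where(any_col, first * dv_spacing, np.nan)
        ventral = np.where(any_col, last * dv_spacing, np.nan)
        return BoundaryProfile(
            mode="per-column",
            dorsal_extent=dorsal,
            ventral_extent=ventral,
            dv_axis=dv_axis,
            dv_spacing=float(dv_spacing),
        )
    raise SegmentationError(f"unknown boundary mode {mode!r}")


def check_not_degenerate(boundaries: BoundaryProfile) -> None:
    """Raise if the neuropil has zero D-V thickness (TI undefined)."""
    if boundaries.is_degenerate:
        raise DegenerateBoundaryError(
            "dorsal and ventral extents coincide; topographic index is undefined"
        )


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Export a mask as an 8-bit TIFF (0 / 255)."""
    tifffile.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def boundaries_to_csv(profile: BoundaryProfile, path: str | Path) -> None:
    """Write boundary extents as CSV (one row globally, or one per column)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if profile.mode == "global":
            w.writerow(["mode", "dorsal_extent_um", "ventral_extent_um"])
            w.writerow(["global", profile.dorsal_extent, profile.ventral_extent])
            return
        w.writerow(["col_a", "col_b", "dorsal_extent_um", "ventral_extent_um"])
        d = np.asarray(profile.dorsal_extent)
        v = np.asarray(profile.ventral_extent)
        for a, b in zip(*np.nonzero(~np.isnan(d))):
            w.writerow([int(a), int(b), d[a, b], v[a, b]])
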