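"""Multi-channel 3D stack container, TIFF I/O, and geometric preprocessing.

A stack is stored channel-major as ``(channel, z, y, x)``. One spatial axis is
designated the dorsal-ventral (D-V) axis; by convention, after orientation the
dorsal side sits at the *low*-index end of that axis. Voxel positions are voxel
centers; physical coordinates along an axis are ``index * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .errors import EmptyMaskError, StackIOError

#: Names of the three spatial axes, in array order (after the channel axis).
SPATIAL_AXES = ("z", "y", "x")


@dataclass(frozen=True)
class ImageStack:
    """A nonnegative multi-channel 3D intensity volume with axis metadata.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, nz, ny, nx)``; intensities must be >= 0.
    spacing_um
        Physical step per spatial axis, ``(z, y, x)``, in micrometres.
    channel_names
        One label per channel (e.g. ``("clone", "reference")``).
    dv_axis
        Which spatial axis ("z", "y" or "x") carries the dorsal-ventral
        direction. Dorsal is at the low-index end (enforce with
        :func:`orient_stack`).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float] = (0.3, 0.3, 0.3)
    channel_names: tuple[str, ...] = ("clone", "reference")
    dv_axis: str = "y"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise StackIOError(f"voxels must be 4D (channel, z, y, x), got ndim={v.ndim}")
        if v.size and float(v.min()) < 0:
            raise StackIOError("intensities must be nonnegative")
        if len(self.channel_names) != v.shape[0]:
            raise StackIOError(
                f"{len(self.channel_names)} channel names for {v.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise StackIOError("channel names must be unique")
        if self.dv_axis not in SPATIAL_AXES:
            raise StackIOError(f"dv_axis must be one of {SPATIAL_AXES}, got {self.dv_axis!r}")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise StackIOError("spacing_um must be three positive steps")
        object.__setattr__(self, "voxels", v)

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def dv_index(self) -> int:
        """Index of the D-V axis among the three spatial axes (0..2)."""
        return SPATIAL_AXES.index(self.dv_axis)

    @property
    def dv_spacing(self) -> float:
        return float(self.spacing_um[self.dv_index])

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise StackIOError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.voxels[i]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path, extra_metadata: dict | None = None) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON sidecar with metadata.

    Pages are channel-major: all z-slices of channel 0, then channel 1, etc.
    Returns the sidecar path.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.voxels), photometric="minisblack")
    meta = {
        "spacing_um": list(stack.spacing_um),
        "channel_names": list(stack.channel_names),
        "dv_axis": stack.dv_axis,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    axis_config: Mapping[str, object] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF back into an :class:`ImageStack`.

    Metadata defaults come from the JSON sidecar written by
    :func:`write_stack`, if present; ``channel_map`` (name -> channel index)
    and ``axis_config`` (keys ``dv_axis``, ``spacing_um``) override it.
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"no such file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as a distinct diagnostic
        raise StackIOError(f"unreadable TIFF {path}: {exc}") from exc
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise StackIOError(f"expected 3D or 4D TIFF data, got ndim={data.ndim}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    names = tuple(meta.get("channel_names", [f"ch{i}" for i in range(data.shape[0])]))
    if channel_map is not None:
        for name, idx in channel_map.items():
            if not 0 <= idx < data.shape[0]:
                raise StackIOError(
                    f"channel {name!r} maps to index {idx} but file has "
                    f"{data.shape[0]} channel(s)"
                )
        names = tuple(channel_map.keys())
        data = data[[channel_map[n] for n in names]]

    spacing = tuple(meta.get("spacing_um", (0.3, 0.3, 0.3)))
    dv_axis = str(meta.get("dv_axis", "y"))
    if axis_config:
        dv_axis = str(axis_config.get("dv_axis", dv_axis))
        spacing = tuple(axis_config.get("spacing_um", spacing))  # type: ignore[arg-type]
    return ImageStack(data, spacing_um=spacing, channel_names=names, dv_axis=dv_axis)


def orient_stack(
    stack: ImageStack,
    flip_dv: bool = False,
    transpose: Sequence[str] | None = None,
) -> ImageStack:
    """Reorder/flip spatial axes so dorsal lies at the low-index end of D-V.

    ``transpose`` is a permutation of ``("z", "y", "x")`` naming, for each new
    spatial slot, which old axis fills it. The D-V designation follows its
    axis. ``flip_dv`` reverses the stack along the D-V axis (declaring the
    opposite end dorsal); applying it twice restores the original.
    """
    v = stack.voxels
    spacing = list(stack.spacing_um)
    dv_axis = stack.dv_axis
    if transpose is not None:
        if sorted(transpose) != sorted(SPATIAL_AXES):
            raise StackIOError(f"transpose must permute {SPATIAL_AXES}, got {tuple(transpose)}")
        order = [SPATIAL_AXES.index(a) for a in transpose]
        v = np.transpose(v, [0] + [1 + i for i in order])
        spacing = [spacing[i] for i in order]
        dv_axis = SPATIAL_AXES[list(transpose).index(dv_axis)]
    if flip_dv:
        v = np.flip(v, axis=1 + SPATIAL_AXES.index(dv_axis))
    return replace(
        stack,
        voxels=np.ascontiguousarray(v),
        spacing_um=tuple(spacing),
        dv_axis=dv_axis,
    )


def crop_to_mask(stack: ImageStack, mask: np.ndarray, margin_vox: int = 0) -> ImageStack:
    """Crop to the bounding box of ``mask`` plus a margin, clipped to bounds.

    ``mask`` may be a boolean array on the stack's spatial grid or any object
    with a boolean ``.mask`` attribute. Axis metadata is preserved.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.shape != stack.spatial_shape:
        raise StackIOError(f"mask shape {m.shape} != stack spatial shape {stack.spatial_shape}")
    if not m.any():
        raise EmptyMaskError("cannot crop to an empty mask")
    if margin_vox < 0:
        raise StackIOError("margin_vox must be >= 0")
    slices = [slice(None)]
    for ax in range(3):
        idx = np.nonzero(m.any(axis=tuple(i for i in range(3) if i != ax)))[0]
        lo = max(int(idx[0]) - margin_vox, 0)
        hi = min(int(idx[-1]) + margin_vox + 1, m.shape[ax])
        slices.append(slice(lo, hi))
    return replace(stack, voxels=np.ascontiguousarray(stack.voxels[tuple(slices)]))


def subtract_background(
    stack: ImageStack,
    method: str = "constant",
    *,
    constant: float = 0.0,
    size: int = 10,
    percentile: float = 10.0,
) -> ImageStack:
    """Subtract an intensity background estimate, clipping results at zero.

    ``constant`` subtracts a fixed offset; ``rolling-percentile`` subtracts a
    per-channel moving-window percentile (a stand-in for instrument-specific
    restoration, which is out of scope).
    """
    if method == "constant":
        if constant < 0:
            raise StackIOError("background constant must be >= 0")
        out = np.clip(stack.voxels.astype(float) - constant, 0, None)
    elif method == "rolling-percentile":
        out = np.empty_like(stack.voxels, dtype=float)
        for c in range(stack.n_channels):
            bg = ndimage.percentile_filter(stack.voxels[c].astype(float), percentile, size=size)
            out[c] = np.clip(stack.voxels[c] - bg, 0, None)
    else:
        raise StackIOError(f"unknown background method {method!r}")
    return replace(stack, voxels=out)
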