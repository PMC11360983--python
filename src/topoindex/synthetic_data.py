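"""Ground-truth-labelled synthetic stacks and tabular fixtures.

Emulates a compact neuropil volume (box or ellipsoid) in a two-channel stack:
the reference channel fills the neuropil solid, the clone channel fills a
compact blob centred at a known fractional dorsal-ventral position ``q``.
Optical blur and Poisson + Gaussian noise are applied to intensities only;
ground-truth masks are kept pre-noise. Output is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .intensity_quant import ROI
from .stack_io import ImageStack, write_stack


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise. ``poisson_scale`` is expected photons per intensity
    unit (0 disables shot noise); ``gaussian_sd`` is the read-noise sd."""

    poisson_scale: float = 1.0
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-channel stack.

    ``dv_extent`` gives the inclusive voxel-index span ``(y_d, y_v)`` of the
    neuropil along the D-V axis (axis ``y``); ``clone_position_q`` places the
    clone blob at fractional position q between those extents (0 = dorsal).
    """

    stack_shape: tuple[int, int, int] = (24, 64, 32)  # (z, y, x)
    spacing_um: tuple[float, float, float] = (0.3, 0.3, 0.3)
    geometry: str = "box"  # or "ellipsoid"
    dv_extent: tuple[int, int] = (8, 55)
    clone_position_q: float = 0.5
    clone_size_vox: int = 150
    blur_sigma_um: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    background_level: float = 0.0
    signal_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clone_position_q <= 1.0:
            raise ValueError("clone_position_q must lie in [0, 1]")
        y_d, y_v = self.dv_extent
        if not 0 <= y_d < y_v < self.stack_shape[1]:
            raise ValueError(
                f"degenerate D-V geometry: need 0 <= y_d < y_v < ny, got {self.dv_extent}"
            )
        if self.geometry not in ("box", "ellipsoid"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.clone_size_vox < 1:
            raise ValueError("clone_size_vox must be >= 1")
        if self.blur_sigma_um < 0:
            raise ValueError("blur_sigma_um must be >= 0")
        if self.background_level < 0 or self.signal_level <= 0:
            raise ValueError("background must be >= 0 and signal level > 0")
        if any(n < 3 for n in self.stack_shape):
            raise ValueError("stack_shape axes must each be >= 3")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Pre-noise truth for one synthetic stack."""

    true_q: float
    true_neuropil_mask: np.ndarray
    true_clone_mask: np.ndarray
    seed: int


def _neuropil_mask(spec: SyntheticSpec) -> np.ndarray:
    nz, ny, nx = spec.stack_shape
    y_d, y_v = spec.dv_extent
    z0, z1 = max(1, nz // 8), nz - max(1, nz // 8)
    x0, x1 = max(1, nx // 8), nx - max(1, nx // 8)
    mask = np.zeros(spec.stack_shape, dtype=bool)
    if spec.geometry == "box":
        mask[z0:z1, y_d : y_v + 1, x0:x1] = True
        return mask
    # ellipsoid with D-V equator exactly spanning [y_d, y_v]
    zc, yc, xc = (z0 + z1 - 1) / 2, (y_d + y_v) / 2, (x0 + x1 - 1) / 2
    rz, ry, rx = max((z1 - z0 - 1) / 2, 1), (y_v - y_d) / 2, max((x1 - x0 - 1) / 2, 1)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    mask = ((zz - zc) / rz) ** 2 + ((yy - yc) / ry) ** 2 + ((xx - xc) / rx) ** 2 <= 1.0
    return mask


def _clone_mask(spec: SyntheticSpec, neuropil: np.ndarray) -> np.ndarray:
    """Gaussian-profile ball thresholded to clone_size_vox voxels, restricted
    to the neuropil, centred at fractional D-V position q."""
    nz, ny, nx = spec.stack_shape
    y_d, y_v = spec.dv_extent
    centers = ndimage.center_of_mass(neuropil)
    yc = y_d + spec.clone_position_q * (y_v - y_d)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    r2 = (zz - centers[0]) ** 2 + (yy - yc) ** 2 + (xx - centers[2]) ** 2
    r2 = np.where(neuropil, r2, np.inf)
    k = min(spec.clone_size_vox, int(neuropil.sum()))
    order = np.argsort(r2.ravel(), kind="stable")[:k]
    mask = np.zeros(spec.stack_shape, dtype=bool)
    mask.ravel()[order] = True
    return mask


def generate_stack(spec: SyntheticSpec) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a two-channel (clone, reference) stack from a spec.

    Intensity = background + signal on each channel's true mask, blurred by a
    Gaussian of ``blur_sigma_um``, then corrupted by shot/read noise. The
    returned ground truth stores the pre-noise masks and q verbatim.
    """
    rng = np.random.default_rng(spec.seed)
    neuropil = _neuropil_mask(spec)
    clone = _clone_mask(spec, neuropil)

    channels = []
    sigma_vox = tuple(spec.blur_sigma_um / s for s in spec.spacing_um)
    for mask in (clone, neuropil):
        img = spec.background_level + spec.signal_level * mask.astype(float)
        if spec.blur_sigma_um > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if spec.noise.poisson_scale > 0:
            img = rng.poisson(img * spec.noise.poisson_scale) / spec.noise.poisson_scale
        if spec.noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.noise.gaussian_sd, size=img.shape)
        channels.append(np.clip(img, 0, None))

    stack = ImageStack(
        np.stack(channels),
        spacing_um=spec.spacing_um,
        channel_names=("clone", "reference"),
        dv_axis="y",
    )
    truth = SyntheticGroundTruth(
        true_q=spec.clone_position_q,
        true_neuropil_mask=neuropil,
        true_clone_mask=clone,
        seed=spec.seed,
    )
    return stack, truth


def write_synthetic_stack(
    spec: SyntheticSpec, path: str | Path, extra_metadata: dict | None = None
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Generate, write TIFF + sidecar (spec, seed, true_q), return both."""
    stack, truth = generate_stack(spec)
    meta = {
        "true_q": truth.true_q,
        "seed": spec.seed,
        "spec": {
            "stack_shape": list(spec.stack_shape),
            "geometry": spec.geometry,
            "dv_extent": list(spec.dv_extent),
            "clone_position_q": spec.clone_position_q,
            "clone_size_vox": spec.clone_size_vox,
            "blur_sigma_um": spec.blur_sigma_um,
            "poisson_scale": spec.noise.poisson_scale,
            "gaussian_sd": spec.noise.gaussian_sd,
            "background_level": spec.background_level,
            "signal_level": spec.signal_level,
        },
    }
    if extra_metadata:
        meta.update(extra_metadata)
    write_stack(stack, path, extra_metadata=meta)
    return stack, truth


def generate_roi_fixture(
    n_cells: int,
    ratio_true: float | Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    reference_level: float = 100.0,
) -> tuple[ImageStack, list[ROI], pd.DataFrame]:
    """Two-channel stack of disjoint square "cells" with known signal/reference
    ratios, plus the ROIs outlining them and a truth table.

    Within each ROI the signal channel equals ``ratio_true * reference`` (plus
    optional Gaussian noise everywhere). ROI masks are 2D, matching
    quantification on a max-intensity projection.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ratios = np.broadcast_to(np.asarray(ratio_true, dtype=float), (n_cells,)).copy()
    if np.any(ratios <= 0):
        raise ValueError("ratio_true values must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    cell, gap, nz = 8, 4, 3
    per_row = int(np.ceil(np.sqrt(n_cells)))
    side = per_row * (cell + gap) + gap
    signal = np.zeros((nz, side, side))
    reference = np.zeros((nz, side, side))
    rois: list[ROI] = []
    records = []
    for i in range(n_cells):
        r, c = divmod(i, per_row)
        y0 = gap + r * (cell + gap)
        x0 = gap + c * (cell + gap)
        roi_mask = np.zeros((side, side), dtype=bool)
        roi_mask[y0 : y0 + cell, x0 : x0 + cell] = True
        reference[:, roi_mask] = reference_level
        signal[:, roi_mask] = ratios[i] * reference_level
        rois.append(ROI(id=f"cell{i}", mask=roi_mask, definition_channel="reference"))
        records.append({"roi_id": f"cell{i}", "ratio_true": float(ratios[i])})
    if noise_sd > 0:
        signal = signal + rng.normal(0, noise_sd, signal.shape)
        reference = reference + rng.normal(0, noise_sd, reference.shape)
    stack = ImageStack(
        np.clip(np.stack([signal, reference]), 0, None),
        spacing_um=(0.3, 0.3, 0.3),
        channel_names=("signal", "reference"),
        dv_axis="y",
    )
    return stack, rois, pd.DataFrame(records)


def generate_group_dataset(
    group_means: Sequence[float],
    group_sds: Sequence[float],
    n_per_group: int | Sequence[int],
    seed: int = 0,
    group_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy (group, value) table with Gaussian structure, for the stats layer."""
    means = list(group_means)
    sds = list(group_sds)
    if np.isscalar(n_per_group):
        ns = [int(n_per_group)] * len(means)
    else:
        ns = [int(n) for n in n_per_group]  # type: ignore[union-attr]
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("group_means, group_sds and n_per_group lengths must agree")
    if any(sd < 0 for sd in sds):
        raise ValueError("group_sds must be >= 0")
    if any(n < 2 for n in ns):
        raise ValueError("each group needs n >= 2")
    names = list(group_names) if group_names is not None else [f"g{i}" for i in range(len(means))]
    rng = np.random.default_rng(seed)
    rows = []
    for name, mu, sd, n in zip(names, means, sds, ns):
        for v in rng.normal(mu, sd, n):
            rows.append({"group": name, "value": float(v)})
    return pd.DataFrame(rows)
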