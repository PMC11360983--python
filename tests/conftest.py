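"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from topoindex import LabelMask, NoiseModel, SyntheticSpec


def brute_force_ti(
    clone: np.ndarray, neuropil: np.ndarray, dv_axis: int = 1, spacing: float = 1.0
) -> tuple[list[float], int]:
    """Independent per-voxel enumeration of the TI (global boundaries).

    Pure-python loops, no vectorization: the oracle the fast path is checked
    against. Returns (per-voxel TI list, n excluded).
    """
    ref_coords = [idx[dv_axis] * spacing for idx in zip(*np.nonzero(neuropil))]
    d_ext, v_ext = min(ref_coords), max(ref_coords)
    tis: list[float] = []
    excluded = 0
    for idx in zip(*np.nonzero(clone)):
        if not neuropil[idx]:
            excluded += 1
            continue
        coord = idx[dv_axis] * spacing
        di = max(coord - d_ext, 0.0)
        vi = max(v_ext - coord, 0.0)
        tis.append(di / (di + vi))
    return tis, excluded


def random_mask_pair(
    rng: np.random.Generator, shape: tuple[int, int, int]
) -> tuple[LabelMask, LabelMask]:
    """Random clone/neuropil masks guaranteed valid for TI computation:
    the neuropil spans >= 2 distinct D-V positions and intersects the clone."""
    while True:
        neuropil = rng.random(shape) < 0.5
        clone = rng.random(shape) < 0.3
        if not neuropil.any():
            continue
        ys = np.nonzero(neuropil)[1]
        if ys.min() == ys.max():
            continue
        inter = clone & neuropil
        if not inter.any():
            continue
        # no clone voxel may sit in a zero-thickness position set when both
        # extremes coincide -- guaranteed above for global mode
        return (
            LabelMask(clone, "clone", "fixed", 0.5),
            LabelMask(neuropil, "reference", "fixed", 0.5),
        )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240322)


@pytest.fixture
def clean_spec() -> SyntheticSpec:
    """Noise-free, blur-free synthetic spec (exact two-level images)."""
    return SyntheticSpec(
        clone_position_q=0.5,
        blur_sigma_um=0.0,
        noise=NoiseModel(poisson_scale=0.0, gaussian_sd=0.0),
        background_level=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_spec() -> SyntheticSpec:
    """Realistic spec: 1.5-voxel blur, shot + read noise, SNR well above 5."""
    return SyntheticSpec(
        clone_position_q=0.5,
        blur_sigma_um=0.45,
        noise=NoiseModel(poisson_scale=1.0, gaussian_sd=8.0),
        background_level=10.0,
        seed=7,
    )
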