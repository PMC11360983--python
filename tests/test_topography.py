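"""Tests for the per-voxel topographic index and its composition paths."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from topoindex import (
    DegenerateBoundaryError,
    EmptyMaskError,
    LabelMask,
    NoiseModel,
    PipelineStageError,
    SPARSE_CLONE_CONFIG,
    SyntheticSpec,
    batch_ti,
    clone_ti_from_stack,
    extract_boundaries,
    generate_stack,
    orient_stack,
    voxel_ti,
    write_synthetic_stack,
)
from conftest import brute_force_ti, random_mask_pair


def box_neuropil(shape=(3, 11, 3), y0=0, y1=10) -> LabelMask:
    m = np.zeros(shape, dtype=bool)
    m[:, y0 : y1 + 1, :] = True
    return LabelMask(m, "reference", "fixed", 0.0)


def point_clone(shape, points) -> LabelMask:
    m = np.zeros(shape, dtype=bool)
    for p in points:
        m[p] = True
    return LabelMask(m, "clone", "fixed", 0.0)


class TestVoxelTI:
    def test_voxel_at_dorsal_extent_is_zero(self):
        neuropil = box_neuropil()
        clone = point_clone(neuropil.mask.shape, [(1, 0, 1)])
        b = extract_boundaries(neuropil)
        res = voxel_ti(clone, neuropil, b)
        assert res.ti_per_voxel.tolist() == [0.0]
        assert res.ti_mean == 0.0

    def test_voxel_at_ventral_extent_is_one(self):
        neuropil = box_neuropil()
        clone = point_clone(neuropil.mask.shape, [(1, 10, 1)])
        res = voxel_ti(clone, neuropil, extract_boundaries(neuropil))
        assert res.ti_mean == 1.0

    def test_equidistant_voxel_is_half(self):
        neuropil = box_neuropil()
        clone = point_clone(neuropil.mask.shape, [(1, 5, 1)])
        res = voxel_ti(clone, neuropil, extract_boundaries(neuropil))
        assert res.ti_mean == 0.5

    def test_four_voxel_hand_example(self):
        # neuropil spans y = 0..10; voxels at y = 2, 4, 6, 8 sit at fractional
        # positions 0.2, 0.4, 0.6, 0.8 -> mean 0.5 (hand enumeration)
        neuropil = box_neuropil()
        clone = point_clone(neuropil.mask.shape, [(1, y, 1) for y in (2, 4, 6, 8)])
        res = voxel_ti(clone, neuropil, extract_boundaries(neuropil))
        assert sorted(res.ti_per_voxel.tolist()) == pytest.approx([0.2, 0.4, 0.6, 0.8])
        assert res.ti_mean == pytest.approx(0.5)

    def test_spacing_cancels(self):
        neuropil = box_neuropil()
        clone = point_clone(neuropil.mask.shape, [(1, 3, 1), (2, 7, 2)])
        r1 = voxel_ti(clone, neuropil, extract_boundaries(neuropil, dv_spacing=1.0))
        r2 = voxel_ti(clone, neuropil, extract_boundaries(neuropil, dv_spacing=0.3))
        assert r1.ti_mean == pytest.approx(r2.ti_mean, rel=1e-12)

    def test_outside_voxels_excluded(self):
        neuropil = box_neuropil(y0=2, y1=8)
        clone = point_clone(neuropil.mask.shape, [(1, 0, 1), (1, 5, 1)])
        res = voxel_ti(clone, neuropil, extract_boundaries(neuropil))
        assert res.n_voxels_inside == 1
        assert res.n_voxels_excluded == 1

    def test_empty_intersection_rejected(self):
        neuropil = box_neuropil(y0=5, y1=9)
        clone = point_clone(neuropil.mask.shape, [(1, 0, 1)])
        with pytest.raises(EmptyMaskError):
            voxel_ti(clone, neuropil, extract_boundaries(neuropil))

    def test_degenerate_boundaries_rejected(self):
        shape = (3, 11, 3)
        neuropil = point_clone(shape, [(1, 4, 1)])  # single-voxel "neuropil"
        clone = point_clone(shape, [(1, 4, 1)])
        b = extract_boundaries(LabelMask(neuropil.mask, "reference", "fixed", 0))
        assert b.is_degenerate
        with pytest.raises(DegenerateBoundaryError):
            voxel_ti(clone, LabelMask(neuropil.mask, "reference", "fixed", 0), b)

    def test_oracle_equivalence_random_masks(self, rng):
        for _ in range(60):
            shape = tuple(int(x) for x in rng.integers(2, 7, 2)) + (int(rng.integers(1, 4)),)
            shape = (shape[2], shape[0], shape[1])  # (z, y, x), y up to 6
            clone, neuropil = random_mask_pair(rng, shape)
            b = extract_boundaries(neuropil, dv_spacing=1.0)
            if b.is_degenerate:
                continue
            res = voxel_ti(clone, neuropil, b)
            oracle, excluded = brute_force_ti(clone.mask, neuropil.mask)
            assert sorted(res.ti_per_voxel.tolist()) == sorted(oracle)
            assert res.n_voxels_excluded == excluded
            assert np.all((res.ti_per_voxel >= 0) & (res.ti_per_voxel <= 1))

    def test_per_column_mode(self):
        # staircase neuropil: column x=1 spans y 0..10, column x=2 spans y 2..6
        shape = (1, 11, 4)
        m = np.zeros(shape, dtype=bool)
        m[0, 0:11, 1] = True
        m[0, 2:7, 2] = True
        neuropil = LabelMask(m, "reference", "fixed", 0)
        clone = point_clone(shape, [(0, 4, 1), (0, 4, 2)])
        b = extract_boundaries(neuropil, mode="per-column")
        res = voxel_ti(clone, neuropil, b)
        assert sorted(res.ti_per_voxel.tolist()) == pytest.approx([0.4, 0.5])

    def test_per_column_extents_nested_in_global(self, rng):
        for _ in range(20):
            _, neuropil = random_mask_pair(rng, (3, 6, 4))
            g = extract_boundaries(neuropil, mode="global")
            pc = extract_boundaries(neuropil, mode="per-column")
            d = np.asarray(pc.dorsal_extent)
            v = np.asarray(pc.ventral_extent)
            ok = ~np.isnan(d)
            assert np.all(d[ok] >= g.dorsal_extent)
            assert np.all(v[ok] <= g.ventral_extent)


class TestProperties:
    def test_reflection(self, rng):
        for _ in range(30):
            clone, neuropil = random_mask_pair(rng, (3, 8, 4))
            b = extract_boundaries(neuropil)
            if b.is_degenerate:
                continue
            res = voxel_ti(clone, neuropil, b)
            fc = LabelMask(clone.mask[:, ::-1, :], "clone", "fixed", 0)
            fn = LabelMask(neuropil.mask[:, ::-1, :], "reference", "fixed", 0)
            res_f = voxel_ti(fc, fn, extract_boundaries(fn))
            assert res_f.ti_mean == pytest.approx(1.0 - res.ti_mean, abs=1e-12)

    def test_translation_invariance(self, rng):
        for _ in range(30):
            clone, neuropil = random_mask_pair(rng, (3, 6, 4))
            b = extract_boundaries(neuropil)
            if b.is_degenerate:
                continue
            res = voxel_ti(clone, neuropil, b)
            pad = ((1, 2), (2, 1), (0, 3))
            tc = LabelMask(np.pad(clone.mask, pad), "clone", "fixed", 0)
            tn = LabelMask(np.pad(neuropil.mask, pad), "reference", "fixed", 0)
            res_t = voxel_ti(tc, tn, extract_boundaries(tn))
            assert res_t.ti_mean == pytest.approx(res.ti_mean, abs=1e-12)

    def test_ventral_shift_monotonicity(self, rng):
        n_checked = 0
        while n_checked < 30:
            neuropil = box_neuropil((3, 12, 4), y0=0, y1=11)
            blob = np.zeros((3, 12, 4), dtype=bool)
            y0 = int(rng.integers(0, 8))
            blob[1, y0 : y0 + 3, 1:3] = rng.random((3, 2)) < 0.7
            if not blob.any():
                continue
            clone = LabelMask(blob, "clone", "fixed", 0)
            shifted = LabelMask(np.roll(blob, 1, axis=1), "clone", "fixed", 0)
            b = extract_boundaries(neuropil)
            ti0 = voxel_ti(clone, neuropil, b).ti_mean
            ti1 = voxel_ti(shifted, neuropil, b).ti_mean
            assert ti1 >= ti0 - 1e-12
            n_checked += 1


class TestCloneTIFromStack:
    def test_recovers_clean_q(self):
        spec = SyntheticSpec(
            clone_position_q=0.25,
            blur_sigma_um=0.0,
            noise=NoiseModel(0.0, 0.0),
            background_level=0.0,
            seed=3,
        )
        stack, truth = generate_stack(spec)
        res = clone_ti_from_stack(stack)
        one_voxel = 1.0 / (spec.dv_extent[1] - spec.dv_extent[0])
        assert abs(res.ti_mean - truth.true_q) < one_voxel

    def test_reflection_through_orientation(self, clean_spec):
        stack, _ = generate_stack(clean_spec)
        res = clone_ti_from_stack(stack)
        res_f = clone_ti_from_stack(orient_stack(stack, flip_dv=True))
        assert res_f.ti_mean == pytest.approx(1.0 - res.ti_mean, abs=1e-9)

    def test_provenance_recorded(self, clean_spec):
        stack, _ = generate_stack(clean_spec)
        res = clone_ti_from_stack(stack, SPARSE_CLONE_CONFIG)
        assert res.provenance["boundary_mode"] == "global"
        assert res.provenance["threshold_method_clone"] == "fraction-of-max"
        assert res.provenance["threshold_clone"] > 0

    def test_clone_outside_neuropil_fails_with_stage(self):
        # clone blob far from the reference solid
        ref = np.zeros((3, 20, 5))
        ref[:, 12:18, 1:4] = 100.0
        clone = np.zeros_like(ref)
        clone[1, 2:4, 2] = 100.0
        stack_arr = np.stack([clone, ref])
        from topoindex import ImageStack

        stack = ImageStack(stack_arr, channel_names=("clone", "reference"))
        with pytest.raises(PipelineStageError) as err:
            clone_ti_from_stack(stack)
        assert err.value.stage == "topography"


class TestBatchTI:
    def _write_stacks(self, tmp_path, qs):
        rows = []
        for i, q in enumerate(qs):
            spec = SyntheticSpec(clone_position_q=q, seed=i, noise=NoiseModel(0, 0))
            path = tmp_path / f"s{i}.tif"
            write_synthetic_stack(spec, path)
            rows.append({"path": str(path), "clone_id": f"c{i}", "group": "g"})
        return pd.DataFrame(rows)

    def test_three_stack_manifest(self, tmp_path):
        manifest = self._write_stacks(tmp_path, [0.2, 0.5, 0.8])
        table, failures = batch_ti(manifest)
        assert len(table) == 3
        assert failures == []
        assert list(table["clone_id"]) == ["c0", "c1", "c2"]

    def test_unreadable_path_recorded(self, tmp_path):
        manifest = self._write_stacks(tmp_path, [0.3, 0.7])
        bad = pd.concat(
            [manifest, pd.DataFrame([{"path": str(tmp_path / "missing.tif"), "clone_id": "x", "group": "g"}])],
            ignore_index=True,
        )
        table, failures = batch_ti(bad)
        assert len(table) == 2
        assert len(failures) == 1
        assert "missing.tif" in failures[0]["path"]

    def test_group_ordering_d_m_v(self, tmp_path):
        rows = []
        for group, q in (("D", 0.2), ("M", 0.55), ("V", 0.8)):
            for i in range(2):
                spec = SyntheticSpec(clone_position_q=q, seed=hash((group, i)) % 1000, noise=NoiseModel(0, 0))
                path = tmp_path / f"{group}{i}.tif"
                write_synthetic_stack(spec, path)
                rows.append({"path": str(path), "clone_id": f"{group}{i}", "group": group})
        table, _ = batch_ti(pd.DataFrame(rows))
        means = table.groupby("group")["ti_mean"].mean()
        assert means["D"] < means["M"] < means["V"]
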