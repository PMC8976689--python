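"""Lucas-Kanade flow: oracles (identity, integer shift, block matching,
analytic phantom truth), tracked-voxel selection, cumulative composition."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from cine4d import flow as fl
from cine4d import phantom as ph
from cine4d.core import GridMismatchError, VolumeFrame

from conftest import roi_box_for


def block_matching_oracle(fixed, moving, voxel_indices, window_radius=3, search=3):
    """Exhaustive integer-displacement SSD search — independent flow oracle."""
    out = np.zeros((len(voxel_indices), 3))
    r = window_radius
    for n, (i, j, k) in enumerate(voxel_indices):
        ref = fixed[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1]
        best, best_d = np.inf, (0, 0, 0)
        for di in range(-search, search + 1):
            for dj in range(-search, search + 1):
                for dk in range(-search, search + 1):
                    cand = moving[i + di - r:i + di + r + 1,
                                  j + dj - r:j + dj + r + 1,
                                  k + dk - r:k + dk + r + 1]
                    if cand.shape != ref.shape:
                        continue
                    ssd = float(np.sum((cand - ref) ** 2))
                    if ssd < best:
                        best, best_d = ssd, (di, dj, dk)
        out[n] = best_d
    return out


class TestTrackedVoxelSelection:
    def test_constant_roi_has_no_eligible_voxels(self, quiet_config):
        flat = VolumeFrame(np.zeros((32, 32, 32), np.float32), (2.0, 2.0, 2.0))
        with pytest.raises(fl.FlowError, match="gradient floor|constant"):
            fl.select_tracked_voxels(flat, [[10, 50], [10, 50], [10, 50]], 16)

    def test_overlarge_n_target_returns_all_eligible_without_duplicates(self, cycle_ct,
                                                                        quiet_config):
        frames, _ = cycle_ct
        tracked = fl.select_tracked_voxels(frames[0], roi_box_for(quiet_config), 10 ** 6)
        assert tracked.n < 10 ** 6
        assert len(np.unique(tracked.voxel_indices, axis=0)) == tracked.n

    def test_selection_matches_bruteforce_gradient_ranking(self, cycle_ct, quiet_config):
        frames, _ = cycle_ct
        roi = roi_box_for(quiet_config)
        tracked = fl.select_tracked_voxels(frames[0], roi, 32)
        sm = ndimage.gaussian_filter(frames[0].data.astype(float), 1.0)
        grad = np.sqrt(sum(g ** 2 for g in np.gradient(sm)))
        chosen = grad[tuple(tracked.voxel_indices.T)]
        # every chosen voxel has gradient >= the weakest chosen one among ROI peers
        lo = np.ceil(roi[:, 0] / 2).astype(int)
        hi = np.floor(roi[:, 1] / 2).astype(int)
        roi_grad = grad[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        n_higher = int(np.sum(roi_grad > chosen.min()))
        assert n_higher <= 32  # nothing stronger was skipped

    def test_selected_voxels_lie_near_structure_boundaries(self, cycle_ct, quiet_config):
        frames, _ = cycle_ct
        tracked = fl.select_tracked_voxels(frames[0], roi_box_for(quiet_config), 64)
        pts = tracked.positions_mm(frames[0])
        r = np.linalg.norm(pts - np.asarray(quiet_config.tumor_center_mm), axis=1)
        # high-gradient voxels concentrate on the tumor shell / nearby vessels
        assert np.median(np.abs(r - quiet_config.tumor_radius_mm)) < 6.0


class TestLucasKanade:
    def test_identity_gives_zero_flow(self, cycle_ct, tracked64):
        frames, _ = cycle_ct
        ff = fl.lucas_kanade_3d(frames[0], frames[0], tracked64)
        np.testing.assert_allclose(ff.vectors_mm, 0.0, atol=1e-9)

    def test_integer_voxel_shift_recovered(self, quiet_config, cycle_ct, tracked64):
        frames, _ = cycle_ct
        moving = frames[0].with_data(np.roll(frames[0].data, 1, axis=2))
        ff = fl.lucas_kanade_3d(frames[0], moving, tracked64)
        err_vox = ff.vectors_mm / np.asarray(quiet_config.spacing_mm) - [0, 0, 1]
        assert np.abs(err_vox).max() < 0.1

    def test_adjacent_phantom_phases_match_truth(self, cycle_ct, tracked64):
        frames, truth = cycle_ct
        ref_pts = tracked64.positions_mm(frames[0])
        ff = fl.lucas_kanade_3d(frames[6], frames[7], tracked64)
        expect = (truth.displacement(frames[7].time_s, ref_pts)
                  - truth.displacement(frames[6].time_s, ref_pts))
        err = np.linalg.norm(ff.vectors_mm - expect, axis=1)
        assert np.median(err) < 0.5

    def test_agrees_with_block_matching_oracle(self, cycle_ct, quiet_config, tracked64):
        frames, _ = cycle_ct
        fixed, moving = frames[5], frames[7]    # ~2 voxels of motion
        ff = fl.lucas_kanade_3d(fixed, moving, tracked64)
        sub = tracked64.voxel_indices[::8]
        bm = block_matching_oracle(fixed.data.astype(float),
                                   moving.data.astype(float), sub)
        lk_vox = ff.vectors_mm[::8] / np.asarray(quiet_config.spacing_mm)
        assert np.abs(lk_vox - bm).max() <= 1.0

    def test_forward_backward_antisymmetry(self, cycle_ct, quiet_config, tracked64):
        frames, _ = cycle_ct
        params = fl.FlowParams(symmetric=False)
        fwd = fl.lucas_kanade_3d(frames[6], frames[8], tracked64, params)
        bwd = fl.lucas_kanade_3d(frames[8], frames[6], tracked64, params)
        resid_vox = (fwd.vectors_mm + bwd.vectors_mm) / np.asarray(quiet_config.spacing_mm)
        assert np.median(np.abs(resid_vox)) < 0.2

    def test_grid_mismatch_raises(self, cycle_ct, tracked64):
        frames, _ = cycle_ct
        other = VolumeFrame(frames[0].data, (1.0, 2.0, 2.0))
        with pytest.raises(GridMismatchError):
            fl.lucas_kanade_3d(frames[0], other, tracked64)


class TestFlowTimeSeries:
    def test_static_sequence_gives_zero_series(self, small_config):
        cfg = dataclasses.replace(small_config, amplitude_mm=0.0)
        frames, _ = ph.generate_4d(cfg, 4, 0.25, modality="ct")
        tracked = fl.select_tracked_voxels(frames[0], roi_box_for(cfg, 12.0), 16)
        series = fl.flow_time_series(frames, tracked)
        for s in series:
            np.testing.assert_allclose(s.vectors_mm, 0.0, atol=1e-9)

    def test_full_cycle_returns_to_zero_and_tracks_truth(self, cycle_ct, tracked64):
        frames, truth = cycle_ct
        ref_pts = tracked64.positions_mm(frames[0])
        series = fl.flow_time_series(frames, tracked64)
        # cumulative displacement vs analytic truth, per axis
        errs = np.array([
            np.sqrt(np.mean((s.vectors_mm - truth.displacement(s.time_s, ref_pts)) ** 2,
                            axis=0))
            for s in series])
        assert errs.max() < 1.0
        # drift at cycle end
        drift = np.linalg.norm(series[20].vectors_mm, axis=1)
        assert drift.max() < 1.0

    def test_reference_frame_entry_is_zero(self, cycle_ct, tracked64):
        frames, _ = cycle_ct
        series = fl.flow_time_series(frames[:6], tracked64, reference_index=2)
        np.testing.assert_array_equal(series[2].vectors_mm, 0.0)
        assert series[0].reference_time_s == frames[2].time_s

    def test_too_few_frames_raises(self, cycle_ct, tracked64):
        frames, _ = cycle_ct
        with pytest.raises(ValueError, match="two frames"):
            fl.flow_time_series(frames[:1], tracked64)
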