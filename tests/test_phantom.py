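"""Phantom generator: geometry, breathing kinematics, rendering, resampling."""

import numpy as np
import pytest
from scipy import ndimage

from cine4d import phantom as ph
from cine4d.core import VolumeFrame

from conftest import roi_box_for


def tumor_centroid_mm(frame: VolumeFrame, threshold: float = 650.0) -> np.ndarray:
    # band-pass below the static markers (~900) and keep only the largest
    # connected component: the marker sigmoid skirts also cross the band and
    # would otherwise drag the centroid toward the (static) markers
    mask = (frame.data > threshold) & (frame.data < 850.0)
    labels, _ = ndimage.label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    com = ndimage.center_of_mass(labels == sizes.argmax())
    return np.asarray(frame.origin_mm) + np.asarray(com) * np.asarray(frame.spacing_mm)


class TestBreathingKinematics:
    def test_zero_amplitude_sequence_is_static(self):
        cfg = ph.PhantomConfig(amplitude_mm=0.0, ct_noise_sd=0.0, mr_noise_sd=0.0)
        frames, truth = ph.generate_4d(cfg, 5, 0.25, modality="ct")
        for f in frames[1:]:
            np.testing.assert_array_equal(f.data, frames[0].data)
        pts = np.array([[60.0, 60.0, 70.0], [40.0, 80.0, 50.0]])
        np.testing.assert_allclose(truth.displacement(0.8, pts), 0.0)

    def test_periodicity_20_frames_at_quarter_second(self, cycle_ct):
        frames, _ = cycle_ct   # period 5.0 s at 0.25 s -> 20 frames per cycle
        np.testing.assert_array_equal(frames[20].data, frames[0].data)

    def test_truth_displacement_zero_at_reference_phase(self, quiet_config):
        truth = ph.PhantomTruth(config=quiet_config)
        pts = np.array([[63.0, 63.0, 72.0], [50.0, 70.0, 40.0]])
        np.testing.assert_allclose(truth.displacement(0.0, pts), 0.0)
        np.testing.assert_allclose(truth.displacement(quiet_config.period_s, pts),
                                   0.0, atol=1e-12)

    def test_peak_to_peak_si_excursion_matches_config(self, quiet_config, cycle_ct):
        frames, truth = cycle_ct
        # analytic trajectory: exactly 16 mm
        t = np.linspace(0, quiet_config.period_s, 201)
        z = truth.tumor_center(t)[:, 2]
        assert z.max() - z.min() == pytest.approx(16.0, abs=1e-9)
        # rendered frames: extreme phases differ by 16 mm within one voxel
        c_ref = tumor_centroid_mm(frames[0])
        c_peak = tumor_centroid_mm(frames[10])   # t = 2.5 s = half period
        si = abs(c_ref[2] - c_peak[2])
        assert abs(si - 16.0) <= quiet_config.spacing_mm[2]

    def test_waveform_dwells_longer_at_exhale(self, quiet_config):
        t = np.linspace(0, quiet_config.period_s, 400, endpoint=False)
        s = ph.waveform(quiet_config, t)
        assert np.mean(s < 0.5) > np.mean(s > 0.5)

    def test_tumor_leaving_grid_raises(self):
        with pytest.raises(ph.PhantomConfigError, match="leaves the grid"):
            ph.PhantomConfig(tumor_center_mm=(63.0, 63.0, 20.0), amplitude_mm=30.0)

    def test_amplitude_and_period_read_back_from_trajectory(self, quiet_config):
        truth = ph.PhantomTruth(config=quiet_config)
        dt = 0.25
        t = np.arange(0, 3 * quiet_config.period_s, dt)
        z = truth.tumor_center(t)[:, 2]
        assert np.ptp(z) == pytest.approx(quiet_config.amplitude_mm, abs=0.2)
        minima = np.flatnonzero((z < np.roll(z, 1)) & (z < np.roll(z, -1)))
        period_est = np.mean(np.diff(t[minima]))
        assert period_est == pytest.approx(quiet_config.period_s, abs=dt)


class TestRendering:
    def test_generation_is_bit_reproducible(self, noisy_config):
        a, _ = ph.generate_4d(noisy_config, 3, 0.25, modality="mr")
        b, _ = ph.generate_4d(noisy_config, 3, 0.25, modality="mr")
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.data, fb.data)

    def test_mr_rendering_is_exact_monotone_map_of_ct(self, quiet_config):
        clean = ph.generate_4d(quiet_config, 2, 0.25, modality="clean")[0][0]
        ct = ph.render_modality(clean, "ct", quiet_config)
        mr = ph.render_modality(clean, "mr", quiet_config)
        ct_to_mr, mr_to_ct = ph.intensity_maps(quiet_config)
        np.testing.assert_allclose(mr.data, ct_to_mr(ct.data), atol=1e-3)
        np.testing.assert_allclose(mr_to_ct(mr.data), ct.data, atol=1e-3)

    def test_render_requires_clean_frame_and_known_modality(self, quiet_config):
        clean = ph.generate_4d(quiet_config, 2, 0.25, modality="clean")[0][0]
        ct = ph.render_modality(clean, "ct", quiet_config)
        with pytest.raises(ValueError, match="clean"):
            ph.render_modality(ct, "mr", quiet_config)
        with pytest.raises(ValueError, match="modality"):
            ph.render_modality(clean, "pet", quiet_config)

    def test_truth_field_warps_reference_onto_phase_frame(self, noisy_config):
        frames, truth = ph.generate_4d(noisy_config, 11, 0.25, modality="ct")
        f = frames[8]
        d = truth.dense_backward_displacement(f.time_s, f)
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in f.shape], indexing="ij")
        coords = [g - d[..., a] / noisy_config.spacing_mm[a]
                  for a, g in enumerate(grids)]
        recon = ndimage.map_coordinates(frames[0].data.astype(float), coords,
                                        order=1, mode="nearest")
        mae = np.abs(recon - f.data).mean()
        # the difference of two independent noise realizations alone has
        # E|diff| ~= 1.1 sigma; allow a small interpolation-edge margin on top
        assert mae < 1.5 * noisy_config.ct_noise_sd


class TestCineExtraction:
    def test_static_volume_gives_identical_cine_frames(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, amplitude_mm=0.0)
        frames, _ = ph.generate_4d(cfg, 4, 0.25, modality="ct")
        cine = ph.extract_cine(frames, cfg.tumor_center_mm[0])
        for c in cine[1:]:
            np.testing.assert_array_equal(c.data, cine[0].data)

    def test_timestamps_and_indices_preserved(self, cycle_ct, quiet_config):
        frames, _ = cycle_ct
        cine = ph.extract_cine(frames, quiet_config.tumor_center_mm[0])
        for i, c in enumerate(cine):
            assert c.frame_index == i
            assert c.time_s == pytest.approx(0.25 * i)

    def test_cine_tumor_span_matches_amplitude(self, cycle_ct, quiet_config):
        frames, _ = cycle_ct
        cine = ph.extract_cine(frames, quiet_config.tumor_center_mm[0])
        centroids = []
        for c in cine:
            mask = c.data > 650.0
            com = ndimage.center_of_mass(mask.astype(float))
            centroids.append(c.origin_mm[1] + com[1] * c.spacing_mm[1])
        span = np.ptp(centroids)
        assert abs(span - 16.0) <= quiet_config.spacing_mm[2]

    def test_slab_outside_grid_raises(self, cycle_ct):
        frames, _ = cycle_ct
        with pytest.raises(ValueError, match="outside grid"):
            ph.extract_cine(frames, 500.0)


class TestPeriodResampling:
    def test_identity_resample_preserves_frames(self, quiet_config):
        frames, _ = ph.generate_4d(quiet_config, 10, 0.5, modality="ct")
        out = ph.resample_period(frames, quiet_config.period_s, quiet_config.period_s)
        assert len(out) == len(frames)
        for a, b in zip(out, frames):
            np.testing.assert_allclose(a.data, b.data, atol=1e-4)

    def test_period_stretch_preserves_amplitude(self, quiet_config):
        import dataclasses
        cfg = dataclasses.replace(quiet_config, period_s=4.0)
        frames, _ = ph.generate_4d(cfg, 16, 0.25, modality="ct")  # one 4 s cycle
        out = ph.resample_period(frames, 4.0, 6.0, frame_interval_s=0.25)
        times = [f.time_s for f in out]
        assert times[-1] + 0.25 == pytest.approx(6.0)
        z = [tumor_centroid_mm(f)[2] for f in out]
        assert np.ptp(z) == pytest.approx(cfg.amplitude_mm, rel=0.05)

    def test_static_sequence_stays_static(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, amplitude_mm=0.0)
        frames, _ = ph.generate_4d(cfg, 17, 0.25, modality="ct")
        out = ph.resample_period(frames, cfg.period_s, 5.5)
        for f in out:
            np.testing.assert_allclose(f.data, frames[0].data, atol=1e-4)

    def test_input_shorter_than_one_period_raises(self, quiet_config):
        frames, _ = ph.generate_4d(quiet_config, 4, 0.25, modality="ct")
        with pytest.raises(ValueError, match="shorter"):
            ph.resample_period(frames, quiet_config.period_s, 4.0)
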