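"""Motion regression: training-set assembly, horizon arithmetic, prediction
contracts and error evaluation.  (Full parameter recovery at 16 mm amplitude
runs in the acceptance suite.)"""

import dataclasses

import numpy as np
import pytest

from cine4d import flow as fl
from cine4d import motion as mo
from cine4d import phantom as ph
from cine4d.core import CineFrame
from cine4d.flow import FlowField

from conftest import roi_box_for


@pytest.fixture(scope="module")
def small_planning(small_config):
    frames, truth = ph.generate_4d(
        small_config, int(round(2 * small_config.period_s / 0.5)) + 1, 0.5,
        modality="ct")
    tracked = fl.select_tracked_voxels(frames[0], roi_box_for(small_config, 12.0), 16)
    return frames, truth, tracked


class TestTrainingSetConstruction:
    def test_sample_count_by_enumeration(self, small_planning, small_config):
        frames, _, tracked = small_planning
        # one 4.0 s cycle at 0.5 s (8 frames) -> 16 cine-cadence frames,
        # so with W = 8 and k = 6: 16 - 8 - 6 + 1 = 3 windows
        one_cycle = frames[:8]
        ts = mo.build_training_set(
            one_cycle, small_config.tumor_center_mm[0], tracked, None,
            k=6, w=8, periods_s=(4.0,), native_period_s=small_config.period_s)
        assert ts.n_samples == 3

    def test_degenerate_horizon_and_window(self, small_planning, small_config):
        frames, _, tracked = small_planning
        one_cycle = frames[:8]
        ts = mo.build_training_set(
            one_cycle, small_config.tumor_center_mm[0], tracked, None,
            k=0, w=1, periods_s=(small_config.period_s,),
            native_period_s=small_config.period_s)
        n_frames = int(round(small_config.period_s / 0.25))
        assert ts.n_samples == n_frames   # every frame usable, target concurrent

    def test_period_manifest_and_summed_counts(self, small_planning, small_config):
        frames, _, tracked = small_planning
        ts = mo.build_training_set(
            frames, small_config.tumor_center_mm[0], tracked, None,
            k=6, w=8, periods_s=(4.0, 5.0, 6.0), native_period_s=small_config.period_s)
        assert ts.manifest["periods_s"] == [4.0, 5.0, 6.0]
        assert sum(ts.manifest["samples_per_period"]) == ts.n_samples

    def test_series_too_short_raises(self, small_planning, small_config):
        frames, _, tracked = small_planning
        with pytest.raises(mo.MotionError, match="too short"):
            mo.build_training_set(
                frames[:9], small_config.tumor_center_mm[0], tracked, None,
                k=30, w=8, periods_s=(4.0,), native_period_s=small_config.period_s)


class TestTraining:
    def test_zero_motion_targets_learned_to_zero(self, small_config):
        cfg = dataclasses.replace(small_config, amplitude_mm=0.0)
        frames, _ = ph.generate_4d(cfg, int(round(2 * cfg.period_s / 0.5)) + 1, 0.5,
                                   modality="ct")
        tracked = fl.select_tracked_voxels(frames[0], roi_box_for(cfg, 12.0), 8)
        ts = mo.build_training_set(frames, cfg.tumor_center_mm[0], tracked, None,
                                   k=6, w=4, periods_s=(cfg.period_s,),
                                   native_period_s=cfg.period_s)
        model = mo.train_motion_model(ts, mo.MotionTrainConfig(
            hidden=16, epochs=60, patience=30, ensemble=1, seed=0))
        preds = model.predict_raw(ts.inputs)
        assert float(np.mean(preds ** 2)) < 1e-3       # mm^2
        assert model.manifest["best_val_mse"] < 1e-3

    def test_same_seed_reproduces_identical_weights(self, small_planning,
                                                    small_config):
        frames, _, tracked = small_planning
        ts = mo.build_training_set(frames, small_config.tumor_center_mm[0], tracked,
                                   None, k=2, w=4, periods_s=(small_config.period_s,),
                                   native_period_s=small_config.period_s)
        cfg = mo.MotionTrainConfig(hidden=16, epochs=20, ensemble=2, seed=5)
        m1 = mo.train_motion_model(ts, cfg)
        m2 = mo.train_motion_model(ts, cfg)
        assert len(m1.nets) == 2
        for n1, n2 in zip(m1.nets, m2.nets):
            for a, b in zip(n1.params, n2.params):
                np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self, small_planning, small_config):
        frames, _, tracked = small_planning
        ts = mo.build_training_set(frames, small_config.tumor_center_mm[0], tracked,
                                   None, k=2, w=4, periods_s=(small_config.period_s,),
                                   native_period_s=small_config.period_s)
        empty = dataclasses.replace(ts, inputs=ts.inputs[:0], targets_mm=ts.targets_mm[:0])
        with pytest.raises(mo.MotionError, match="empty"):
            mo.train_motion_model(empty)


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self, small_planning, small_config):
        frames, truth, tracked = small_planning
        ts = mo.build_training_set(frames, small_config.tumor_center_mm[0], tracked,
                                   None, k=6, w=4,
                                   periods_s=(small_config.period_s,),
                                   native_period_s=small_config.period_s)
        model = mo.train_motion_model(ts, mo.MotionTrainConfig(
            hidden=32, epochs=150, patience=60, ensemble=1, seed=1))
        return model, frames, truth, tracked

    def _cine_window(self, model, small_config, start=0):
        cfg = small_config
        frames, _ = ph.generate_4d(cfg, model.window_w + start + 1, 0.25, modality="ct")
        return ph.extract_cine(frames, cfg.tumor_center_mm[0])[start:start + model.window_w]

    def test_horizon_timestamp_arithmetic_exact(self, trained, small_config):
        model, *_ = trained
        window = self._cine_window(model, small_config)
        out = mo.predict_flow(model, window)
        assert out.time_s == window[-1].time_s + 6 * 0.25

    def test_wrong_window_length_rejected(self, trained, small_config):
        model, *_ = trained
        window = self._cine_window(model, small_config)
        with pytest.raises(mo.MotionError, match="exactly W"):
            mo.predict_flow(model, window[:-1])

    def test_cadence_gap_rejected(self, trained, small_config):
        model, *_ = trained
        window = self._cine_window(model, small_config)
        window[-1] = dataclasses.replace(window[-1], time_s=window[-1].time_s + 0.2)
        with pytest.raises(mo.MotionError, match="cadence"):
            mo.predict_flow(model, window)

    def test_mr_frames_rejected(self, trained, small_config):
        model, *_ = trained
        window = [dataclasses.replace(c, modality="mr")
                  for c in self._cine_window(model, small_config)]
        with pytest.raises(mo.MotionError, match="CT-appearance"):
            mo.predict_flow(model, window)

    def test_model_round_trip_preserves_inference(self, tmp_path, trained,
                                                  small_config):
        model, *_ = trained
        window = self._cine_window(model, small_config)
        model.save(tmp_path / "m")
        reloaded = mo.MotionModel.load(tmp_path / "m")
        np.testing.assert_array_equal(mo.predict_flow(model, window).vectors_mm,
                                      mo.predict_flow(reloaded, window).vectors_mm)


class TestEvaluation:
    def _series(self, values):
        return [FlowField(np.tile(v, (4, 1)), time_s=0.25 * i, reference_time_s=0.0)
                for i, v in enumerate(values)]

    def test_identical_series_give_zero_errors(self):
        truth = self._series([[0, 0, -z] for z in (0.0, 2.0, 5.0, 2.0, 0.0)])
        rep = mo.evaluate_prediction(truth, truth)
        np.testing.assert_array_equal(rep.per_axis_rmse_mm, 0.0)
        assert rep.max_3d_mm == 0.0

    def test_constant_z_offset_isolated_to_z_axis(self):
        truth = self._series([[0, 0, -z] for z in (0.0, 2.0, 5.0, 8.0, 2.0)])
        pred = self._series([[0, 0, -z + 1.0] for z in (0.0, 2.0, 5.0, 8.0, 2.0)])
        rep = mo.evaluate_prediction(pred, truth)
        np.testing.assert_allclose(rep.per_axis_rmse_mm, [0.0, 0.0, 1.0])
        np.testing.assert_allclose(rep.max_abs_mm, [0.0, 0.0, 1.0])
        assert rep.max_3d_mm == pytest.approx(1.0)

    def test_phase_stratification_finds_both_extremes(self):
        z = -8.0 * np.sin(np.linspace(0, np.pi, 9)) ** 2
        truth = self._series([[0, 0, zi] for zi in z])
        rep = mo.evaluate_prediction(truth, truth)
        assert "inspiration_peak" in rep.phase_labels[4]
        assert rep.phase_labels[0] == "expiration_peak"
        assert "transition" in rep.phase_labels

    def test_timestamp_mismatch_raises(self):
        truth = self._series([[0, 0, 0.0], [0, 0, 1.0]])
        pred = self._series([[0, 0, 0.0], [0, 0, 1.0]])
        pred[1] = FlowField(pred[1].vectors_mm, time_s=9.0, reference_time_s=0.0)
        with pytest.raises(mo.MotionError, match="timestamp"):
            mo.evaluate_prediction(pred, truth)
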