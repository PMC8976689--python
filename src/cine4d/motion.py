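"""Future prediction of 3D tumor-region displacement from 2D cine pixel values.

Pretreatment: the planning 4D series is augmented over a range of
respiratory periods (time-resampled to the cine cadence), the cumulative 3D
optical flow of the tracked voxel set provides the regression targets, and
the pixel values of the sagittal cine plane provide the inputs.  A recurrent
(LSTM) network maps a window of W consecutive frames' features to the
displacement k frames after the window end — k = 6 frames at 0.25 s covers
the 1.5 s the device needs between seeing the anatomy and irradiating it.

Input features are ROI-cropped, downsampled, percentile-normalized pixel
values per frame; targets are normalized per world axis by their
training-set standard deviation and denormalized to mm at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import flow as _flow
from . import phantom as _phantom
from ._lstm import LSTMRegressor
from .core import CineFrame, cadence_of
from .flow import FlowField, FlowParams, TrackedVoxelSet


class MotionError(ValueError):
    pass


@dataclass
class FeatureConfig:
    """How a cine frame becomes a feature vector (fixed at training time)."""

    crop_y_mm: tuple[float, float]
    crop_z_mm: tuple[float, float]
    shape: tuple[int, int] = (16, 16)

    def extract(self, frame: CineFrame) -> np.ndarray:
        y = frame.origin_mm[0] + np.arange(frame.shape[0]) * frame.spacing_mm[0]
        z = frame.origin_mm[1] + np.arange(frame.shape[1]) * frame.spacing_mm[1]
        ys = np.searchsorted(y, self.crop_y_mm[0]), np.searchsorted(y, self.crop_y_mm[1], "right")
        zs = np.searchsorted(z, self.crop_z_mm[0]), np.searchsorted(z, self.crop_z_mm[1], "right")
        crop = frame.data[ys[0]:ys[1], zs[0]:zs[1]].astype(np.float64)
        if crop.size == 0:
            raise MotionError("feature crop box lies outside the cine frame")
        zoom = [t / s for t, s in zip(self.shape, crop.shape)]
        return ndimage.zoom(crop, zoom, order=1).ravel()

    def to_dict(self) -> dict:
        return {"crop_y_mm": list(self.crop_y_mm), "crop_z_mm": list(self.crop_z_mm),
                "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(crop_y_mm=tuple(d["crop_y_mm"]), crop_z_mm=tuple(d["crop_z_mm"]),
                   shape=tuple(d["shape"]))


@dataclass
class MotionTrainingSet:
    """Windows of cine features paired with future cumulative flow targets."""

    inputs: np.ndarray          # (S, W, F)
    targets_mm: np.ndarray      # (S, 3N)
    horizon_k: int
    window_w: int
    n_tracked: int
    frame_interval_s: float
    feature_config: FeatureConfig
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.horizon_k < 0 or self.window_w < 1:
            raise MotionError("need horizon k >= 0 and window W >= 1")
        if len(self.inputs) != len(self.targets_mm):
            raise MotionError("inputs/targets length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.inputs)


def _windows_from_series(features: np.ndarray, flows: list[FlowField],
                         w: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(features)
    n_samples = n - w - k + 1
    if n_samples < 1:
        raise MotionError(
            f"series of {n} frames too short for window W={w} and horizon k={k}")
    xs = np.stack([features[i:i + w] for i in range(n_samples)])
    ys = np.stack([flows[i + w - 1 + k].vectors_mm.ravel() for i in range(n_samples)])
    return xs, ys


def build_training_set(
    planning_frames,
    slab_x_mm: float,
    tracked: TrackedVoxelSet,
    flow_params: FlowParams | None,
    k: int = 6,
    w: int = 12,
    periods_s=(4.0, 4.5, 5.0, 5.5, 6.0),
    native_period_s: float = 5.0,
    cine_interval_s: float = 0.25,
    feature_shape: tuple[int, int] = (16, 16),
    crop_margin_mm: float = 6.0,
) -> MotionTrainingSet:
    """Build (cine-feature window, future 3D flow) pairs from a planning series.

    For each requested respiratory period the planning series is
    time-resampled to that period at the cine cadence; targets are the
    cumulative tracked-voxel flow ``k`` frames after each window's end and
    inputs the per-frame feature vectors of the sagittal slice at
    ``slab_x_mm``.  Windows never wrap across the end of a resampled series.
    """
    planning_frames = list(planning_frames)
    dt_in = cadence_of(planning_frames)
    duration = (len(planning_frames) - 1) * dt_in
    if duration + dt_in < native_period_s - 1e-9:
        raise MotionError("planning series must cover at least one full period")
    roi = tracked.roi_box_mm
    feat_cfg = FeatureConfig(
        crop_y_mm=(roi[1, 0] - crop_margin_mm, roi[1, 1] + crop_margin_mm),
        crop_z_mm=(roi[2, 0] - crop_margin_mm - 8.0, roi[2, 1] + crop_margin_mm + 8.0),
        shape=feature_shape)

    xs_all, ys_all = [], []
    for period in periods_s:
        frames_p = _phantom.resample_period(
            planning_frames, native_period_s, period, frame_interval_s=cine_interval_s)
        flows = _flow.flow_time_series(frames_p, tracked, flow_params)
        cine = _phantom.extract_cine(frames_p, slab_x_mm)
        feats = np.stack([feat_cfg.extract(c) for c in cine])
        xs, ys = _windows_from_series(feats, flows, w, k)
        xs_all.append(xs)
        ys_all.append(ys)
    return MotionTrainingSet(
        inputs=np.concatenate(xs_all), targets_mm=np.concatenate(ys_all),
        horizon_k=k, window_w=w, n_tracked=tracked.n,
        frame_interval_s=cine_interval_s, feature_config=feat_cfg,
        manifest={"periods_s": [float(p) for p in periods_s],
                  "native_period_s": float(native_period_s),
                  "samples_per_period": [int(len(x)) for x in xs_all]})


@dataclass
class MotionTrainConfig:
    hidden: int = 64
    layers: int = 2
    epochs: int = 800
    batch_size: int = 32
    lr: float = 3e-3
    val_fraction: float = 0.2
    patience: int = 150
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    peak_weight: float = 4.0     # extra loss weight on large-displacement samples
    ensemble: int = 3            # independently seeded members, predictions averaged
    seed: int = 0


@dataclass
class MotionModel:
    """Trained recurrent regressor from cine windows to future 3D flow.

    Holds a small ensemble of independently initialized LSTMs whose
    predictions are averaged — the members share data and differ only in
    seed, which damps initialization-dependent errors at the breathing
    extremes without touching determinism (member seeds derive from the
    configured seed).
    """

    nets: list[LSTMRegressor]
    window_w: int
    horizon_k: int
    n_tracked: int
    frame_interval_s: float
    feature_config: FeatureConfig
    input_lo: float
    input_hi: float
    target_mean: np.ndarray      # (3N,)
    target_sd: np.ndarray        # (3,) per world axis
    manifest: dict = field(default_factory=dict)

    def normalize_inputs(self, x: np.ndarray) -> np.ndarray:
        return np.clip((x - self.input_lo) / (self.input_hi - self.input_lo), 0.0, 1.0)

    def _sd_full(self) -> np.ndarray:
        """Per-axis SD broadcast to the (3N,) output layout (x, y, z per voxel)."""
        return np.tile(self.target_sd, self.n_tracked)

    def predict_raw(self, windows: np.ndarray) -> np.ndarray:
        x = self.normalize_inputs(windows)
        out = np.mean([net.predict(x) for net in self.nets], axis=0)
        return out * self._sd_full() + self.target_mean

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {"target_mean": self.target_mean, "target_sd": self.target_sd}
        for j, net in enumerate(self.nets):
            arrays.update({f"m{j}_{k}": v for k, v in net.state().items()})
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps({
            "kind": "motion_model", "window_w": self.window_w, "horizon_k": self.horizon_k,
            "n_tracked": self.n_tracked, "frame_interval_s": self.frame_interval_s,
            "n_members": len(self.nets),
            "feature_config": self.feature_config.to_dict(),
            "input_lo": self.input_lo, "input_hi": self.input_hi,
            **{k: v for k, v in self.manifest.items()},
        }, indent=2, sort_keys=True, default=str))

    @classmethod
    def load(cls, path) -> "MotionModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        nets = []
        for j in range(int(meta["n_members"])):
            member = {k[len(f"m{j}_"):]: v for k, v in arrays.items()
                      if k.startswith(f"m{j}_")}
            nets.append(LSTMRegressor.from_state(member))
        known = {"kind", "window_w", "horizon_k", "n_tracked", "frame_interval_s",
                 "feature_config", "input_lo", "input_hi", "n_members"}
        return cls(
            nets=nets, window_w=int(meta["window_w"]), horizon_k=int(meta["horizon_k"]),
            n_tracked=int(meta["n_tracked"]),
            frame_interval_s=float(meta["frame_interval_s"]),
            feature_config=FeatureConfig.from_dict(meta["feature_config"]),
            input_lo=float(meta["input_lo"]), input_hi=float(meta["input_hi"]),
            target_mean=arrays["target_mean"], target_sd=arrays["target_sd"],
            manifest={k: v for k, v in meta.items() if k not in known})


def train_motion_model(ts: MotionTrainingSet,
                       config: MotionTrainConfig | None = None) -> MotionModel:
    """Train the LSTM on normalized features/targets with early stopping."""
    config = config or MotionTrainConfig()
    if ts.n_samples < 1:
        raise MotionError("empty training set")
    lo, hi = np.percentile(ts.inputs, list(config.norm_percentiles))
    if hi <= lo:
        hi = lo + 1.0
    t_mean = ts.targets_mm.mean(axis=0)
    per_axis = ts.targets_mm.reshape(ts.n_samples, ts.n_tracked, 3)
    sd = per_axis.std(axis=(0, 1))
    sd = np.where(sd < 1e-6, 1.0, sd)

    model = MotionModel(
        nets=[], window_w=ts.window_w, horizon_k=ts.horizon_k, n_tracked=ts.n_tracked,
        frame_interval_s=ts.frame_interval_s, feature_config=ts.feature_config,
        input_lo=float(lo), input_hi=float(hi), target_mean=t_mean,
        target_sd=sd, manifest={})
    x = model.normalize_inputs(ts.inputs)
    y = (ts.targets_mm - t_mean) / model._sd_full()
    weights = None
    if config.peak_weight > 0:
        z_mag = np.abs(per_axis[:, :, 2].mean(axis=1))
        z_max = z_mag.max()
        if z_max > 0:
            weights = 1.0 + config.peak_weight * (z_mag / z_max) ** 2
    members, curves = [], []
    for j in range(max(1, config.ensemble)):
        member_seed = config.seed + 1013 * j
        net = LSTMRegressor(
            n_features=ts.inputs.shape[2], n_outputs=3 * ts.n_tracked,
            hidden=config.hidden, layers=config.layers, seed=member_seed)
        train_curve, val_curve = net.fit(
            x, y, epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
            val_fraction=config.val_fraction, patience=config.patience,
            seed=member_seed, sample_weight=weights)
        members.append(net)
        curves.append({"epochs_run": len(train_curve),
                       "final_train_mse": train_curve[-1],
                       "best_val_mse": float(min(val_curve))})
    model.nets = members
    model.manifest = {
        "seed": config.seed, "members": curves,
        "best_val_mse": float(min(c["best_val_mse"] for c in curves)),
        **ts.manifest,
    }
    return model


def predict_flow(model: MotionModel, recent: list[CineFrame],
                 cadence_rtol: float = 0.05) -> FlowField:
    """Predict the tracked-set displacement k frames after the window end.

    ``recent`` must be exactly W consecutive CT-appearance frames at the
    model's cadence; the returned FlowField is stamped
    ``last frame time + k * frame_interval``.
    """
    if len(recent) != model.window_w:
        raise MotionError(f"need exactly W={model.window_w} frames, got {len(recent)}")
    for f in recent:
        if f.modality != "ct":
            raise MotionError("prediction inputs must be CT-appearance frames")
    if model.window_w > 1:
        try:
            dt = cadence_of(recent)
        except ValueError as exc:
            raise MotionError(f"cadence gap in prediction window: {exc}") from exc
        if abs(dt - model.frame_interval_s) > cadence_rtol * model.frame_interval_s:
            raise MotionError(
                f"cadence gap: frames at {dt:.4f} s vs model {model.frame_interval_s} s")
    feats = np.stack([model.feature_config.extract(f) for f in recent])
    vec = model.predict_raw(feats[None])[0]
    t_pred = recent[-1].time_s + model.horizon_k * model.frame_interval_s
    return FlowField(vectors_mm=vec.reshape(model.n_tracked, 3),
                     time_s=t_pred, reference_time_s=0.0)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class PredictionErrorReport:
    """Per-axis and phase-stratified error summary of predicted vs true flow."""

    times_s: np.ndarray
    signed_error_mm: np.ndarray        # (T, 3): tumor-mean predicted - true, per axis
    per_axis_rmse_mm: np.ndarray       # (3,)
    max_abs_mm: np.ndarray             # (3,)
    max_3d_mm: float
    phase_labels: list[str]            # per frame: inspiration/expiration/transition
    phase_rmse_mm: dict

    def to_dict(self) -> dict:
        return {
            "times_s": self.times_s.tolist(),
            "signed_error_mm": self.signed_error_mm.tolist(),
            "per_axis_rmse_mm": self.per_axis_rmse_mm.tolist(),
            "max_abs_mm": self.max_abs_mm.tolist(),
            "max_3d_mm": self.max_3d_mm,
            "phase_labels": self.phase_labels,
            "phase_rmse_mm": self.phase_rmse_mm,
        }


def evaluate_prediction(predictions: list[FlowField], truth: list[FlowField],
                        time_atol: float = 1e-6) -> PredictionErrorReport:
    """Compare predicted and true flow series at matched timestamps.

    Errors are on the tumor-mean displacement (mean over the tracked set),
    reported per world axis in mm, with frames stratified by breathing phase
    from the true superior-inferior displacement (inspiration peak =
    most-inferior decile band, expiration peak = least-displaced band).
    """
    if len(predictions) != len(truth):
        raise MotionError("prediction/truth length mismatch")
    for p, t in zip(predictions, truth):
        if abs(p.time_s - t.time_s) > time_atol:
            raise MotionError(f"timestamp mismatch: {p.time_s} vs {t.time_s}")
        if p.n != t.n:
            raise MotionError("tracked-set size mismatch")
    times = np.array([p.time_s for p in predictions])
    pred = np.stack([p.mean_mm() for p in predictions])
    true = np.stack([t.mean_mm() for t in truth])
    err = pred - true
    rmse = np.sqrt(np.mean(err ** 2, axis=0))
    max_abs = np.max(np.abs(err), axis=0)
    max3d = float(np.max(np.linalg.norm(err, axis=1)))

    z = true[:, 2]
    z_lo, z_hi = z.min(), z.max()
    band = 0.1 * max(z_hi - z_lo, 1e-9)
    labels = ["inspiration_peak" if zi <= z_lo + band
              else "expiration_peak" if zi >= z_hi - band
              else "transition" for zi in z]
    phase_rmse = {}
    for lab in ("inspiration_peak", "expiration_peak", "transition"):
        sel = np.array([l == lab for l in labels])
        phase_rmse[lab] = (np.sqrt(np.mean(err[sel] ** 2, axis=0)).tolist()
                           if sel.any() else None)
    return PredictionErrorReport(
        times_s=times, signed_error_mm=err, per_axis_rmse_mm=rmse,
        max_abs_mm=max_abs, max_3d_mm=max3d, phase_labels=labels,
        phase_rmse_mm=phase_rmse)
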