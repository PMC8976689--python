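"""Pretreatment training and the simulated real-time streaming loop.

Before treatment: planning 4D data (phantom-generated here) feed the
optical-flow label extraction, the translation-model fit and the motion-model
training; all artifacts are persisted with manifests.  During treatment: each
incoming MR-appearance cine frame is translated to CT appearance, buffered,
and once W frames are available the 3D displacement k frames ahead is
predicted, densified and used to warp the reference MR volume — one
reconstructed 3D frame per cine frame, timestamped k*dt into the future.

Real-time capability is validated by contract: the prediction horizon must
cover imaging time + beam delay + measured per-frame compute time (+ a
configurable margin for unmodelled overheads such as monitor output); the
absolute stage times are hardware-bound and are reported, never asserted.
"""

from __future__ import annotations

import dataclasses
import json
import time
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel

from . import flow as _flow
from . import io as _io
from . import motion as _motion
from . import phantom as _phantom
from . import reconstruct as _reconstruct
from . import translate as _translate
from .core import CineFrame, VolumeFrame
from .flow import FlowField, FlowParams, TrackedVoxelSet
from .motion import MotionModel, MotionTrainConfig
from .reconstruct import ReconstructionConfig
from .translate import CycleTrainConfig, TranslationModel


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PretreatConfig:
    """Everything the before-treatment branch needs, with study defaults."""

    phantom: _phantom.PhantomConfig = field(default_factory=_phantom.PhantomConfig)
    planning_cycles: float = 2.0
    planning_interval_s: float = 0.5
    cine_interval_s: float = 0.25
    horizon_k: int = 6
    window_w: int = 12
    periods_s: tuple = (4.0, 4.5, 5.0, 5.5, 6.0)
    n_tracked: int = 64
    roi_margin_mm: float = 16.0
    translation_mode: str = "lookup"          # "lookup" | "cycle-adversarial"
    flow: FlowParams = field(default_factory=FlowParams)
    recon: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    motion_train: MotionTrainConfig = field(default_factory=MotionTrainConfig)
    cycle_train: CycleTrainConfig = field(default_factory=CycleTrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.translation_mode not in ("lookup", "cycle-adversarial"):
            raise ValueError(f"unknown translation mode {self.translation_mode!r}")
        # one seed drives every stage deterministically
        self.phantom = dataclasses.replace(self.phantom, seed=self.seed)
        self.motion_train = dataclasses.replace(self.motion_train, seed=self.seed + 1)
        self.cycle_train = dataclasses.replace(self.cycle_train, seed=self.seed + 2)

    def roi_box_mm(self) -> np.ndarray:
        c = np.asarray(self.phantom.tumor_center_mm)
        return np.stack([c - self.roi_margin_mm, c + self.roi_margin_mm], axis=1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PretreatConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = _phantom.PhantomConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["phantom"].items()})
        for key, typ in (("flow", FlowParams), ("recon", ReconstructionConfig),
                         ("motion_train", MotionTrainConfig),
                         ("cycle_train", CycleTrainConfig)):
            if key in kwargs:
                kwargs[key] = typ(**kwargs[key])
        if "periods_s" in kwargs:
            kwargs["periods_s"] = tuple(kwargs["periods_s"])
        return cls(**kwargs)


@dataclass
class PretreatResult:
    translation_model: TranslationModel
    motion_model: MotionModel
    tracked: TrackedVoxelSet
    reference: VolumeFrame                  # MR-appearance reference volume
    planning_flows: list[FlowField]
    config: PretreatConfig

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg_dict = self.config.to_dict()
        _io.write_volume(self.reference, outdir / "reference_mr.nii.gz")
        self.translation_model.save(outdir / "translation_model")
        self.motion_model.save(outdir / "motion_model")
        _io.write_flow_series(self.planning_flows, self.tracked,
                              outdir / "planning_flows",
                              seed=self.config.seed, config=cfg_dict)
        (outdir / "pretreat_manifest.json").write_text(json.dumps(
            _io.make_manifest("pretreat", seed=self.config.seed, config=cfg_dict,
                              artifacts=["reference_mr.nii.gz", "translation_model",
                                         "motion_model", "planning_flows"]),
            indent=2, sort_keys=True))
        (outdir / "pretreat_config.yaml").write_text(
            yaml.safe_dump(json.loads(json.dumps(cfg_dict, default=str))))

    @classmethod
    def load(cls, outdir, config: PretreatConfig | None = None) -> "PretreatResult":
        outdir = Path(outdir)
        flows, tracked = _io.read_flow_series(outdir / "planning_flows")
        return cls(
            translation_model=TranslationModel.load(outdir / "translation_model"),
            motion_model=MotionModel.load(outdir / "motion_model"),
            tracked=tracked,
            reference=_io.read_volume(outdir / "reference_mr.nii.gz"),
            planning_flows=flows,
            config=config or PretreatConfig())


def _translation_training_data(config: PretreatConfig, plan_ct: list[VolumeFrame]):
    """Phantom stand-in for a patient's planning MR/CT image sets."""
    plan_mr, _ = _phantom.generate_4d(
        config.phantom, len(plan_ct), config.planning_interval_s, modality="mr")
    if config.translation_mode == "lookup":
        # paired voxel samples from one phase volume
        return plan_mr[0].data, plan_ct[0].data
    # unpaired sagittal slices: MR from even phases, CT from odd phases
    slab = config.phantom.tumor_center_mm[0]
    mr_slices = [c.data for c in _phantom.extract_cine(plan_mr[0::2], slab)]
    ct_slices = [c.data for c in _phantom.extract_cine(plan_ct[1::2], slab)]
    return mr_slices, ct_slices


def pretreat(config: PretreatConfig, outdir=None) -> PretreatResult:
    """Run the full before-treatment branch on phantom-generated data.

    Stages: planning 4D generation -> tracked-voxel selection -> flow
    extraction -> translation-model fit/training -> motion training-set
    build -> motion-model training.  Any stage failure aborts with a
    stage-tagged error; rerunning with the same config and seed reproduces
    every artifact bit-identically.
    """
    ph_cfg = config.phantom
    n_plan = int(round(config.planning_cycles * ph_cfg.period_s
                       / config.planning_interval_s)) + 1
    try:
        plan_ct, _ = _phantom.generate_4d(ph_cfg, n_plan, config.planning_interval_s,
                                          modality="ct")
        reference = _phantom.reference_volume(ph_cfg, "mr")
    except Exception as exc:
        raise PipelineError("phantom", str(exc)) from exc

    try:
        tracked = _flow.select_tracked_voxels(
            plan_ct[0], config.roi_box_mm(), config.n_tracked, config.flow)
    except Exception as exc:
        raise PipelineError("tracked-voxels", str(exc)) from exc

    try:
        mr_data, ct_data = _translation_training_data(config, plan_ct)
        if config.translation_mode == "lookup":
            translation = _translate.fit_lookup(mr_data, ct_data)
        else:
            translation = _translate.train_translation(mr_data, ct_data,
                                                       config.cycle_train)
    except Exception as exc:
        raise PipelineError("translation", str(exc)) from exc

    try:
        ts = _motion.build_training_set(
            plan_ct, slab_x_mm=ph_cfg.tumor_center_mm[0], tracked=tracked,
            flow_params=config.flow, k=config.horizon_k, w=config.window_w,
            periods_s=config.periods_s, native_period_s=ph_cfg.period_s,
            cine_interval_s=config.cine_interval_s)
    except Exception as exc:
        raise PipelineError("training-set", str(exc)) from exc

    try:
        motion_model = _motion.train_motion_model(ts, config.motion_train)
    except Exception as exc:
        raise PipelineError("motion-training", str(exc)) from exc

    # native-period planning flow series, persisted as the label artifact
    try:
        native_frames = _phantom.resample_period(
            plan_ct, ph_cfg.period_s, ph_cfg.period_s,
            frame_interval_s=config.cine_interval_s)
        planning_flows = _flow.flow_time_series(native_frames, tracked, config.flow)
    except Exception as exc:
        raise PipelineError("planning-flows", str(exc)) from exc

    result = PretreatResult(
        translation_model=translation, motion_model=motion_model, tracked=tracked,
        reference=reference, planning_flows=planning_flows, config=config)
    if outdir is not None:
        result.save(outdir)
    return result


# ---------------------------------------------------------------------------
# streaming
# ---------------------------------------------------------------------------

@dataclass
class LatencyBudget:
    """Frame-count latency contract of the device + algorithm."""

    imaging_s: float = 0.25
    beam_delay_s: float = 0.5
    alpha_margin_s: float = 0.0       # unquantified overheads (monitor output, ...)
    horizon_s: float = 1.5

    def violated(self, compute_s: float) -> bool:
        return self.horizon_s < (self.imaging_s + self.beam_delay_s
                                 + self.alpha_margin_s + compute_s)


@dataclass
class BudgetEntry:
    frame_index: int
    translate_s: float
    input_prep_s: float
    predict_s: float
    reconstruct_s: float
    violation: bool

    @property
    def compute_s(self) -> float:
        return self.translate_s + self.input_prep_s + self.predict_s + self.reconstruct_s


@dataclass
class StreamOutput:
    frame: VolumeFrame
    flow: FlowField
    budget: BudgetEntry


@dataclass
class StreamState:
    """Ring buffer of translated frames plus the running budget log."""

    window_w: int
    buffer: deque = field(default_factory=deque)
    current_index: int = -1
    n_emitted: int = 0
    budget_log: list = field(default_factory=list)

    def push(self, frame: CineFrame) -> None:
        if self.buffer and frame.time_s <= self.buffer[-1].time_s:
            raise PipelineError("stream", "timestamps must be strictly increasing")
        self.buffer.append(frame)
        while len(self.buffer) > self.window_w:
            self.buffer.popleft()
        self.current_index += 1

    @property
    def full(self) -> bool:
        return len(self.buffer) == self.window_w


def stream(result: PretreatResult, cine_source, budget: LatencyBudget | None = None,
            extra_delay_s: float = 0.0):
    """Simulated real-time loop: translate -> buffer -> predict -> reconstruct.

    Yields one :class:`StreamOutput` per input frame once the buffer holds W
    frames (first emission at frame index W-1).  ``extra_delay_s`` injects an
    artificial per-frame stage delay (for exercising the budget flag).
    """
    model = result.motion_model
    k, dt = model.horizon_k, model.frame_interval_s
    if budget is None:
        budget = LatencyBudget(imaging_s=dt, horizon_s=k * dt)
    state = StreamState(window_w=model.window_w)
    for frame in cine_source:
        t0 = time.perf_counter()
        ct_frame = _translate.translate(result.translation_model, frame)
        t1 = time.perf_counter()
        state.push(ct_frame)
        if not state.full:
            continue
        window = list(state.buffer)
        t2 = time.perf_counter()
        flow = _motion.predict_flow(model, window)
        t3 = time.perf_counter()
        recon = _reconstruct.reconstruct_frame(
            result.reference, flow, result.tracked, result.config.recon)
        t4 = time.perf_counter()
        if extra_delay_s:
            time.sleep(min(extra_delay_s, 0.05))
            t4 += extra_delay_s
        entry = BudgetEntry(
            frame_index=state.current_index,
            translate_s=t1 - t0, input_prep_s=t2 - t1,
            predict_s=t3 - t2, reconstruct_s=t4 - t3,
            violation=False)
        entry.violation = budget.violated(entry.compute_s)
        state.budget_log.append(entry)
        state.n_emitted += 1
        yield StreamOutput(frame=recon, flow=flow, budget=entry)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

class StageTimes(BaseModel):
    mean_s: float
    max_s: float


class BudgetSummary(BaseModel):
    horizon_s: float
    imaging_s: float
    beam_delay_s: float
    alpha_margin_s: float
    frames: int
    violations: int


class ErrorSummary(BaseModel):
    per_axis_rmse_mm: list[float]
    max_abs_mm: list[float]
    max_3d_mm: float
    phase_rmse_mm: dict[str, list[float] | None]


class StreamReport(BaseModel):
    """Schema of the JSON summary produced by :func:`report`."""

    stages: dict[str, StageTimes]
    budget: BudgetSummary
    errors: ErrorSummary | None = None


def report(budget_log: list[BudgetEntry], budget: LatencyBudget,
           error_report=None) -> tuple[StreamReport, str]:
    """Summarize per-stage times, budget violations and prediction errors.

    Returns the validated report model plus a human-readable rendering.
    """
    if not budget_log:
        raise PipelineError("report", "empty budget log")
    stages = {}
    for name in ("translate", "input_prep", "predict", "reconstruct"):
        vals = [getattr(e, f"{name}_s") for e in budget_log]
        stages[name] = StageTimes(mean_s=float(np.mean(vals)), max_s=float(np.max(vals)))
    summary = StreamReport(
        stages=stages,
        budget=BudgetSummary(
            horizon_s=budget.horizon_s, imaging_s=budget.imaging_s,
            beam_delay_s=budget.beam_delay_s, alpha_margin_s=budget.alpha_margin_s,
            frames=len(budget_log),
            violations=int(sum(e.violation for e in budget_log))),
        errors=None if error_report is None else ErrorSummary(
            per_axis_rmse_mm=list(map(float, error_report.per_axis_rmse_mm)),
            max_abs_mm=list(map(float, error_report.max_abs_mm)),
            max_3d_mm=float(error_report.max_3d_mm),
            phase_rmse_mm=error_report.phase_rmse_mm))
    lines = ["per-frame stage times (s):"]
    for name, st in summary.stages.items():
        lines.append(f"  {name:<12} mean {st.mean_s:.4f}  max {st.max_s:.4f}")
    b = summary.budget
    lines.append(f"latency budget: horizon {b.horizon_s:.2f} s vs imaging {b.imaging_s:.2f}"
                 f" + beam {b.beam_delay_s:.2f} + margin {b.alpha_margin_s:.2f} + compute")
    lines.append(f"budget violations: {b.violations}/{b.frames} frames")
    if summary.errors is not None:
        e = summary.errors
        lines.append(f"per-axis RMSE (mm): x {e.per_axis_rmse_mm[0]:.3f} "
                     f"y {e.per_axis_rmse_mm[1]:.3f} z {e.per_axis_rmse_mm[2]:.3f}")
        lines.append(f"max 3D error: {e.max_3d_mm:.3f} mm")
        for phase, vals in e.phase_rmse_mm.items():
            if vals is not None:
                lines.append(f"  {phase:<18} RMSE (mm) "
                             + " ".join(f"{v:.3f}" for v in vals))
    return summary, "\n".join(lines)
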