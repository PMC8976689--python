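"""Synthetic breathing phantom with analytically known ground-truth motion.

The phantom stands in for treatment-planning 4DCT, a pre-treatment 3D MR
volume, and the intra-treatment 2D sagittal cine stream.  Anatomy is a set of
smooth analytic structures in *reference* (material) coordinates:

* soft-tissue background (abdomen / chest wall),
* a lung compartment above a curved diaphragm dome,
* a spherical tumor embedded in the lung, with a few vessel-like blobs
  around it (these give the optical-flow tracker texture to lock onto),
* two bright fiducial-like markers near the lung apex, in the zero-motion
  zone, acting as static background structures.

Breathing is modelled as a smooth periodic displacement field

    u(p, t) = s(t) * A * g(p_z)

where ``s(t) = ((1 - cos(2*pi*t/T)) / 2)**n`` is a 1-cos-style waveform with
a longer dwell at exhale for n > 1, ``A`` is the peak displacement vector
(superior-inferior amplitude plus a lateral fraction), and ``g(z)`` is a
motion weight equal to 1 around the diaphragm and tumor and decaying
smoothly to 0 towards the lung apex.  Because ``u`` depends on position only
through the reference z coordinate and points move *inferiorly* while ``g``
decreases superiorly, the forward map ``p -> p + u(p, t)`` is strictly
monotone in z and can be inverted exactly; every phase frame is rendered by
evaluating the anatomy at the exactly-inverted coordinates, so the rendered
images and the analytic truth displacement are consistent by construction.

Reference phase is t = 0 (maximum expiration, s = 0): truth displacement at
the reference phase is identically zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import CineFrame, VolumeFrame, cadence_of

# clean-intensity scale (arbitrary CT-like units)
TISSUE_CT = {
    "lung": 100.0,
    "soft": 500.0,
    "vessel": 320.0,
    "tumor": 800.0,
    "marker": 900.0,
}
_CT_SCALE = 1000.0


class PhantomConfigError(ValueError):
    """Configuration puts the phantom in an unphysical / unrenderable state."""


@dataclass
class PhantomConfig:
    """Geometry, breathing regime and rendering parameters of the phantom.

    Defaults describe the study regime: a 64x64x64 grid at 2 mm isotropic
    spacing, ~16 mm peak-to-peak superior-inferior tumor excursion and a
    5 s respiratory period.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    period_s: float = 5.0
    amplitude_mm: float = 16.0
    tumor_center_mm: tuple[float, float, float] = (63.0, 63.0, 72.0)
    tumor_radius_mm: float = 8.0
    diaphragm_z0_mm: float = 40.0
    dome_drop_mm: float = 20.0
    lateral_fraction: float = 0.15
    waveform_power: float = 2.0
    edge_width_mm: float = 2.0
    mr_gamma: float = 0.6
    mr_bias_amplitude: float = 0.0
    ct_noise_sd: float = 2.0
    mr_noise_sd: float = 4.0
    amplitude_drift_per_s: float = 0.0
    period_jitter_sd: float = 0.0
    seed: int = 0
    # motion-weight ramp; None -> derived from the anatomy in __post_init__
    motion_plateau_z_mm: float | None = None
    motion_zero_z_mm: float | None = None

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise PhantomConfigError("period_s must be > 0")
        if self.amplitude_mm < 0:
            raise PhantomConfigError("amplitude_mm must be >= 0")
        if any(n < 8 for n in self.grid_shape):
            raise PhantomConfigError("grid too small for the phantom anatomy")
        ext = self.extent_mm()
        if self.motion_plateau_z_mm is None:
            self.motion_plateau_z_mm = max(
                self.tumor_center_mm[2] + self.tumor_radius_mm, self.diaphragm_z0_mm
            ) + 6.0
        if self.motion_zero_z_mm is None:
            self.motion_zero_z_mm = self.apex_z_mm()
        if self.motion_zero_z_mm <= self.motion_plateau_z_mm:
            raise PhantomConfigError("motion ramp must have positive width")
        # tumor must stay inside the grid at every phase (worst case s = 1)
        amp_max = self.amplitude_mm * (1.0 + abs(self.amplitude_drift_per_s) * 60.0)
        lo = np.asarray(self.tumor_center_mm) - self.tumor_radius_mm
        hi = np.asarray(self.tumor_center_mm) + self.tumor_radius_mm
        peak = np.asarray(self.displacement_direction()) * amp_max
        for disp in (np.zeros(3), peak):
            if np.any(lo + np.minimum(disp, 0) < -1e-9) or np.any(hi + np.maximum(disp, 0) > ext + 1e-9):
                raise PhantomConfigError(
                    "tumor leaves the grid at some breathing phase "
                    f"(center {self.tumor_center_mm}, amplitude {self.amplitude_mm} mm)"
                )

    # ---- derived geometry -------------------------------------------------
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)

    def apex_z_mm(self) -> float:
        """Top of the lung compartment."""
        return float(self.extent_mm()[2] - 10.0)

    def displacement_direction(self) -> np.ndarray:
        """Unit-amplitude peak displacement vector (SI excursion = 1)."""
        return np.array([self.lateral_fraction, self.lateral_fraction, -1.0])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# breathing kinematics
# ---------------------------------------------------------------------------

def _cycle_periods(config: PhantomConfig, n_cycles: int) -> np.ndarray:
    if config.period_jitter_sd <= 0:
        return np.full(n_cycles, config.period_s)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6A1]))
    factors = 1.0 + config.period_jitter_sd * rng.standard_normal(n_cycles)
    return config.period_s * np.clip(factors, 0.3, 3.0)


def breathing_phase(config: PhantomConfig, t: np.ndarray) -> np.ndarray:
    """Phase angle theta(t) in [0, 2*pi) accounting for cycle-to-cycle jitter."""
    t = np.asarray(t, dtype=float)
    if config.period_jitter_sd <= 0:
        return 2.0 * np.pi * np.mod(t / config.period_s, 1.0)
    n_cycles = int(np.ceil(np.max(t, initial=0.0) / (0.3 * config.period_s))) + 2
    periods = _cycle_periods(config, n_cycles)
    edges = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_cycles - 1)
    frac = (t - edges[idx]) / periods[idx]
    return 2.0 * np.pi * np.mod(frac, 1.0)


def waveform(config: PhantomConfig, t) -> np.ndarray:
    """Normalized breathing waveform s(t) in [0, 1]; s(0) = 0 (max expiration)."""
    theta = breathing_phase(config, t)
    return ((1.0 - np.cos(theta)) / 2.0) ** config.waveform_power


def motion_weight(config: PhantomConfig, z_mm) -> np.ndarray:
    """Spatial motion weight g(z): 1 below the plateau, cos^2 ramp to 0 at the apex."""
    z = np.asarray(z_mm, dtype=float)
    p, z1 = config.motion_plateau_z_mm, config.motion_zero_z_mm
    frac = np.clip((z - p) / (z1 - p), 0.0, 1.0)
    return np.cos(0.5 * np.pi * frac) ** 2


def _effective_amplitude(config: PhantomConfig, t) -> np.ndarray:
    return config.amplitude_mm * (1.0 + config.amplitude_drift_per_s * np.asarray(t, dtype=float))


def displacement_at(config: PhantomConfig, t: float, points_mm: np.ndarray) -> np.ndarray:
    """Forward displacement u(p, t) (mm) of material points p (reference coords)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    s_amp = float(waveform(config, t)) * float(_effective_amplitude(config, t))
    g = motion_weight(config, pts[:, 2])
    return s_amp * g[:, None] * config.displacement_direction()[None, :]


# ---------------------------------------------------------------------------
# anatomy in reference coordinates
# ---------------------------------------------------------------------------

def _sphere_frac(px, py, pz, center, radius, width):
    d = radius - np.sqrt((px - center[0]) ** 2 + (py - center[1]) ** 2 + (pz - center[2]) ** 2)
    return expit(d / width)


def anatomy_clean(config: PhantomConfig, px, py, pz) -> np.ndarray:
    """Clean CT-scale intensity of the anatomy at reference coordinates (mm)."""
    px, py, pz = np.broadcast_arrays(px, py, pz)
    ext = config.extent_mm()
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    w = config.edge_width_mm
    # diaphragm dome: apex at z0 in the middle, dropping towards the edges
    r2 = (px - cx) ** 2 + (py - cy) ** 2
    edge_r2 = (0.45 * min(ext[0], ext[1])) ** 2
    dome_z = config.diaphragm_z0_mm - config.dome_drop_mm * r2 / edge_r2
    lung = expit((pz - dome_z) / w) * expit((config.apex_z_mm() - pz) / w)
    out = TISSUE_CT["soft"] * (1.0 - lung) + TISSUE_CT["lung"] * lung
    # vessel-like blobs near the tumor (texture for flow tracking)
    c0 = np.asarray(config.tumor_center_mm)
    rt = config.tumor_radius_mm
    for off in ((1.6 * rt, 0.7 * rt, -0.6 * rt), (-1.5 * rt, -0.9 * rt, 0.8 * rt),
                (0.5 * rt, -1.5 * rt, 1.3 * rt)):
        v = _sphere_frac(px, py, pz, c0 + np.asarray(off), 0.45 * rt, w) * lung
        out = out * (1.0 - v) + TISSUE_CT["vessel"] * v
    tf = _sphere_frac(px, py, pz, c0, rt, w)
    out = out * (1.0 - tf) + TISSUE_CT["tumor"] * tf
    # static markers above the motion-zero level
    zm = config.motion_zero_z_mm + 0.4 * (ext[2] - config.motion_zero_z_mm)
    for mx in (0.3 * ext[0], 0.7 * ext[0]):
        m = _sphere_frac(px, py, pz, (mx, cy, zm), 3.0, w)
        out = out * (1.0 - m) + TISSUE_CT["marker"] * m
    return out


# ---------------------------------------------------------------------------
# modality rendering
# ---------------------------------------------------------------------------

def intensity_maps(config: PhantomConfig):
    """Return (ct_to_mr, mr_to_ct) — the exact monotone per-tissue intensity maps."""
    gamma = config.mr_gamma

    def ct_to_mr(c):
        c = np.clip(np.asarray(c, dtype=np.float64), 0.0, None)
        return (_CT_SCALE * (c / _CT_SCALE) ** gamma).astype(np.float32)

    def mr_to_ct(m):
        m = np.clip(np.asarray(m, dtype=np.float64), 0.0, None)
        return (_CT_SCALE * (m / _CT_SCALE) ** (1.0 / gamma)).astype(np.float32)

    return ct_to_mr, mr_to_ct


def _bias_field(config: PhantomConfig, frame: VolumeFrame) -> np.ndarray:
    """Smooth multiplicative MR bias field (deterministic, low order)."""
    if config.mr_bias_amplitude <= 0:
        return np.ones(frame.shape, dtype=np.float32)
    ext = np.maximum(config.extent_mm(), 1e-9)
    x = frame.axis_coords_mm(0) / ext[0]
    y = frame.axis_coords_mm(1) / ext[1]
    z = frame.axis_coords_mm(2) / ext[2]
    f = (np.sin(np.pi * x)[:, None, None]
         * np.sin(np.pi * y)[None, :, None]
         * np.cos(0.5 * np.pi * z)[None, None, :])
    return (1.0 + config.mr_bias_amplitude * f).astype(np.float32)


def render_modality(
    frame: VolumeFrame,
    modality: str,
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> VolumeFrame:
    """Render a clean (tissue-intensity) phantom frame as CT-like or MR-like.

    CT-like keeps the absolute tissue scale; MR-like applies the documented
    monotone per-tissue gamma map plus an optional smooth bias field.  Noise
    is additive Gaussian with the configured per-modality SD; pass ``rng``
    for reproducible noise (defaults to a generator seeded from the config).
    """
    if frame.modality != "clean":
        raise ValueError("render_modality requires a clean phantom frame "
                         f"(got modality {frame.modality!r})")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1]))
    if modality == "ct":
        data = frame.data.astype(np.float64)
        if config.ct_noise_sd > 0:
            data = data + config.ct_noise_sd * rng.standard_normal(frame.shape)
    elif modality == "mr":
        ct_to_mr, _ = intensity_maps(config)
        data = ct_to_mr(frame.data).astype(np.float64) * _bias_field(config, frame)
        if config.mr_noise_sd > 0:
            data = data + config.mr_noise_sd * rng.standard_normal(frame.shape)
    else:
        raise ValueError(f"unknown modality {modality!r}; expected 'ct' or 'mr'")
    return frame.with_data(data.astype(np.float32), modality=modality)


# ---------------------------------------------------------------------------
# phase-frame rendering via exact inversion of the forward map
# ---------------------------------------------------------------------------

def _invert_z(config: PhantomConfig, s_amp: float, z_out: np.ndarray) -> np.ndarray:
    """Solve x_z = p_z + s_amp * dir_z * g(p_z) for p_z (exact, monotone)."""
    dir_z = config.displacement_direction()[2]  # -1: inferior motion
    lo = float(np.min(z_out)) - 2.0 * abs(s_amp) - 4.0
    hi = float(np.max(z_out)) + 2.0 * abs(s_amp) + 4.0
    p_dense = np.linspace(lo, hi, 4096)
    x_dense = p_dense + s_amp * dir_z * motion_weight(config, p_dense)
    if np.any(np.diff(x_dense) <= 0):
        raise PhantomConfigError("breathing field is not invertible (z fold-over)")
    return np.interp(z_out, x_dense, p_dense)


def _clean_frame(config: PhantomConfig, t: float) -> VolumeFrame:
    spacing = config.spacing_mm
    x = np.arange(config.grid_shape[0]) * spacing[0]
    y = np.arange(config.grid_shape[1]) * spacing[1]
    z = np.arange(config.grid_shape[2]) * spacing[2]
    s_amp = float(waveform(config, t)) * float(_effective_amplitude(config, t))
    direction = config.displacement_direction()
    pz = _invert_z(config, s_amp, z)                     # (nz,)
    g = motion_weight(config, pz)                        # (nz,)
    ux = s_amp * direction[0] * g
    uy = s_amp * direction[1] * g
    data = anatomy_clean(
        config,
        x[:, None, None] - ux[None, None, :],
        y[None, :, None] - uy[None, None, :],
        np.broadcast_to(pz[None, None, :], config.grid_shape),
    )
    return VolumeFrame(data=data, spacing_mm=spacing, modality="clean", time_s=float(t))


@dataclass
class PhantomTruth:
    """Analytic ground truth of the phantom: test/evaluation oracle only."""

    config: PhantomConfig
    times_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def waveform(self, t) -> np.ndarray:
        return waveform(self.config, t)

    def tumor_center(self, t) -> np.ndarray:
        """Tumor-centre world position (mm) at time(s) t."""
        t = np.asarray(t, dtype=float)
        s = waveform(self.config, t) * _effective_amplitude(self.config, t)
        c0 = np.asarray(self.config.tumor_center_mm)
        g = motion_weight(self.config, c0[2])
        return c0 + np.multiply.outer(s * g, self.config.displacement_direction())

    def displacement(self, t: float, points_mm: np.ndarray,
                     reference_time_s: float = 0.0) -> np.ndarray:
        """Ground-truth displacement (mm) of reference-phase material points."""
        d = displacement_at(self.config, t, points_mm)
        if reference_time_s != 0.0:
            d = d - displacement_at(self.config, reference_time_s, points_mm)
        return d

    def tumor_mean_displacement(self, t: float, points_mm: np.ndarray) -> np.ndarray:
        return self.displacement(t, points_mm).mean(axis=0)

    def dense_displacement(self, t: float, frame: VolumeFrame) -> np.ndarray:
        """Forward displacement field (nx, ny, nz, 3) at reference voxel centres."""
        z = frame.axis_coords_mm(2)
        s_amp = float(waveform(self.config, t)) * float(_effective_amplitude(self.config, t))
        g = motion_weight(self.config, z)
        field3 = np.empty(frame.shape + (3,), dtype=np.float64)
        direction = self.config.displacement_direction()
        for a in range(3):
            field3[..., a] = (s_amp * direction[a] * g)[None, None, :]
        return field3

    def dense_backward_displacement(self, t: float, frame: VolumeFrame) -> np.ndarray:
        """Exact backward field d(x) with frame(x) = reference(x - d(x))."""
        z = frame.axis_coords_mm(2)
        s_amp = float(waveform(self.config, t)) * float(_effective_amplitude(self.config, t))
        pz = _invert_z(self.config, s_amp, z)
        g = motion_weight(self.config, pz)
        direction = self.config.displacement_direction()
        field3 = np.empty(frame.shape + (3,), dtype=np.float64)
        for a in range(3):
            field3[..., a] = (s_amp * direction[a] * g)[None, None, :]
        return field3


# ---------------------------------------------------------------------------
# public generation operations
# ---------------------------------------------------------------------------

def generate_4d(
    config: PhantomConfig,
    n_frames: int,
    frame_interval_s: float,
    modality: str = "ct",
) -> tuple[list[VolumeFrame], PhantomTruth]:
    """Generate a 4D phantom sequence plus its analytic ground truth.

    ``frame_interval_s = 0.5`` emulates the planning 4D series; ``0.25`` the
    intra-treatment volumetric stream.  ``modality`` is 'ct', 'mr' or 'clean'.
    Output is bit-identical for identical (config, seed).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, {"ct": 1, "mr": 2, "clean": 3}[modality]]))
    frames: list[VolumeFrame] = []
    times = np.arange(n_frames) * float(frame_interval_s)
    for t in times:
        clean = _clean_frame(config, float(t))
        frames.append(clean if modality == "clean" else render_modality(clean, modality, config, rng))
    return frames, PhantomTruth(config=config, times_s=times)


def reference_volume(config: PhantomConfig, modality: str = "mr") -> VolumeFrame:
    """Reference-phase (t = 0, maximum expiration) volume in the given modality."""
    clean = _clean_frame(config, 0.0)
    if modality == "clean":
        return clean
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x4EF]))
    return render_modality(clean, modality, config, rng)


def extract_cine(frames, slab_x_mm: float) -> list[CineFrame]:
    """Cut a sagittal (fixed-x) cine sequence out of a volume sequence."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    f0 = frames[0]
    x = f0.axis_coords_mm(0)
    if not (x[0] - 1e-9 <= slab_x_mm <= x[-1] + 1e-9):
        raise ValueError(f"slab position {slab_x_mm} mm outside grid [{x[0]}, {x[-1]}] mm")
    ix = int(np.argmin(np.abs(x - slab_x_mm)))
    out = []
    for i, f in enumerate(frames):
        f0.require_same_grid(f)
        out.append(CineFrame(
            data=f.data[ix],
            spacing_mm=(f.spacing_mm[1], f.spacing_mm[2]),
            time_s=f.time_s,
            frame_index=i,
            modality=f.modality,
            slab_x_mm=float(x[ix]),
            origin_mm=(f.origin_mm[1], f.origin_mm[2]),
        ))
    return out


def resample_period(
    frames,
    native_period_s: float,
    new_period_s: float,
    n_frames: int | None = None,
    frame_interval_s: float | None = None,
) -> list[VolumeFrame]:
    """Time-stretch a periodic volume sequence to a new respiratory period.

    Voxel intensities are linearly interpolated in time after phase
    rescaling; the output cadence equals the input cadence unless
    ``frame_interval_s`` overrides it.  One full output cycle spans
    ``new_period_s``.  The input must cover at least one full period.
    """
    frames = list(frames)
    if new_period_s <= 0:
        raise ValueError("new_period_s must be > 0")
    dt_in = cadence_of(frames)
    t0 = frames[0].time_s
    duration = frames[-1].time_s - t0
    if duration + dt_in < native_period_s - 1e-9:
        raise ValueError(
            f"input ({duration + dt_in:.3f} s incl. trailing interval) is shorter "
            f"than one native period ({native_period_s} s)")
    dt_out = dt_in if frame_interval_s is None else float(frame_interval_s)
    if n_frames is None:
        # cover the same time span as the input, trailing interval included,
        # so one full input cycle yields one full output cycle at the new period
        n_frames = int(round((duration + dt_in) * new_period_s / native_period_s / dt_out))
    out: list[VolumeFrame] = []
    for j in range(n_frames):
        t_out = j * dt_out
        # phase-equivalent source time, wrapped into one native period
        t_src = np.mod(t_out * native_period_s / new_period_s, native_period_s)
        pos = t_src / dt_in
        i0 = int(np.floor(pos))
        w = pos - i0
        i0 = min(i0, len(frames) - 1)
        i1 = i0 + 1
        if i1 >= len(frames):
            # wrap via periodicity of the underlying cycle
            n_per = max(int(round(native_period_s / dt_in)), 1)
            i1 = i1 % n_per
        data = (1.0 - w) * frames[i0].data.astype(np.float64) + w * frames[i1].data.astype(np.float64)
        out.append(frames[0].with_data(data.astype(np.float32), time_s=t0 + t_out))
    return out
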