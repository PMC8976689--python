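"""3D Lucas-Kanade optical flow of a tracked voxel set between volume frames.

This is the label generator of the pretreatment stage: the displacement of N
voxels around the tumor is estimated between breathing phases of the planning
4D series and vectorized in 3D (mm, world axes).  The solver is
coarse-to-fine Lucas-Kanade in *scale space*: levels are Gaussian smoothing
scales at full grid resolution (halving the smoothing each level) rather
than decimated grids — the tracked ROI boxes here are a few tens of voxels
across, too small to decimate meaningfully under a 7-voxel window.  At each
level the local least-squares brightness-constancy system over a cubic
window is solved per voxel, using the fixed image's structure tensor
(computed once per level, so the system matrix is inverted once) and
iterating the temporal term with warping of the moving image; the flow field
is mildly smoothed after every update, which keeps the per-voxel Jacobi-type
iteration from oscillating where windows overlap.  Voxels whose structure
tensor is ill-conditioned (smallest eigenvalue below a relative floor) are
flagged and follow their nearest well-conditioned neighbor.

Cumulative flow from a reference frame is composed incrementally from
inter-frame flows, sampling each inter-frame field at the carried (displaced)
position — a single solve from reference to a distant phase would exceed the
capture range at ~16 mm excursions.  Each inter-frame flow is by default the
average of the forward and the negated backward solve, which cancels the
leading-order bias that otherwise accumulates over a composed cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GridMismatchError, VolumeFrame


class FlowError(RuntimeError):
    pass


@dataclass
class FlowParams:
    """Lucas-Kanade solver parameters (voxel units unless noted)."""

    window_radius: int = 3
    pyramid_levels: int = 2              # scale-space levels; level l smooths at gradient_sigma * 2**l
    max_iters: int = 10                  # warping iterations per level
    eigenvalue_floor_rel: float = 1e-4   # fraction of the max structure-tensor trace
    gradient_sigma: float = 1.0          # finest-level presmoothing, voxels
    flow_smooth_sigma: float = 1.0       # per-iteration flow regularization, voxels
    convergence_tol: float = 0.01        # voxels
    symmetric: bool = True               # average forward and negated backward flow

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.eigenvalue_floor_rel <= 0:
            raise ValueError("eigenvalue_floor_rel must be > 0")

    def level_sigmas(self) -> list[float]:
        return [self.gradient_sigma * 2.0 ** level
                for level in range(self.pyramid_levels - 1, -1, -1)]

    def capture_margin_vox(self) -> int:
        return int(self.window_radius + 2 ** self.pyramid_levels + 4)


@dataclass
class TrackedVoxelSet:
    """N voxel indices inside a tumor-surrounding ROI, tracked through time."""

    voxel_indices: np.ndarray      # (N, 3) int
    roi_box_mm: np.ndarray         # (3, 2) world-axis bounds [lo, hi] per axis

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        self.roi_box_mm = np.asarray(self.roi_box_mm, dtype=float)
        if self.voxel_indices.ndim != 2 or self.voxel_indices.shape[1] != 3:
            raise ValueError("voxel_indices must be (N, 3)")
        if len(np.unique(self.voxel_indices, axis=0)) != len(self.voxel_indices):
            raise ValueError("voxel indices must be unique")

    @property
    def n(self) -> int:
        return len(self.voxel_indices)

    def positions_mm(self, frame: VolumeFrame) -> np.ndarray:
        return np.asarray(frame.origin_mm) + self.voxel_indices * np.asarray(frame.spacing_mm)


@dataclass
class FlowField:
    """3D displacement (mm, world axes) of a tracked voxel set at one time step."""

    vectors_mm: np.ndarray         # (N, 3)
    time_s: float
    reference_time_s: float
    ill_conditioned: np.ndarray | None = None   # (N,) bool, True where filled

    def __post_init__(self) -> None:
        self.vectors_mm = np.asarray(self.vectors_mm, dtype=np.float64)
        if self.vectors_mm.ndim != 2 or self.vectors_mm.shape[1] != 3:
            raise ValueError("vectors_mm must be (N, 3)")
        if not np.all(np.isfinite(self.vectors_mm)):
            raise ValueError("flow vectors contain non-finite values")

    @property
    def n(self) -> int:
        return len(self.vectors_mm)

    def mean_mm(self) -> np.ndarray:
        return self.vectors_mm.mean(axis=0)


# ---------------------------------------------------------------------------
# tracked-voxel selection
# ---------------------------------------------------------------------------

def select_tracked_voxels(
    reference: VolumeFrame,
    roi_box_mm,
    n_target: int,
    params: FlowParams | None = None,
    gradient_floor_rel: float = 1e-3,
) -> TrackedVoxelSet:
    """Pick up to ``n_target`` well-conditioned voxels inside the ROI.

    Voxels are ranked by descending Gaussian-smoothed gradient magnitude
    (ties broken by lexicographic index), which favours structure edges —
    exactly the voxels Lucas-Kanade can track.
    """
    params = params or FlowParams()
    roi = np.asarray(roi_box_mm, dtype=float)
    if roi.shape != (3, 2):
        raise ValueError("roi_box_mm must be (3, 2)")
    grad = np.zeros(reference.shape)
    sm = ndimage.gaussian_filter(reference.data.astype(np.float64), params.gradient_sigma)
    for g in np.gradient(sm):
        grad += g ** 2
    grad = np.sqrt(grad)

    coords = [reference.axis_coords_mm(a) for a in range(3)]
    margin = params.window_radius + 2
    masks = []
    for a in range(3):
        in_roi = (coords[a] >= roi[a, 0]) & (coords[a] <= roi[a, 1])
        in_roi[:margin] = False
        in_roi[len(in_roi) - margin:] = False
        masks.append(in_roi)
    roi_mask = masks[0][:, None, None] & masks[1][None, :, None] & masks[2][None, None, :]
    if not roi_mask.any():
        raise FlowError("ROI box contains no voxels (or lies outside the grid)")
    gmax = grad[roi_mask].max()
    eligible = roi_mask & (grad > gradient_floor_rel * gmax)
    if not eligible.any():
        raise FlowError("no voxels above the gradient floor inside the ROI "
                        "(constant-intensity region?)")
    flat = np.flatnonzero(eligible.ravel())
    order = np.argsort(-grad.ravel()[flat], kind="stable")   # stable => lexicographic ties
    chosen = flat[order[: int(n_target)]]
    idx = np.stack(np.unravel_index(chosen, reference.shape), axis=1)
    return TrackedVoxelSet(voxel_indices=idx, roi_box_mm=roi)


# ---------------------------------------------------------------------------
# dense Lucas-Kanade on a box
# ---------------------------------------------------------------------------

def _warp_by_flow(vol_coef: np.ndarray, flow_vox: np.ndarray) -> np.ndarray:
    # cubic interpolation: trilinear warping leaves a systematic residual in
    # the temporal term that accumulates visibly over a composed cycle.
    # ``vol_coef`` holds precomputed cubic spline coefficients.
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in vol_coef.shape], indexing="ij")
    coords = [g + flow_vox[..., a] for a, g in enumerate(grids)]
    return ndimage.map_coordinates(vol_coef, coords, order=3, mode="nearest",
                                   prefilter=False)


def _lk_level(fixed: np.ndarray, moving: np.ndarray, flow: np.ndarray,
              params: FlowParams) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level; returns (updated flow, valid mask)."""
    size = 2 * params.window_radius + 1
    grads = np.gradient(fixed)
    a_mat = np.empty(fixed.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            s = ndimage.uniform_filter(grads[i] * grads[j], size)
            a_mat[..., i, j] = s
            a_mat[..., j, i] = s
    trace = a_mat[..., 0, 0] + a_mat[..., 1, 1] + a_mat[..., 2, 2]
    eig_min = np.linalg.eigvalsh(a_mat)[..., 0]
    valid = eig_min > params.eigenvalue_floor_rel * max(trace.max(), 1e-30)
    a_reg = a_mat + (1e-9 * max(trace.max(), 1.0)) * np.eye(3)
    a_inv = np.linalg.inv(a_reg)
    # ill-conditioned voxels inherit their nearest valid neighbor's flow at
    # every iteration; leaving them frozen would inject false residuals into
    # the window sums of adjacent well-conditioned voxels through the warp
    nearest = None
    if valid.any() and not valid.all():
        _, nearest = ndimage.distance_transform_edt(~valid, return_indices=True)
        flow = flow[tuple(nearest)]

    moving_coef = ndimage.spline_filter(moving, order=3, mode="nearest")
    for _ in range(params.max_iters):
        warped = _warp_by_flow(moving_coef, flow)
        it = warped - fixed
        b = np.empty(fixed.shape + (3,))
        for i in range(3):
            b[..., i] = -ndimage.uniform_filter(grads[i] * it, size)
        delta = np.einsum("...ij,...j->...i", a_inv, b)
        # trust region: one voxel per iteration keeps divergent voxels bounded
        delta = np.clip(delta, -1.0, 1.0)
        delta[~valid] = 0.0
        flow = flow + delta
        if nearest is not None:
            flow = flow[tuple(nearest)]
        if params.flow_smooth_sigma > 0:
            flow = np.stack(
                [ndimage.gaussian_filter(flow[..., a], params.flow_smooth_sigma)
                 for a in range(3)], axis=-1)
        if np.max(np.abs(delta)) < params.convergence_tol:
            break
    return flow, valid


def dense_lucas_kanade(fixed: np.ndarray, moving: np.ndarray,
                       params: FlowParams) -> tuple[np.ndarray, np.ndarray]:
    """Dense coarse-to-fine LK flow (voxel units) on a raw array pair.

    Returns ``(flow, valid)`` with flow shaped ``fixed.shape + (3,)`` such
    that ``moving(x + flow(x)) ~= fixed(x)`` — i.e. the forward motion of
    material located at x in the fixed frame.  ``valid`` marks voxels whose
    finest-level structure tensor was well conditioned; invalid voxels are
    filled from their nearest valid neighbor.
    """
    if fixed.shape != moving.shape:
        raise GridMismatchError(f"array shapes differ: {fixed.shape} vs {moving.shape}")
    fixed = fixed.astype(np.float64)
    moving = moving.astype(np.float64)

    def _one_direction(src, dst):
        flow = np.zeros(src.shape + (3,))
        valid = np.ones(src.shape, dtype=bool)
        for sigma in params.level_sigmas():
            f = ndimage.gaussian_filter(src, sigma)
            m = ndimage.gaussian_filter(dst, sigma)
            flow, valid = _lk_level(f, m, flow, params)
        return flow, valid

    flow, valid = _one_direction(fixed, moving)
    if params.symmetric:
        # first-order bias cancellation: the backward solve carries the
        # opposite-signed systematic error of the forward solve
        back, _ = _one_direction(moving, fixed)
        flow = 0.5 * (flow - back)
    if not valid.any():
        raise FlowError("all voxels ill-conditioned for Lucas-Kanade")
    return flow, valid


def _tracked_box(indices: np.ndarray, shape, margin: int) -> tuple[slice, slice, slice]:
    lo = np.maximum(indices.min(axis=0) - margin, 0)
    hi = np.minimum(indices.max(axis=0) + margin + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def lucas_kanade_3d(
    fixed: VolumeFrame,
    moving: VolumeFrame,
    tracked: TrackedVoxelSet,
    params: FlowParams | None = None,
) -> FlowField:
    """LK displacement (mm) of the tracked voxels from ``fixed`` to ``moving``."""
    params = params or FlowParams()
    fixed.require_same_grid(moving)
    box = _tracked_box(tracked.voxel_indices, fixed.shape, params.capture_margin_vox())
    flow_vox, valid = dense_lucas_kanade(fixed.data[box], moving.data[box], params)
    local = tracked.voxel_indices - np.array([s.start for s in box])
    vecs = flow_vox[local[:, 0], local[:, 1], local[:, 2]] * np.asarray(fixed.spacing_mm)
    flagged = ~valid[local[:, 0], local[:, 1], local[:, 2]]
    return FlowField(vectors_mm=vecs, time_s=moving.time_s,
                     reference_time_s=fixed.time_s, ill_conditioned=flagged)


def flow_time_series(
    frames,
    tracked: TrackedVoxelSet,
    params: FlowParams | None = None,
    reference_index: int = 0,
) -> list[FlowField]:
    """Cumulative LK displacement of the tracked set from the reference frame.

    One FlowField per input frame (zeros at the reference frame itself),
    composed incrementally: the inter-frame dense field is sampled at each
    voxel's carried position by spline interpolation, then accumulated.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    params = params or FlowParams()
    spacing = np.asarray(frames[reference_index].spacing_mm)
    n = tracked.n
    ref_t = frames[reference_index].time_s
    results: dict[int, FlowField] = {
        reference_index: FlowField(np.zeros((n, 3)), time_s=ref_t, reference_time_s=ref_t)
    }

    for direction in (+1, -1):
        pos_vox = tracked.voxel_indices.astype(np.float64)
        cum_mm = np.zeros((n, 3))
        i = reference_index
        while 0 <= i + direction < len(frames):
            j = i + direction
            frames[i].require_same_grid(frames[j])
            margin = params.capture_margin_vox()
            span = np.vstack([np.floor(pos_vox.min(axis=0)), np.ceil(pos_vox.max(axis=0))])
            lo = np.maximum(span[0].astype(int) - margin, 0)
            hi = np.minimum(span[1].astype(int) + margin + 1, frames[i].shape)
            box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            flow_vox, _ = dense_lucas_kanade(frames[i].data[box], frames[j].data[box], params)
            local = np.clip(pos_vox - lo, 0, np.array(flow_vox.shape[:3]) - 1.0)
            step = np.stack(
                [ndimage.map_coordinates(flow_vox[..., a], local.T, order=3, mode="nearest")
                 for a in range(3)], axis=1)
            cum_mm = cum_mm + step * spacing
            pos_vox = pos_vox + step
            results[j] = FlowField(vectors_mm=cum_mm.copy(), time_s=frames[j].time_s,
                                   reference_time_s=ref_t)
            i = j
    return [results[i] for i in range(len(frames))]
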