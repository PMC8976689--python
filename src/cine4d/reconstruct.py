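"""Reconstruct 3D frames by warping the reference MR volume with predicted flow.

The motion model predicts displacements only at the N tracked voxels; these
scattered vectors are first interpolated to a smooth dense field
(Gaussian-weighted scattered-data interpolation inside the ROI box, tapered
to zero over a margin outside it) and the reference volume is then
backward-warped: output voxel x samples the reference at ``x - d(x)``.  The
dense field is interpreted as target-to-reference displacement via the
small-displacement inversion ``d_back ~ d_forward``, with an optional
fixed-point refinement (``p = x - d(p)`` iterated) that matters only when
the cumulative field varies across the excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GridMismatchError, VolumeFrame
from .flow import FlowField, TrackedVoxelSet


class ReconstructionError(ValueError):
    pass


@dataclass
class ReconstructionConfig:
    interpolation: str = "trilinear"        # "nearest" | "trilinear"
    fill_value: float = 0.0
    smoothing_radius_mm: float = 6.0        # Gaussian kernel of the scattered interpolation
    taper_margin_mm: float = 12.0           # decay-to-zero band outside the ROI box
    fixed_point_iters: int = 2              # backward-field refinement iterations
    restrict_to_roi: bool = True            # reconstruct ROI box + margin only

    def __post_init__(self) -> None:
        if self.interpolation not in ("nearest", "trilinear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.smoothing_radius_mm <= 0:
            raise ValueError("smoothing_radius_mm must be positive")


def densify_flow(
    flow: FlowField,
    tracked: TrackedVoxelSet,
    grid: VolumeFrame,
    config: ReconstructionConfig | None = None,
) -> np.ndarray:
    """Interpolate N scattered displacement vectors to a dense (mm) field.

    Gaussian-weighted normalized scattered interpolation: every grid voxel
    takes the weight-averaged tracked vectors, multiplied by a smooth taper
    that is 1 inside the tracked ROI box and decays to 0 over the configured
    margin, so anatomy far from the tumor stays still.
    """
    config = config or ReconstructionConfig()
    if flow.n != tracked.n:
        raise ReconstructionError("flow and tracked set size mismatch")
    pts = tracked.positions_mm(grid)                       # (N, 3)
    if flow.n < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ReconstructionError("need >= 4 non-collinear tracked voxels")
    coords = [grid.axis_coords_mm(a) for a in range(3)]
    sigma = config.smoothing_radius_mm

    # separable Gaussian weights: w[n, i] per axis, combined by outer product
    wx = np.exp(-0.5 * ((coords[0][None, :] - pts[:, 0:1]) / sigma) ** 2)
    wy = np.exp(-0.5 * ((coords[1][None, :] - pts[:, 1:2]) / sigma) ** 2)
    wz = np.exp(-0.5 * ((coords[2][None, :] - pts[:, 2:3]) / sigma) ** 2)
    den = np.einsum("ni,nj,nk->ijk", wx, wy, wz)
    field = np.empty(grid.shape + (3,))
    for a in range(3):
        num = np.einsum("n,ni,nj,nk->ijk", flow.vectors_mm[:, a], wx, wy, wz)
        field[..., a] = num / np.maximum(den, 1e-12)
    # where no tracked voxel has meaningful weight the average is unreliable;
    # the taper below forces those regions toward zero anyway
    taper = np.ones(grid.shape)
    for a, c in enumerate(coords):
        lo, hi = tracked.roi_box_mm[a]
        m = config.taper_margin_mm
        t = np.clip(np.minimum(c - (lo - m), (hi + m) - c) / m, 0.0, 1.0)
        ramp = 0.5 - 0.5 * np.cos(np.pi * t)
        shape = [1, 1, 1]
        shape[a] = len(c)
        taper = taper * ramp.reshape(shape)
    return field * taper[..., None]


def warp_volume(
    reference: VolumeFrame,
    field_mm: np.ndarray,
    config: ReconstructionConfig | None = None,
    time_s: float | None = None,
) -> VolumeFrame:
    """Backward-warp the reference volume by a dense displacement field (mm).

    Output voxel x samples the reference at ``x - d_back(x)`` where the
    backward field is obtained from the given (forward) field by optional
    fixed-point refinement; with ``fixed_point_iters = 0`` the field is used
    as-is (small-displacement approximation).
    """
    config = config or ReconstructionConfig()
    if field_mm.shape != reference.shape + (3,):
        raise GridMismatchError(
            f"field shape {field_mm.shape} does not match volume {reference.shape}")
    spacing = np.asarray(reference.spacing_mm)
    field_vox = field_mm / spacing
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in reference.shape],
                        indexing="ij")
    # fixed point of p = x - d(p): start at p0 = x - d(x)
    sample = [g - field_vox[..., a] for a, g in enumerate(grids)]
    for _ in range(config.fixed_point_iters):
        d_at_p = [ndimage.map_coordinates(field_vox[..., a], sample, order=1,
                                          mode="nearest") for a in range(3)]
        sample = [g - d for g, d in zip(grids, d_at_p)]
    order = 0 if config.interpolation == "nearest" else 1
    out = ndimage.map_coordinates(reference.data.astype(np.float64), sample,
                                  order=order, mode="constant",
                                  cval=config.fill_value)
    return reference.with_data(
        out.astype(np.float32), modality=reference.modality,
        time_s=reference.time_s if time_s is None else float(time_s))


def reconstruct_frame(
    reference: VolumeFrame,
    flow: FlowField,
    tracked: TrackedVoxelSet,
    config: ReconstructionConfig | None = None,
) -> VolumeFrame:
    """Densify a predicted FlowField and warp the reference volume with it."""
    config = config or ReconstructionConfig()
    field = densify_flow(flow, tracked, reference, config)
    return warp_volume(reference, field, config, time_s=flow.time_s)


def difference_image(
    recon: VolumeFrame,
    truth: VolumeFrame,
    tumor_threshold: float | None = None,
) -> tuple[VolumeFrame, dict]:
    """Signed voxelwise difference plus summary statistics.

    Returns ``(difference frame, stats)`` with MAE, max |diff| and — when a
    ``tumor_threshold`` is given — the Dice overlap of the thresholded tumor
    masks of the two volumes.
    """
    recon.require_same_grid(truth)
    diff = recon.data.astype(np.float64) - truth.data.astype(np.float64)
    stats = {
        "mae": float(np.mean(np.abs(diff))),
        "max_abs": float(np.max(np.abs(diff))),
    }
    if tumor_threshold is not None:
        a = recon.data > tumor_threshold
        b = truth.data > tumor_threshold
        denom = int(a.sum()) + int(b.sum())
        stats["tumor_dice"] = (2.0 * int(np.sum(a & b)) / denom) if denom else 1.0
    return recon.with_data(diff.astype(np.float32), time_s=recon.time_s), stats
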