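"""Core in-memory containers shared by every module.

Conventions (binding for the whole package):

* voxel indices are 0-based, axis order ``(x, y, z)`` with
  x = left-right, y = anterior-posterior, z = inferior-superior;
* world coordinates are in millimetres, voxel-centre convention:
  ``world = origin_mm + index * spacing_mm``;
* displacement vectors are expressed in world axes, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MODALITIES = ("ct", "mr", "clean")


class GridMismatchError(ValueError):
    """Two frames do not share shape / spacing / origin."""


@dataclass
class VolumeFrame:
    """One 3D scalar image with geometry, modality tag and acquisition time."""

    data: np.ndarray            # (nx, ny, nz), float32
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "ct"
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def extent_mm(self) -> np.ndarray:
        """World position of the last voxel centre on each axis."""
        return np.asarray(self.origin_mm) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm)

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.spacing_mm[axis]

    def same_grid(self, other: "VolumeFrame", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_same_grid(self, other: "VolumeFrame") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing_mm}/{self.origin_mm} vs "
                f"{other.shape}/{other.spacing_mm}/{other.origin_mm}"
            )

    def with_data(self, data: np.ndarray, **changes) -> "VolumeFrame":
        return replace(self, data=np.asarray(data, dtype=np.float32), **changes)


@dataclass
class CineFrame:
    """One 2D sagittal (y-z plane, fixed x) slice of the anatomy at one time point."""

    data: np.ndarray            # (ny, nz), float32
    spacing_mm: tuple[float, float]   # (dy, dz)
    time_s: float
    frame_index: int
    modality: str = "mr"
    slab_x_mm: float = 0.0
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"cine data must be 2D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, **changes) -> "CineFrame":
        return replace(self, data=np.asarray(data, dtype=np.float32), **changes)


def cadence_of(frames) -> float:
    """Frame interval of a sequence; raises if the cadence is not constant."""
    times = np.asarray([f.time_s for f in frames], dtype=float)
    if times.size < 2:
        raise ValueError("need at least two frames to establish a cadence")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"frame cadence is not constant: intervals {dts}")
    return float(dts[0])
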