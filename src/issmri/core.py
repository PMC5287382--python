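"""Core spatial and time-series containers shared by the whole pipeline.

Conventions
-----------
* Physical coordinates are in millimetres, axis order ``(x, y, z)``.
* Voxel indices are 0-based; ``origin`` is the physical coordinate of the
  *center* of voxel ``(0, 0, 0)``.
* Image arrays are indexed ``[x, y, z]`` (3D) or ``[t, x, y, z]`` (4D).
* Concentrations are interstitial-fluid (ISF) concentrations in mM;
  signal values are in arbitrary scanner units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "VoxelGrid",
    "ImageSeries",
    "ConcentrationSeries",
    "IncrementSeries",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel grid in physical (mm) coordinates.

    Parameters
    ----------
    shape
        Number of voxels along each axis, all >= 1.
    voxel_size
        Edge length of a voxel along each axis in mm (default the scan
        protocol's isotropic 0.5 mm).
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        origin = tuple(float(v) for v in self.origin)
        if len(shape) != 3 or len(vs) != 3 or len(origin) != 3:
            raise ValueError("shape, voxel_size and origin must have length 3")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"all voxel_size entries must be > 0, got {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (equivalently microlitres)."""
        return float(np.prod(self.voxel_size))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    def center(self) -> np.ndarray:
        """Physical coordinate of the grid's geometric center, mm."""
        return np.array(
            [self.origin[i] + self.voxel_size[i] * (self.shape[i] - 1) / 2.0 for i in range(3)]
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (mm) spanned by the voxel volumes (lo, hi)."""
        lo = np.array(self.origin) - np.array(self.voxel_size) / 2.0
        hi = lo + np.array(self.voxel_size) * np.array(self.shape)
        return lo, hi

    def contains(self, point: np.ndarray) -> bool:
        lo, hi = self.bounds()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def distance_map(self, point) -> np.ndarray:
        """Euclidean distance (mm) from ``point`` to every voxel center."""
        p = np.asarray(point, dtype=float)
        dx = self.axis_coords(0) - p[0]
        dy = self.axis_coords(1) - p[1]
        dz = self.axis_coords(2) - p[2]
        return np.sqrt(
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int] = (64, 64, 64),
        voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    ) -> "VoxelGrid":
        """Grid whose physical center sits at the coordinate origin."""
        origin = tuple(-voxel_size[i] * (shape[i] - 1) / 2.0 for i in range(3))
        return cls(shape=shape, voxel_size=voxel_size, origin=origin)


def _check_frames(grid: VoxelGrid, frames: np.ndarray, times: np.ndarray, what: str) -> None:
    if frames.ndim != 4:
        raise ValueError(f"{what} must be a 4D (t, x, y, z) array, got ndim={frames.ndim}")
    if frames.shape[1:] != grid.shape:
        raise ValueError(
            f"{what} spatial shape {frames.shape[1:]} does not match grid shape {grid.shape}"
        )
    if frames.shape[0] != times.shape[0]:
        raise ValueError(
            f"{what} has {frames.shape[0]} frames but {times.shape[0]} time points"
        )
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be a strictly increasing 1D array")


@dataclass
class ImageSeries:
    """An MRI study of one subject: pre-injection baseline + dynamic frames.

    ``times`` are hours post-injection (the scanner clock, counted from the
    end of the tracer infusion).
    """

    grid: VoxelGrid
    baseline: np.ndarray
    frames: np.ndarray
    times: np.ndarray
    subject_id: str = "subject"
    group: str = "custom"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.baseline.shape != self.grid.shape:
            raise ValueError(
                f"baseline shape {self.baseline.shape} does not match grid {self.grid.shape}"
            )
        _check_frames(self.grid, self.frames, self.times, "frames")

    @property
    def n_times(self) -> int:
        return int(self.times.size)


@dataclass
class ConcentrationSeries:
    """Voxelwise ISF tracer concentration over time.

    ``times`` are seconds since the end of the infusion; ``values`` is the
    (t, x, y, z) concentration array in mM.  ``meta`` carries provenance from
    the conversion step (noise floor in concentration units, clip fraction).
    """

    grid: VoxelGrid
    times: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_frames(self.grid, self.values, self.times, "values")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def total_amounts(self, alpha: float = 1.0) -> np.ndarray:
        """Total tracer amount per frame: alpha * sum(C) * voxel volume, nmol.

        With ``alpha`` the ISS volume fraction this converts ISF concentration
        back to moles of tracer actually present in the tissue.
        """
        return alpha * self.values.reshape(self.values.shape[0], -1).sum(axis=1) * self.grid.voxel_volume


@dataclass
class IncrementSeries:
    """Signal increment over the pre-injection baseline, per voxel per time.

    Values may be negative (noise) — they are preserved here and clipped only
    at the concentration-conversion step.  ``noise_sigma_est`` is the
    background noise scale of the *increments*, estimated from tracer-free
    corner blocks.
    """

    grid: VoxelGrid
    times: np.ndarray
    values: np.ndarray
    noise_sigma_est: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_frames(self.grid, self.values, self.times, "values")
        if self.noise_sigma_est < 0:
            raise ValueError("noise_sigma_est must be >= 0")
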