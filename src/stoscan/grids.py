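"""Core spatial containers: voxel grids, volumes, 4D images, projection
stacks and the cone-beam system geometry.

Conventions
-----------
* World frame is right-handed with the rotation axis along ``z``
  (superior), origin at the isocenter. All lengths in mm, attenuation in
  1/mm.
* Volumes are stored as C-contiguous arrays indexed ``[ix, iy, iz]``;
  ``origin`` is the world position of the center of voxel ``(0, 0, 0)``.
* Gantry angle increases monotonically over the scan arc. At angle
  ``beta`` (degrees) the source sits at ``SAD * (cos b, sin b, 0)`` and
  the flat-panel detector is centered at ``(SAD - SDD) * (cos b, sin b, 0)``
  with column axis ``u = (-sin b, cos b, 0)`` and row axis ``v = z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "Volume3D", "Image4D", "ScanGeometry", "ProjectionSet"]


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: shape, isotropic-or-not spacing and origin (mm)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if self.origin is not None:
            object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if self.origin is None:
            # center the grid on the isocenter
            org = tuple(
                -(n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
            )
            object.__setattr__(self, "origin", org)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class Volume3D:
    """A 3D attenuation map on a regular grid (values in 1/mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("Volume3D.voxels must be 3-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("Volume3D spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume3D contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.voxels.shape, self.spacing, self.origin)

    def like(self, voxels: np.ndarray) -> "Volume3D":
        """A new volume with the same grid and the given voxel data."""
        return Volume3D(voxels, self.spacing, self.origin)

    @classmethod
    def zeros(cls, grid: GridSpec) -> "Volume3D":
        return cls(np.zeros(grid.shape, np.float32), grid.spacing, grid.origin)


@dataclass
class Image4D:
    """One reconstructed volume per respiratory bin, on a shared grid."""

    frames: list[Volume3D]
    bins: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Image4D needs at least one frame")
        if not self.bins:
            self.bins = list(range(1, len(self.frames) + 1))
        if len(self.bins) != len(self.frames):
            raise ValueError("Image4D bins and frames disagree in length")
        g0 = self.frames[0].grid
        for f in self.frames[1:]:
            if f.grid != g0:
                raise ValueError("Image4D frames must share a common grid")

    @property
    def n_bins(self) -> int:
        return len(self.frames)

    def frame(self, bin_label: int) -> Volume3D:
        return self.frames[self.bins.index(bin_label)]


@dataclass(frozen=True)
class ScanGeometry:
    """Circular cone-beam geometry with a flat-panel detector.

    Parameters are conventional linac values: source-axis distance 1000 mm,
    source-detector distance 1536 mm, and a 200 degree short-scan arc.
    """

    sad: float = 1000.0
    sdd: float = 1536.0
    det_rows: int = 96
    det_cols: int = 96
    pixel_pitch: float = 4.0
    arc_deg: float = 200.0

    def __post_init__(self) -> None:
        if not (self.sdd > self.sad > 0):
            raise ValueError("geometry requires SDD > SAD > 0")
        if self.det_rows <= 0 or self.det_cols <= 0 or self.pixel_pitch <= 0:
            raise ValueError("detector dimensions must be positive")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    def fan_half_angle_deg(self) -> float:
        """Half fan angle subtended by the detector columns, degrees."""
        half_width = self.det_cols * self.pixel_pitch / 2.0
        return float(np.degrees(np.arctan2(half_width, self.sdd)))

    def det_u(self) -> np.ndarray:
        """Physical column coordinates (mm) of detector pixel centers."""
        n = self.det_cols
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def det_v(self) -> np.ndarray:
        """Physical row coordinates (mm) of detector pixel centers."""
        n = self.det_rows
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch


@dataclass
class ProjectionSet:
    """Stack of 2D line-integral projections with per-projection metadata.

    ``stack`` has shape ``(n_proj, det_rows, det_cols)``; ``angles_deg``,
    ``times_s`` and ``bins`` hold per-projection gantry angle, acquisition
    time and respiratory bin label (0 marks an unassigned bin).
    """

    stack: np.ndarray
    angles_deg: np.ndarray
    geometry: ScanGeometry
    times_s: np.ndarray | None = None
    bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float32)
        if self.stack.ndim != 3:
            raise ValueError("projection stack must be (n_proj, rows, cols)")
        n = self.stack.shape[0]
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.angles_deg.shape != (n,):
            raise ValueError("angles_deg length must equal stack depth")
        if self.times_s is None:
            self.times_s = np.full(n, np.nan)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.bins is None:
            self.bins = np.zeros(n, dtype=np.int64)
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if self.times_s.shape != (n,) or self.bins.shape != (n,):
            raise ValueError("per-projection metadata length mismatch")

    @property
    def n_proj(self) -> int:
        return self.stack.shape[0]

    def select(self, mask: np.ndarray) -> "ProjectionSet":
        """Sub-stack at the given boolean/index mask, metadata included."""
        return ProjectionSet(
            self.stack[mask],
            self.angles_deg[mask],
            self.geometry,
            self.times_s[mask],
            self.bins[mask],
        )

    def for_bin(self, bin_label: int) -> "ProjectionSet":
        return self.select(self.bins == bin_label)

    def replace_stack(self, stack: np.ndarray) -> "ProjectionSet":
        return ProjectionSet(
            stack, self.angles_deg.copy(), self.geometry,
            self.times_s.copy(), self.bins.copy(),
        )
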