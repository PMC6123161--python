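"""Core voxel-grid geometry and image containers.

Conventions used throughout the package:

* arrays are indexed ``(i, j, k)`` along axes 0, 1, 2;
* axis 2 is the superior--inferior (SI) axis, with larger ``k`` more superior;
* physical units are millimetres; world coordinate = index * spacing + origin;
* masks are boolean voxel-centre membership (no sub-voxel geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

Shape3 = Tuple[int, int, int]
Vec3 = Tuple[float, float, float]


class GeometryError(ValueError):
    """Raised when two objects do not live on the same voxel grid."""


@dataclass(frozen=True)
class Grid:
    """A regular 3-D voxel grid with anisotropic spacing (mm)."""

    shape: Shape3
    spacing_mm: Vec3 = (2.0, 2.0, 5.0)
    origin_mm: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def fov_mm(self) -> np.ndarray:
        """Physical field of view along each axis."""
        return np.asarray(self.shape, float) * np.asarray(self.spacing_mm, float)

    def coordinate_axes(self):
        """World coordinates of voxel centres along each axis (three 1-D arrays)."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a], dtype=float)
            for a in range(3)
        )

    def meshgrid_mm(self):
        """World-coordinate arrays (x, y, z), each of shape ``self.shape``."""
        ax = self.coordinate_axes()
        return np.meshgrid(*ax, indexing="ij")

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, float)
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_as(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )


def require_same_grid(a: Grid, b: Grid, what: str = "operands") -> None:
    if not a.same_as(b):
        raise GeometryError(f"{what} must share a voxel grid: {a} vs {b}")


@dataclass
class PhaseVolume:
    """One scalar 3-D intensity volume at one respiratory phase."""

    intensity: np.ndarray
    grid: Grid
    phase_index: int = 0

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.shape != self.grid.shape:
            raise GeometryError(
                f"intensity shape {self.intensity.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity volume contains non-finite values")

    def with_intensity(self, intensity: np.ndarray) -> "PhaseVolume":
        return PhaseVolume(intensity=intensity, grid=self.grid, phase_index=self.phase_index)


@dataclass
class ContourMask:
    """Binary organ mask with provenance tags."""

    data: np.ndarray
    grid: Grid
    organ: str = ""
    phase_index: int = 0
    source: str = "truth"  # e.g. truth / manual-U1 / auto-U2 / s95
    series: str = "navigator"  # navigator | bellows

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def com_mm(self) -> np.ndarray:
        """Voxel-volume-weighted centroid in world coordinates (mm)."""
        if self.is_empty():
            raise ValueError(f"empty mask ({self.organ!r}, phase {self.phase_index}) has no COM")
        idx = np.argwhere(self.data).astype(float)
        com_idx = idx.mean(axis=0)
        return com_idx * np.asarray(self.grid.spacing_mm) + np.asarray(self.grid.origin_mm)

    def tagged(self, **kw) -> "ContourMask":
        return replace(self, **kw)


@dataclass
class DisplacementField:
    """Per-voxel 3-component displacement (mm) on the fixed-image grid.

    ``vectors[..., c]`` maps fixed-image point x to moving-image point
    x + u(x) along world axis ``c``.
    """

    vectors: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.shape != self.grid.shape + (3,):
            raise GeometryError(
                f"DVF shape {self.vectors.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, grid: Grid) -> "DisplacementField":
        return cls(np.zeros(grid.shape + (3,), dtype=np.float32), grid)

    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors.astype(float) ** 2).sum(axis=-1)).max())


#: organ label values in the anatomy label map
ORGAN_LABELS = {
    "right_lung": 1,
    "left_lung": 2,
    "heart": 3,
    "liver": 4,
    "stomach": 5,
    "body": 6,
}
#: the five delineated organs-at-risk (body is background tissue, not an OAR)
OAR_ORGANS = ("right_lung", "left_lung", "heart", "liver", "stomach")
#: organs treated as incompressible under respiration
VOLUME_CONSERVING_ORGANS = ("heart", "liver", "stomach")


@dataclass
class AnatomyLabelMap:
    """Integer anatomy labels: 0 background, 1-5 organs, 6 other body tissue."""

    labels: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.grid.shape:
            raise GeometryError("label map shape mismatch")

    def organ_mask(self, organ: str) -> ContourMask:
        lab = ORGAN_LABELS[organ]
        return ContourMask(self.labels == lab, self.grid, organ=organ, source="truth")
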