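"""Geometry-aware scalar grids, displacement fields, masks and FOV regions.

All coordinates are in a fixed world frame in millimetres.  A grid is
axis-aligned; its ``origin`` is the world position of the *centre* of voxel
``(0, 0, 0)`` and voxel ``(i, j, k)`` sits at ``origin + index * spacing``.
Arrays are indexed ``[i, j, k]`` matching world axes ``(x, y, z)``, with z the
superior-inferior axis (positive = superior).

Displacement fields use the pull (backward-sampling) convention: a field
defined on grid A maps a point ``x`` in A's frame to ``x + d(x)`` in the frame
of the image being sampled.  Warping an image from B onto A therefore uses a
field defined on A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

UNIT_TAGS = ("HU", "Gy", "binary", "unitless")


@dataclass(frozen=True)
class Geometry:
    """Axis-aligned voxel lattice: origin (mm), spacing (mm), size (voxels)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    size: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise ValueError(f"size must be >= 1 on all axes, got {self.size}")
        if not all(np.isfinite(self.origin)):
            raise ValueError(f"origin must be finite, got {self.origin}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points, shape (..., 3)."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.array(self.origin)) / np.array(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.array(self.origin) + idx * np.array(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.size[axis])

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape size + (3,)."""
        ax = [self.axis_coords(a) for a in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world corners of the voxel-centre bounding box."""
        lo = np.array(self.origin)
        hi = lo + (np.array(self.size) - 1) * np.array(self.spacing)
        return lo, hi


@dataclass
class ScalarGrid:
    """A 3D voxel volume with world geometry and a unit tag (HU/Gy/binary)."""

    geometry: Geometry
    values: np.ndarray
    unit_tag: str = "unitless"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.geometry.size):
            raise ValueError(
                f"values shape {self.values.shape} != geometry size {self.geometry.size}"
            )
        if self.unit_tag not in UNIT_TAGS:
            raise ValueError(f"unit_tag must be one of {UNIT_TAGS}, got {self.unit_tag!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must all be finite")

    def copy(self) -> "ScalarGrid":
        return ScalarGrid(self.geometry, self.values.copy(), self.unit_tag)

    def with_values(self, values: np.ndarray, unit_tag: str | None = None) -> "ScalarGrid":
        return ScalarGrid(self.geometry, values, unit_tag or self.unit_tag)

    def sample(self, points_mm: np.ndarray, fill: float = 0.0,
               mode: str = "constant") -> np.ndarray:
        """Trilinear sample at world points; outside the grid returns ``fill``
        (or the edge value with ``mode="nearest"``)."""
        if not np.isfinite(fill):
            raise ValueError("fill value must be finite")
        pts = np.asarray(points_mm, dtype=float)
        idx = self.geometry.world_to_index(pts)
        flat = idx.reshape(-1, 3).T
        out = ndimage.map_coordinates(
            self.values, flat, order=1, mode=mode, cval=fill, prefilter=False
        )
        return out.reshape(pts.shape[:-1])


@dataclass
class VectorField:
    """Displacement field (mm, world axes) on a grid geometry; pull convention."""

    geometry: Geometry
    displacements: np.ndarray  # shape size + (3,)

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float)
        expected = tuple(self.geometry.size) + (3,)
        if self.displacements.shape != expected:
            raise ValueError(
                f"displacements shape {self.displacements.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement components must all be finite")

    @classmethod
    def zeros(cls, geometry: Geometry) -> "VectorField":
        return cls(geometry, np.zeros(tuple(geometry.size) + (3,)))

    @classmethod
    def constant(cls, geometry: Geometry, vec_mm: Sequence[float]) -> "VectorField":
        d = np.empty(tuple(geometry.size) + (3,))
        d[...] = np.asarray(vec_mm, dtype=float)
        return cls(geometry, d)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def copy(self) -> "VectorField":
        return VectorField(self.geometry, self.displacements.copy())


@dataclass
class ROIMask:
    """Binary region of interest on a grid (target, organ-at-risk or external)."""

    grid: ScalarGrid
    name: str
    category: str = "OAR"  # {target, OAR, external}

    def __post_init__(self):
        if self.grid.unit_tag != "binary":
            raise ValueError("ROI mask grid must have unit_tag 'binary'")
        vals = self.grid.values
        if not np.all((vals == 0) | (vals == 1)):
            raise ValueError("ROI mask values must be 0/1")

    @property
    def mask(self) -> np.ndarray:
        return self.grid.values.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.grid.values.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.geometry.voxel_volume_mm3 / 1000.0

    def center_of_mass_mm(self) -> np.ndarray:
        m = self.mask
        if not m.any():
            raise ValueError(f"ROI {self.name!r} is empty")
        idx = np.array(np.nonzero(m), dtype=float).T
        return self.grid.geometry.index_to_world(idx).mean(axis=0)


def mask_from_bool(geometry: Geometry, arr: np.ndarray, name: str,
                   category: str = "OAR") -> ROIMask:
    return ROIMask(ScalarGrid(geometry, arr.astype(float), "binary"), name, category)


@dataclass(frozen=True)
class FOVRegion:
    """Imaging field of view: a cylinder (axis-aligned) or a box, in mm."""

    shape: str  # {cylinder, box}
    center: tuple[float, float, float]
    diameter: float | None = None  # cylinder
    length: float | None = None    # cylinder extent along its axis; None = infinite
    extents: tuple[float, float, float] | None = None  # box full widths
    axis: int = 2  # world axis of the cylinder

    def __post_init__(self):
        if self.shape not in ("cylinder", "box"):
            raise ValueError(f"FOV shape must be cylinder or box, got {self.shape!r}")
        if self.shape == "cylinder":
            if self.diameter is None or self.diameter <= 0:
                raise ValueError("cylinder FOV needs a positive diameter")
            if self.length is not None and self.length <= 0:
                raise ValueError("cylinder length must be positive")
        else:
            if self.extents is None or any(e <= 0 for e in self.extents):
                raise ValueError("box FOV needs positive extents")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean inside-test for world points, shape (..., 3) -> (...)."""
        p = np.asarray(points_mm, dtype=float)
        c = np.array(self.center)
        if self.shape == "cylinder":
            lat = [a for a in range(3) if a != self.axis]
            r2 = sum((p[..., a] - c[a]) ** 2 for a in lat)
            inside = r2 <= (self.diameter / 2.0) ** 2
            if self.length is not None:
                inside &= np.abs(p[..., self.axis] - c[self.axis]) <= self.length / 2.0
            return inside
        half = np.array(self.extents) / 2.0
        return np.all(np.abs(p - c) <= half, axis=-1)

    def mask_on(self, geometry: Geometry) -> np.ndarray:
        return self.contains(geometry.voxel_centers())


@dataclass
class Phase4DSet:
    """Ordered respiratory-phase-sorted image set (10 phases, shared geometry).

    ``reference_index`` marks the end-of-inhale phase used as the common frame
    for dose accumulation.
    """

    phases: list[ScalarGrid]
    reference_index: int = 0
    n_expected: int = 10

    def __post_init__(self):
        if len(self.phases) != self.n_expected:
            raise ValueError(
                f"expected {self.n_expected} phases, got {len(self.phases)}"
            )
        g0 = self.phases[0].geometry
        for i, ph in enumerate(self.phases):
            if ph.geometry != g0:
                raise ValueError(f"phase {i} geometry differs from phase 0")
        if not (0 <= self.reference_index < len(self.phases)):
            raise ValueError(f"reference_index {self.reference_index} out of range")

    @property
    def geometry(self) -> Geometry:
        return self.phases[0].geometry

    @property
    def reference(self) -> ScalarGrid:
        return self.phases[self.reference_index]

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, i: int) -> ScalarGrid:
        return self.phases[i]

    def phase_label(self, i: int) -> str:
        return f"{i * 100 // len(self.phases)}%"


# ---------------------------------------------------------------------------
# Resampling primitives
# ---------------------------------------------------------------------------

def resample(grid: ScalarGrid, target_geometry: Geometry, fill: float = 0.0) -> ScalarGrid:
    """Resample a grid onto a target geometry by trilinear interpolation.

    Voxels of the target whose centres fall outside the source grid take the
    caller-supplied ``fill`` value.  Identity resampling is exact (the source
    array is copied bitwise).
    """
    if not np.isfinite(fill):
        raise ValueError("fill value must be finite")
    if target_geometry == grid.geometry:
        return grid.copy()
    pts = target_geometry.voxel_centers()
    vals = grid.sample(pts, fill=fill)
    return ScalarGrid(target_geometry, vals, grid.unit_tag)


def sample_vector(field: VectorField, points_mm: np.ndarray,
                  mode: str = "constant") -> np.ndarray:
    """Componentwise trilinear sample of a displacement field at world points.

    Outside the field's grid the displacement is zero (``mode="constant"``,
    the default) or the edge value (``mode="nearest"``, used by DVF inversion
    where the zero fill would fabricate a discontinuity at the boundary).
    """
    pts = np.asarray(points_mm, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    idx = field.geometry.world_to_index(pts).reshape(-1, 3).T
    out = np.empty(idx.shape[1] * 3).reshape(-1, 3)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            field.displacements[..., c], idx, order=1, mode=mode, cval=0.0,
            prefilter=False,
        )
    return out.reshape(pts.shape)


def warp_scalar(image: ScalarGrid, field: VectorField, fill: float = 0.0,
                mode: str = "constant") -> ScalarGrid:
    """Pull-warp ``image`` onto the field's geometry: out(x) = image(x + d(x))."""
    pts = field.geometry.voxel_centers() + field.displacements
    vals = image.sample(pts, fill=fill, mode=mode)
    return ScalarGrid(field.geometry, vals, image.unit_tag)


def compose_displacement(outer: VectorField, inner: VectorField) -> VectorField:
    """Displacement of the composite map x -> x + d_in(x) -> + d_out(x + d_in(x)).

    Both fields keep the pull convention; the result lives on ``inner``'s grid.
    """
    pts = inner.geometry.voxel_centers()
    moved = pts + inner.displacements
    d_out = sample_vector(outer, moved)
    return VectorField(inner.geometry, inner.displacements + d_out)
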