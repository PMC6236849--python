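"""Paired fiducial landmarks for target-registration-error evaluation.

The on-disk format follows the public lung-landmark benchmark convention:
plain text, one voxel-index triple ``x y z`` per line, with paired files for
the two respiratory phases of a case.  Indices in those files are assumed to
be 1-based and are converted to world millimetres through the image geometry;
pass ``one_based=False`` for 0-based files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import Geometry


@dataclass
class LandmarkSet:
    """Corresponding world-space points (mm) on a fixed and a moving image."""

    points_fixed: np.ndarray   # (N, 3) mm
    points_moving: np.ndarray  # (N, 3) mm
    source_convention: str = "world-mm"  # or "voxel-index"

    def __post_init__(self):
        self.points_fixed = np.atleast_2d(np.asarray(self.points_fixed, dtype=float))
        self.points_moving = np.atleast_2d(np.asarray(self.points_moving, dtype=float))
        if self.points_fixed.shape != self.points_moving.shape:
            raise ValueError(
                f"landmark count mismatch: {self.points_fixed.shape[0]} fixed vs "
                f"{self.points_moving.shape[0]} moving"
            )
        if self.points_fixed.shape[0] < 1 or self.points_fixed.shape[1] != 3:
            raise ValueError("landmark sets need at least one (x, y, z) pair")
        if not (np.all(np.isfinite(self.points_fixed))
                and np.all(np.isfinite(self.points_moving))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.points_fixed.shape[0]

    def pair_distances(self) -> np.ndarray:
        """Euclidean distance (mm) between each fixed/moving pair."""
        return np.linalg.norm(self.points_moving - self.points_fixed, axis=1)


def _read_index_file(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 values, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: unparsable triple {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no landmarks found")
    return np.array(rows, dtype=float)


def read_landmarks(path_fixed: str | Path, path_moving: str | Path,
                   image_geometry: Geometry, one_based: bool = True) -> LandmarkSet:
    """Read a paired pair of voxel-index landmark files into world mm.

    Raises a count-mismatch error naming both counts, and a parse error with
    the offending line number.
    """
    fixed = _read_index_file(Path(path_fixed))
    moving = _read_index_file(Path(path_moving))
    if fixed.shape[0] != moving.shape[0]:
        raise ValueError(
            f"landmark count mismatch: {fixed.shape[0]} in {path_fixed} vs "
            f"{moving.shape[0]} in {path_moving}"
        )
    if one_based:
        fixed = fixed - 1.0
        moving = moving - 1.0
    return LandmarkSet(
        points_fixed=image_geometry.index_to_world(fixed),
        points_moving=image_geometry.index_to_world(moving),
        source_convention="voxel-index",
    )


def write_landmarks(path: str | Path, indices: np.ndarray, one_based: bool = True) -> None:
    """Write integer voxel-index triples, one per line."""
    idx = np.asarray(indices)
    if one_based:
        idx = idx + 1
    with open(path, "w") as fh:
        for row in np.rint(idx).astype(int):
            fh.write(f"{row[0]} {row[1]} {row[2]}\n")
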