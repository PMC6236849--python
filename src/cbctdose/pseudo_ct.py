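"""Pseudo-CT synthesis on the treatment-day geometry.

A pseudo-CT carries planning-CT numbers on the daily (CB)CT geometry so that
dose can be computed on the anatomy of the day: inside the CBCT field of view
each voxel samples the (optionally intensity-overridden) planning CT through
the backward DVF; outside the FOV, where the CBCT carries no information, the
volume is patched with the matching-phase planning CT shifted by the recorded
couch correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import FOVRegion, ROIMask, ScalarGrid, VectorField


@dataclass
class OverrideSpec:
    """Assign a fixed HU value inside an ROI of the planning CT."""

    roi: ROIMask
    value_hu: float

    def __post_init__(self):
        if not np.isfinite(self.value_hu):
            raise ValueError("override HU value must be finite")


def apply_overrides(ct: ScalarGrid, overrides: Sequence[OverrideSpec]) -> ScalarGrid:
    """Apply intensity overrides in list order (later entries win on overlap)."""
    out = ct.copy()
    for ov in overrides:
        if ov.roi.grid.geometry != ct.geometry:
            raise ValueError(
                f"override ROI {ov.roi.name!r} geometry does not match the CT"
            )
        out.values[ov.roi.mask] = ov.value_hu
    return out


def generate_pseudo_ct(ct_plan: ScalarGrid,
                       backward_dvf: VectorField,
                       fov: FOVRegion | None = None,
                       patch_phase_ct: ScalarGrid | None = None,
                       couch_shift_mm: Sequence[float] = (0.0, 0.0, 0.0),
                       fill_hu: float = -1000.0) -> ScalarGrid:
    """Warp planning-CT numbers onto the day geometry of the backward DVF.

    Inside the FOV: ``pseudo(x) = ct_plan(x + b(x))`` (trilinear).  Outside:
    the matching-phase planning CT, rigidly shifted by the couch correction.
    With ``fov=None`` the whole grid is treated as inside.
    """
    day_geometry = backward_dvf.geometry
    pts = day_geometry.voxel_centers()
    warped = ct_plan.sample(pts + backward_dvf.displacements, fill=fill_hu)
    if fov is None:
        return ScalarGrid(day_geometry, warped, "HU")

    inside = fov.mask_on(day_geometry)
    if inside.all():
        return ScalarGrid(day_geometry, warped, "HU")
    if patch_phase_ct is None:
        raise ValueError(
            "FOV does not cover the day grid and no patch image was supplied"
        )
    shift = np.asarray(couch_shift_mm, dtype=float)
    patch = patch_phase_ct.sample(pts - shift, fill=fill_hu)
    return ScalarGrid(day_geometry, np.where(inside, warped, patch), "HU")
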