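"""Stand-in dose engine and the dose warping/accumulation chain.

The engine is an intentionally simple, explicitly non-clinical divergent-beam
model used to exercise the reconstruction pipeline: for every voxel inside a
rectangular aperture the dose is

    weight * exp(-mu * radiological_depth) * (SAD / d)**2

with the radiological depth ray-marched through density (HU + 1000)/1000
(clamped at 0) from the source, and ``d`` the source-voxel distance.  It
reproduces exponential depth dose with inverse-square divergence, which is
all the accumulation and DVH machinery needs.

Dose warping is direct trilinear pull-sampling (no mass/energy-transfer
correction).  4D accumulation sums the ten phase doses warped to the
reference phase with phase weights (uniform by default); course accumulation
warps each daily dose through the replan chain back to the pretreatment CT
and sums.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from .grids import Geometry, ScalarGrid, VectorField, warp_scalar


@dataclass(frozen=True)
class BeamSpec:
    """A rectangular divergent beam aimed at an isocenter."""

    isocenter_mm: tuple[float, float, float]
    direction: tuple[float, float, float]     # source -> isocenter, normalized
    field_size_mm: tuple[float, float] = (40.0, 40.0)  # at the isocenter plane
    weight: float = 1.0
    mu_per_mm: float = 0.005                  # attenuation per unit density
    sad_mm: float = 1000.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("beam direction must be nonzero")
        object.__setattr__(self, "direction", tuple(d / n))
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if min(self.field_size_mm) <= 0:
            raise ValueError("field size must be positive")
        if self.sad_mm <= 0 or self.mu_per_mm <= 0:
            raise ValueError("SAD and mu must be positive")

    @property
    def source_mm(self) -> np.ndarray:
        return np.asarray(self.isocenter_mm) - self.sad_mm * np.asarray(self.direction)


def beam_from_gantry(gantry_deg: float, isocenter_mm: Sequence[float],
                     field_size_mm: Sequence[float] = (40.0, 40.0),
                     weight: float = 1.0, mu_per_mm: float = 0.005,
                     sad_mm: float = 1000.0) -> BeamSpec:
    """Coplanar beam in the axial plane; gantry 0 enters from the anterior."""
    g = np.deg2rad(gantry_deg)
    direction = (np.sin(g), np.cos(g), 0.0)  # +y = posterior
    return BeamSpec(tuple(isocenter_mm), direction, tuple(field_size_mm),
                    weight, mu_per_mm, sad_mm)


@dataclass
class DoseGrid:
    """A Gy-valued grid with provenance (phase/daily/cumulative dose)."""

    grid: ScalarGrid
    provenance: str = "daily"  # {phase, daily, cumulative, plan}
    fraction_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if self.grid.unit_tag != "Gy":
            raise ValueError("dose grids must carry unit_tag 'Gy'")
        if np.any(self.grid.values < 0):
            raise ValueError("dose must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def geometry(self) -> Geometry:
        return self.grid.geometry

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.grid.with_values(self.grid.values * factor),
                        self.provenance, self.fraction_ids)

    def integral_dose(self) -> float:
        """Sum of dose times voxel volume (Gy * mm^3)."""
        return float(self.values.sum()) * self.geometry.voxel_volume_mm3


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    w = np.cross(direction, u)
    return u, w


def _ray_box_entry(src: np.ndarray, vec: np.ndarray, lo: np.ndarray,
                   hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slab-method intersection parameters of rays src + t*vec with a box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - src) / vec
        t_hi = (hi - src) / vec
    t1 = np.minimum(t_lo, t_hi)
    t2 = np.maximum(t_lo, t_hi)
    t1 = np.where(np.isfinite(t1), t1, -np.inf)
    t2 = np.where(np.isfinite(t2), t2, np.inf)
    return np.max(t1, axis=-1), np.min(t2, axis=-1)


def compute_dose(image: ScalarGrid, beams: Sequence[BeamSpec],
                 step_mm: float = 1.0, provenance: str = "daily") -> DoseGrid:
    """Ray-marched exponential-attenuation dose of a set of beams."""
    if not beams:
        raise ValueError("at least one beam is required")
    geom = image.geometry
    lo, hi = geom.extent()
    lo_f = lo - np.array(geom.spacing) / 2.0
    hi_f = hi + np.array(geom.spacing) / 2.0
    density = np.maximum((image.values + 1000.0) / 1000.0, 0.0)
    density_grid = ScalarGrid(geom, density, "unitless")
    pts = geom.voxel_centers().reshape(-1, 3)
    dose = np.zeros(len(pts))

    for beam in beams:
        src = beam.source_mm
        if np.all(src >= lo_f) and np.all(src <= hi_f):
            raise ValueError("beam source lies inside the image volume")
        if beam.weight == 0.0:
            continue
        dirv = np.asarray(beam.direction)
        u, w = _perp_basis(dirv)
        v = pts - src
        d_axis = v @ dirv
        front = d_axis > 1e-6
        proj = beam.sad_mm / np.where(front, d_axis, 1.0)
        in_ap = (front
                 & (np.abs((v @ u) * proj) <= beam.field_size_mm[0] / 2.0)
                 & (np.abs((v @ w) * proj) <= beam.field_size_mm[1] / 2.0))
        if not in_ap.any():
            continue
        vv = v[in_ap]
        dist = np.linalg.norm(vv, axis=1)
        t0, t1 = _ray_box_entry(src, vv, lo_f, hi_f)
        t0 = np.clip(t0, 0.0, 1.0)
        t1 = np.clip(t1, 0.0, 1.0)
        span = np.maximum(t1 - t0, 0.0)
        n_steps = max(4, int(np.ceil(span.max() * dist.max() / step_mm)))
        frac = (np.arange(n_steps) + 0.5) / n_steps
        # sample points: src + (t0 + span*frac) * vv, shape (M, K, 3)
        tt = t0[:, None] + span[:, None] * frac[None, :]
        samples = src[None, None, :] + tt[..., None] * vv[:, None, :]
        dens = density_grid.sample(samples, fill=0.0)
        radpath = dens.sum(axis=1) * span * dist / n_steps
        contrib = beam.weight * np.exp(-beam.mu_per_mm * radpath)
        contrib *= (beam.sad_mm / np.linalg.norm(vv, axis=1)) ** 2
        dose[in_ap] += contrib

    grid = ScalarGrid(geom, dose.reshape(geom.size), "Gy")
    return DoseGrid(grid, provenance=provenance)


def warp_dose(dose: DoseGrid, dvf: VectorField) -> DoseGrid:
    """Pull-warp a dose onto the DVF's geometry; outside the source -> 0 Gy."""
    if dvf.geometry == dose.geometry and not dvf.displacements.any():
        return DoseGrid(dose.grid.copy(), dose.provenance, dose.fraction_ids)
    warped = warp_scalar(dose.grid, dvf, fill=0.0)
    warped.values[warped.values < 0] = 0.0
    return DoseGrid(warped, dose.provenance, dose.fraction_ids)


def accumulate_4d(phase_doses: Sequence[DoseGrid],
                  phase_dvfs: Sequence[VectorField | None],
                  weights: Sequence[float] | None = None) -> DoseGrid:
    """Phase-weighted sum of phase doses warped to the reference phase.

    ``phase_dvfs[p]`` lives on the reference geometry and maps it into phase
    p; ``None`` means the identity (the reference phase itself).  Weights
    default to uniform 1/10 and must sum to 1.
    """
    n = len(phase_doses)
    if n != 10:
        raise ValueError(f"expected 10 phase doses, got {n}")
    if len(phase_dvfs) != n:
        raise ValueError("need one DVF (or None) per phase")
    if weights is None:
        weights = [1.0 / n] * n
    if abs(sum(weights) - 1.0) > 1e-6:
        raise ValueError(f"phase weights must sum to 1, got {sum(weights)}")
    total = None
    geometry = None
    for d, f, w in zip(phase_doses, phase_dvfs, weights):
        warped = d if f is None else warp_dose(d, f)
        if total is None:
            geometry = warped.geometry
            total = w * warped.values
        else:
            if warped.geometry != geometry:
                raise ValueError("warped phase doses must share the reference geometry")
            total = total + w * warped.values
    return DoseGrid(ScalarGrid(geometry, total, "Gy"), provenance="daily")


@dataclass
class PlanChain:
    """Ordered planning CTs with the DVFs linking each replan to its predecessor.

    ``plans`` holds (plan_id, start_date) with strictly increasing dates; the
    first entry is the pretreatment CT.  ``links[i]`` (i >= 1) lives on plan
    i-1's geometry and maps it into plan i's frame, so warping a dose from
    plan i onto plan i-1 applies ``links[i]`` directly.
    """

    plans: list[tuple[str, datetime.date]]
    links: dict[int, VectorField] = dc_field(default_factory=dict)

    def __post_init__(self):
        if not self.plans:
            raise ValueError("plan chain needs at least one plan")
        dates = [d for _, d in self.plans]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("plan start dates must be strictly increasing")
        for i in range(1, len(self.plans)):
            if i not in self.links:
                raise ValueError(f"missing DVF link for replan segment {i}")

    def segment_for(self, date: datetime.date) -> int:
        if date < self.plans[0][1]:
            raise ValueError(
                f"fraction date {date} precedes the first plan {self.plans[0][1]}"
            )
        seg = 0
        for i, (_, start) in enumerate(self.plans):
            if date >= start:
                seg = i
        return seg

    def warp_to_pretreatment(self, dose: DoseGrid, segment: int) -> DoseGrid:
        out = dose
        for i in range(segment, 0, -1):
            out = warp_dose(out, self.links[i])
        return out


def accumulate_course(daily_doses: Sequence[tuple[datetime.date, DoseGrid]],
                      chain: PlanChain) -> DoseGrid:
    """Sum daily doses on the pretreatment CT, warped through the replan chain."""
    if not daily_doses:
        raise ValueError("no daily doses to accumulate")
    total = None
    geometry = None
    ids: list[int] = []
    for k, (date, dose) in enumerate(daily_doses):
        seg = chain.segment_for(date)
        warped = chain.warp_to_pretreatment(dose, seg)
        if total is None:
            geometry = warped.geometry
            total = warped.values.copy()
        else:
            total += warped.values
        ids.extend(dose.fraction_ids or (k + 1,))
    return DoseGrid(ScalarGrid(geometry, total, "Gy"),
                    provenance="cumulative", fraction_ids=tuple(ids))
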