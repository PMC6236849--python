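"""Synthetic 4D thorax phantom with exact ground-truth deformations.

The phantom is an analytic HU function of continuous world coordinates:
a soft-tissue body ellipsoid containing two lung ellipsoids (truncated
inferiorly by a flat diaphragm), a spinal-cord cylinder, a spherical tumor
inside one lung and vessel-like spheroids that double as landmarks.  Tissue
boundaries are blended over a few millimetres so that trilinear resampling of
the voxelized volumes is well conditioned.

Breathing is a 10-phase cosine law with phase 0 = end of inhale (the reference
phase): a material point at reference position ``x`` sits at ``x + s_p(x)`` in
phase ``p``, where ``s_p`` is a superior-inferior field equal to the diaphragm
amplitude below the diaphragm, tapering linearly to zero at the lung apex,
with a localized blend that carries the tumor by its own amplitude.  Phase
images are produced by evaluating the analytic anatomy at the numerically
inverted motion map, which makes ``s_p`` the *exact* pull-convention
displacement field that warps phase ``p`` back onto the reference phase.
Ground-truth fields are therefore emitted analytically, never by
registration.

CBCT-like degradation applies a global intensity scale/offset, additive
Gaussian noise, cylindrical field-of-view truncation (air fill outside) and an
optional rigid setup shift; everything is seeded and bitwise reproducible.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .grids import (
    FOVRegion,
    Geometry,
    Phase4DSet,
    ROIMask,
    ScalarGrid,
    VectorField,
    mask_from_bool,
    resample,
)
from .landmarks import LandmarkSet

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomy, motion and sampling parameters of the synthetic thorax."""

    size: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_half_axes_mm: tuple[float, float, float] = (70.0, 55.0, 400.0)
    soft_tissue_hu: float = 40.0
    lung_hu: float = -750.0
    lung_half_axes_mm: tuple[float, float, float] = (24.0, 30.0, 55.0)
    lung_center_x_mm: float = 38.0
    lung_center_z_mm: float = 0.0  # low enough that the diaphragm cut is wide and flat
    diaphragm_rest_mm: float = -40.0
    cord_center_y_mm: float = 40.0
    cord_radius_mm: float = 5.0
    cord_hu: float = 100.0
    tumor_center_mm: tuple[float, float, float] = (38.0, 0.0, -10.0)
    tumor_radius_mm: float = 10.0
    tumor_hu: float = 60.0
    vessel_hu: float = -100.0
    vessel_radius_mm: float = 4.0
    n_vessels_per_lung: int = 25
    diaphragm_amplitude_mm: float = 10.0  # A_d
    tumor_amplitude_mm: float = 8.0       # A_t
    n_phases: int = 10
    edge_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_phases != 10:
            raise ValueError("the phantom models 10 respiratory phases")
        if self.diaphragm_amplitude_mm < 0 or self.tumor_amplitude_mm < 0:
            raise ValueError("motion amplitudes must be >= 0")

    @property
    def geometry(self) -> Geometry:
        origin = tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.size, self.spacing_mm)
        )
        return Geometry(origin=origin, spacing=self.spacing_mm, size=self.size)

    @property
    def lung_apex_mm(self) -> float:
        return self.lung_center_z_mm + self.lung_half_axes_mm[2]

    def phase_amplitude(self, p: int, full_mm: float) -> float:
        """Cosine phase law: 0 at end of inhale, ``full_mm`` at end of exhale."""
        return full_mm * (1.0 - np.cos(2.0 * np.pi * p / self.n_phases)) / 2.0

    def tumor_center_at_phase(self, p: int) -> np.ndarray:
        c = np.array(self.tumor_center_mm)
        c[2] += self.phase_amplitude(p, self.tumor_amplitude_mm)
        return c


@dataclass(frozen=True)
class CBCTDegradeSpec:
    """CBCT-like image degradation: intensity map, noise, FOV, setup shift."""

    noise_std_hu: float = 20.0
    intensity_scale: float = 0.95
    intensity_offset_hu: float = -10.0
    fov: FOVRegion | None = None
    setup_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_std_hu < 0:
            raise ValueError("noise std must be >= 0")


@dataclass
class Phantom4D:
    """A generated 4D phantom with ground truth."""

    spec: PhantomSpec
    ct4d: Phase4DSet
    gt_fields: list[VectorField]        # phase p -> reference, on reference grid
    rois: dict[str, ROIMask]            # on the reference phase
    gtv_phase_masks: list[ROIMask]      # tumor mask per phase
    gtv_volumes_cc: list[float]         # soft (sub-voxel) tumor volume per phase
    landmarks: list[LandmarkSet]        # reference vs phase p, per phase
    vessel_centers_mm: np.ndarray


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _edge_weight(signed_dist_mm: np.ndarray, edge_mm: float) -> np.ndarray:
    """1 well inside (positive distance), 0 well outside, smooth over edge_mm."""
    return _smoothstep((signed_dist_mm + edge_mm / 2.0) / edge_mm)


def _ellipsoid_dist(points: np.ndarray, center: Sequence[float],
                    half_axes: Sequence[float]) -> np.ndarray:
    """Approximate signed distance (mm, positive inside) to an ellipsoid."""
    c = np.asarray(center, dtype=float)
    ax = np.asarray(half_axes, dtype=float)
    rho = np.sqrt(np.sum(((points - c) / ax) ** 2, axis=-1))
    return (1.0 - rho) * ax.min()


class _Anatomy:
    """Evaluates the reference-phase HU and tissue weights at world points."""

    def __init__(self, spec: PhantomSpec, vessel_centers: np.ndarray):
        self.spec = spec
        self.vessels = vessel_centers
        self.tree = cKDTree(vessel_centers) if len(vessel_centers) else None

    def lung_weight(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        w = np.zeros(p.shape[:-1])
        for sx in (+1.0, -1.0):
            center = (sx * s.lung_center_x_mm, 0.0, s.lung_center_z_mm)
            d = _ellipsoid_dist(p, center, s.lung_half_axes_mm)
            # flat diaphragm: lung truncated below diaphragm_rest
            d = np.minimum(d, p[..., 2] - s.diaphragm_rest_mm)
            w = np.maximum(w, _edge_weight(d, s.edge_mm))
        return w

    def body_weight(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        d = _ellipsoid_dist(p, (0.0, 0.0, 0.0), s.body_half_axes_mm)
        return _edge_weight(d, s.edge_mm)

    def cord_weight(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        r = np.sqrt(p[..., 0] ** 2 + (p[..., 1] - s.cord_center_y_mm) ** 2)
        return _edge_weight(s.cord_radius_mm - r, s.edge_mm)

    def tumor_weight(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        r = np.linalg.norm(p - np.array(s.tumor_center_mm), axis=-1)
        return _edge_weight(s.tumor_radius_mm - r, s.edge_mm)

    def vessel_weight(self, p: np.ndarray) -> np.ndarray:
        if self.tree is None:
            return np.zeros(p.shape[:-1])
        flat = p.reshape(-1, 3)
        dist, _ = self.tree.query(flat, k=1)
        w = _edge_weight(self.spec.vessel_radius_mm - dist, self.spec.edge_mm)
        return w.reshape(p.shape[:-1])

    def hu(self, points: np.ndarray) -> np.ndarray:
        s = self.spec
        wb = self.body_weight(points)
        wl = self.lung_weight(points)
        wc = self.cord_weight(points)
        wt = self.tumor_weight(points)
        wv = self.vessel_weight(points)
        hu = AIR_HU + wb * (s.soft_tissue_hu - AIR_HU)
        hu = hu + wb * wl * (s.lung_hu - s.soft_tissue_hu)
        hu = hu + wb * wl * wv * (s.vessel_hu - s.lung_hu)
        hu = hu + wb * wt * (s.tumor_hu - hu)
        hu = hu + wb * wc * (s.cord_hu - hu)
        return hu


def _taper(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """1 below the diaphragm, linear to 0 at the lung apex."""
    span = spec.lung_apex_mm - spec.diaphragm_rest_mm
    t = (spec.lung_apex_mm - z) / span
    return np.clip(t, 0.0, 1.0)


def _tumor_bump(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """1 on the tumor (plus margin), smoothly 0 outside a carrier radius."""
    r = np.linalg.norm(points - np.array(spec.tumor_center_mm), axis=-1)
    inner = spec.tumor_radius_mm + 4.0
    outer = spec.tumor_radius_mm + 16.0
    return 1.0 - _smoothstep((r - inner) / (outer - inner))


def motion_displacement(spec: PhantomSpec, phase: int, points: np.ndarray) -> np.ndarray:
    """Analytic reference->phase displacement s_p at reference points (mm)."""
    a_d = spec.phase_amplitude(phase, spec.diaphragm_amplitude_mm)
    a_t = spec.phase_amplitude(phase, spec.tumor_amplitude_mm)
    sz = a_d * _taper(spec, points[..., 2])
    b = _tumor_bump(spec, points)
    sz = (1.0 - b) * sz + b * a_t
    disp = np.zeros(points.shape)
    disp[..., 2] = sz
    return disp


def _invert_motion(spec: PhantomSpec, phase: int, targets: np.ndarray,
                   n_iter: int = 12, tol: float = 1e-8) -> np.ndarray:
    """Solve x + s_p(x) = y per point by fixed-point iteration (contractive)."""
    x = targets.copy()
    for _ in range(n_iter):
        x_new = targets - motion_displacement(spec, phase, x)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x


def _place_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded vessel/landmark spheroid centres well inside each lung."""
    centers: list[np.ndarray] = []
    half = np.array(spec.lung_half_axes_mm)
    keepout = (spec.tumor_radius_mm + spec.tumor_amplitude_mm
               + spec.vessel_radius_mm + 8.0)
    min_sep = 2.5 * spec.vessel_radius_mm
    for sx in (+1.0, -1.0):
        lc = np.array([sx * spec.lung_center_x_mm, 0.0, spec.lung_center_z_mm])
        placed = 0
        attempts = 0
        while placed < spec.n_vessels_per_lung and attempts < 4000:
            attempts += 1
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u ** 2) > 1.0:
                continue
            c = lc + u * (half - spec.vessel_radius_mm - spec.edge_mm - 2.0)
            # keep above the moving diaphragm at all phases
            if c[2] - spec.vessel_radius_mm < spec.diaphragm_rest_mm + spec.edge_mm:
                continue
            if np.linalg.norm(c - np.array(spec.tumor_center_mm)) < keepout:
                continue
            if centers and np.min(
                np.linalg.norm(np.array(centers) - c, axis=1)
            ) < min_sep:
                continue
            centers.append(c)
            placed += 1
    return np.array(centers) if centers else np.zeros((0, 3))


def _check_tumor_in_lung(spec: PhantomSpec) -> None:
    half = np.array(spec.lung_half_axes_mm)
    for p in range(spec.n_phases):
        c = spec.tumor_center_at_phase(p)
        lc = np.array([spec.lung_center_x_mm, 0.0, spec.lung_center_z_mm])
        rho = np.sqrt(np.sum(((c - lc) / half) ** 2))
        if rho + spec.tumor_radius_mm / half.min() > 1.0:
            raise ValueError(
                f"tumor leaves the lung at phase {p} "
                f"(center {tuple(np.round(c, 1))}, radius {spec.tumor_radius_mm} mm)"
            )
        if c[2] - spec.tumor_radius_mm < spec.diaphragm_rest_mm:
            raise ValueError(f"tumor crosses the diaphragm at phase {p}")


def make_4dct(spec: PhantomSpec) -> Phantom4D:
    """Generate the 10-phase CT, exact DVFs, ROI masks and landmark pairs."""
    _check_tumor_in_lung(spec)
    rng = np.random.default_rng(spec.seed)
    vessels = _place_vessels(spec, rng)
    anatomy = _Anatomy(spec, vessels)
    geom = spec.geometry
    centers = geom.voxel_centers()

    phases: list[ScalarGrid] = []
    gt_fields: list[VectorField] = []
    gtv_masks: list[ROIMask] = []
    gtv_vols: list[float] = []
    landmark_sets: list[LandmarkSet] = []
    voxvol = geom.voxel_volume_mm3

    for p in range(spec.n_phases):
        if p == 0:
            pre = centers
        else:
            pre = _invert_motion(spec, p, centers.reshape(-1, 3)).reshape(centers.shape)
        hu = anatomy.hu(pre)
        phases.append(ScalarGrid(geom, hu, "HU"))
        gt_fields.append(VectorField(geom, motion_displacement(spec, p, centers)))

        c_t = spec.tumor_center_at_phase(p)
        r = np.linalg.norm(centers - c_t, axis=-1)
        gtv_masks.append(mask_from_bool(geom, r <= spec.tumor_radius_mm,
                                        f"GTV_phase{p}", "target"))
        soft = _edge_weight(spec.tumor_radius_mm - r, spec.edge_mm)
        gtv_vols.append(float(soft.sum()) * voxvol / 1000.0)

        if len(vessels):
            moving = vessels + motion_displacement(spec, p, vessels)
            landmark_sets.append(LandmarkSet(vessels.copy(), moving))
        else:
            c0 = np.array(spec.tumor_center_mm)[None, :]
            landmark_sets.append(LandmarkSet(c0, c0 + motion_displacement(spec, p, c0)))

    rois = {
        "BODY": mask_from_bool(geom, anatomy.body_weight(centers) > 0.5,
                               "BODY", "external"),
        "LUNGS": mask_from_bool(geom, anatomy.lung_weight(centers) > 0.5,
                                "LUNGS", "OAR"),
        "CORD": mask_from_bool(
            geom,
            (anatomy.cord_weight(centers) > 0.5) & (anatomy.body_weight(centers) > 0.5),
            "CORD", "OAR"),
        "GTV": gtv_masks[0],
    }

    return Phantom4D(
        spec=spec,
        ct4d=Phase4DSet(phases, reference_index=0, n_expected=spec.n_phases),
        gt_fields=gt_fields,
        rois=rois,
        gtv_phase_masks=gtv_masks,
        gtv_volumes_cc=gtv_vols,
        landmarks=landmark_sets,
        vessel_centers_mm=vessels,
    )


def degrade_to_cbct(ct4d: Phase4DSet, spec: CBCTDegradeSpec) -> Phase4DSet:
    """Degrade a 4D CT into a CBCT-like set (scale/offset, noise, FOV, shift)."""
    rng = np.random.default_rng(spec.seed)
    out: list[ScalarGrid] = []
    shift = np.asarray(spec.setup_shift_mm, dtype=float)
    for ph in ct4d:
        vals = ph.values
        if np.any(shift != 0.0):
            # setup error: the patient appears displaced by +shift on the scan
            pts = ph.geometry.voxel_centers() - shift
            vals = ph.sample(pts, fill=AIR_HU)
        if spec.intensity_scale != 1.0 or spec.intensity_offset_hu != 0.0:
            vals = vals * spec.intensity_scale + spec.intensity_offset_hu
        if spec.noise_std_hu > 0.0:
            vals = vals + rng.normal(0.0, spec.noise_std_hu, size=vals.shape)
        if spec.fov is not None:
            inside = spec.fov.mask_on(ph.geometry)
            vals = np.where(inside, vals, AIR_HU)
        if vals is ph.values:
            vals = vals.copy()
        out.append(ScalarGrid(ph.geometry, vals, "HU"))
    return Phase4DSet(out, reference_index=ct4d.reference_index,
                      n_expected=len(ct4d.phases))


@dataclass
class FractionFixture:
    index: int
    date: datetime.date
    truth: Phantom4D            # noiseless anatomy of the day
    cbct4d: Phase4DSet          # degraded daily images
    degrade: CBCTDegradeSpec


@dataclass
class CourseFixture:
    plan: Phantom4D
    fractions: list[FractionFixture]


def make_course(spec: PhantomSpec,
                degrade: CBCTDegradeSpec,
                n_fractions: int,
                shrink_per_fraction: float = 0.0,
                drift_per_fraction_mm: Sequence[float] = (0.0, 0.0, 0.0),
                start_date: datetime.date = datetime.date(2024, 1, 8),
                ) -> CourseFixture:
    """A treatment course: per-fraction tumor shrinkage and/or setup drift.

    ``shrink_per_fraction`` is the fractional *volume* lost per fraction, so
    the fraction-f tumor volume is ``(1 - s)**(f-1)`` times the planning one.
    Setup drift accumulates linearly: fraction f is shifted by
    ``(f - 1) * drift_per_fraction_mm``.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if not (0.0 <= shrink_per_fraction < 1.0):
        raise ValueError("shrink_per_fraction must be in [0, 1)")
    plan = make_4dct(spec)
    drift = np.asarray(drift_per_fraction_mm, dtype=float)
    fractions: list[FractionFixture] = []
    for f in range(1, n_fractions + 1):
        radius = spec.tumor_radius_mm * (1.0 - shrink_per_fraction) ** ((f - 1) / 3.0)
        day_spec = replace(spec, tumor_radius_mm=radius)
        truth = make_4dct(day_spec)
        frac_degrade = replace(
            degrade,
            setup_shift_mm=tuple(drift * (f - 1)),
            seed=degrade.seed + f,
        )
        cbct = degrade_to_cbct(truth.ct4d, frac_degrade)
        fractions.append(FractionFixture(
            index=f,
            date=start_date + datetime.timedelta(days=f - 1),
            truth=truth,
            cbct4d=cbct,
            degrade=frac_degrade,
        ))
    return CourseFixture(plan=plan, fractions=fractions)
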