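"""Deformable registration and displacement-field utilities.

The registration follows a two-stage architecture: an exhaustive integer-voxel
block-matching pass at the coarsest pyramid level gives a robust initial
alignment, and a dense, demons-style refinement driven by locally normalized
intensities (a local-correlation-coefficient surrogate, robust to the global
intensity scaling between CT and CBCT) polishes the field, with Gaussian
fluid (update) and diffusion (total field) regularization over a
multi-resolution pyramid.

Conventions: the planning CT is the fixed/reference image and the CBCT the
moving image.  The returned field lives on the fixed geometry and maps a fixed
point ``x`` to ``x + d(x)`` in the moving image (pull convention), so warping
the moving image onto the fixed grid uses the field directly.

Also here: cropping the CT to the CBCT field of view (masking to air, with a
crop record), expanding a small-FOV DVF to the full CT FOV by smoothing over
the boundary, and fixed-point DVF inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import (
    FOVRegion,
    Geometry,
    ScalarGrid,
    VectorField,
    resample,
    sample_vector,
    warp_scalar,
)
from .phantom import AIR_HU


# ---------------------------------------------------------------------------
# Local correlation coefficient
# ---------------------------------------------------------------------------

def lcc(window_a: np.ndarray, window_b: np.ndarray) -> float:
    """Pearson correlation of two intensity windows; 0 if either is constant."""
    a = np.asarray(window_a, dtype=float).ravel()
    b = np.asarray(window_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"window shapes differ: {window_a.shape} vs {window_b.shape}")
    if a.size < 2:
        raise ValueError("windows need at least 2 voxels")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# FOV cropping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropRecord:
    """What was masked away, so a DVF can later be expanded back."""

    fov: FOVRegion
    geometry: Geometry
    fill_hu: float = AIR_HU


def crop_to_fov(ct: ScalarGrid, fov: FOVRegion,
                fill: float = AIR_HU) -> tuple[ScalarGrid, CropRecord]:
    """Mask CT voxels outside the CBCT field of view to air.

    The grid geometry is unchanged (mask-crop), which keeps DVFs from the
    cropped registration on the full lattice; the crop record carries the FOV
    so ``expand_dvf`` can smooth the field across the boundary afterwards.
    """
    inside = fov.mask_on(ct.geometry)
    if not inside.any():
        raise ValueError("FOV does not intersect the CT volume")
    vals = np.where(inside, ct.values, fill)
    return ScalarGrid(ct.geometry, vals, ct.unit_tag), CropRecord(fov, ct.geometry, fill)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationParams:
    """Two-stage registration parameters (all lengths in mm unless noted)."""

    block_size_mm: float = 16.0
    search_radius_mm: float = 20.0
    lcc_radius_vox: int = 3          # local-normalization window radius, voxels
    sigma_fluid_mm: float = 2.0      # smoothing of each update
    sigma_diffusion_mm: float = 2.5  # smoothing of the total field
    pyramid_levels: int = 3
    max_iterations: tuple[int, ...] = (15, 25, 35)  # coarse -> fine
    convergence_tol_mm: float = 0.02  # mean update magnitude
    step_scale: float = 0.8          # demons force normalization (x mean spacing)
    presmooth_vox: float = 1.0       # Gaussian presmoothing of each level (voxels)
    norm_floor_hu: float = 5.0       # local-normalization variance floor
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if len(self.max_iterations) < self.pyramid_levels:
            raise ValueError("need one iteration count per pyramid level")
        for name in ("block_size_mm", "search_radius_mm", "sigma_fluid_mm",
                     "sigma_diffusion_mm", "convergence_tol_mm", "step_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


FAST_PARAMS = RegistrationParams(
    pyramid_levels=2, max_iterations=(20, 12), lcc_radius_vox=2
)


@dataclass
class RegistrationResult:
    field: VectorField
    objective: list[list[float]]  # per level, per iteration: mean local correlation
    converged: bool
    diverged: bool = False


def _downsample_geometry(geom: Geometry, factor: int) -> Geometry:
    size = tuple(max(2, int(np.ceil(n / factor))) for n in geom.size)
    spacing = tuple(s * factor for s in geom.spacing)
    return Geometry(origin=geom.origin, spacing=spacing, size=size)


def _downsample(grid: ScalarGrid, factor: int, fill: float) -> ScalarGrid:
    if factor == 1:
        return grid
    sigma_vox = [factor / 2.0] * 3
    sm = ndimage.gaussian_filter(grid.values, sigma=sigma_vox, mode="nearest")
    return resample(ScalarGrid(grid.geometry, sm, grid.unit_tag),
                    _downsample_geometry(grid.geometry, factor), fill=fill)


def _resample_field(field: VectorField, target: Geometry) -> VectorField:
    """Upsample a displacement field (nearest-edge extension, per component)."""
    idx = target.voxel_centers()
    coords = field.geometry.world_to_index(idx).reshape(-1, 3).T
    out = np.empty(tuple(target.size) + (3,))
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            field.displacements[..., c], coords, order=1, mode="nearest",
            prefilter=False,
        ).reshape(target.size)
    return VectorField(target, out)


def _local_normalize(vals: np.ndarray, sigma_vox: float,
                     floor_hu: float = 5.0) -> np.ndarray:
    # smooth variance floor: flat regions fade to zero instead of amplifying
    # interpolation residue into unit-scale pseudo-structure
    mean = ndimage.gaussian_filter(vals, sigma_vox, mode="nearest")
    var = ndimage.gaussian_filter(vals * vals, sigma_vox, mode="nearest") - mean ** 2
    return (vals - mean) / np.sqrt(np.maximum(var, 0.0) + floor_hu ** 2)


def _block_sums(arr: np.ndarray, b: tuple[int, int, int]) -> np.ndarray:
    nb = tuple(n // bb for n, bb in zip(arr.shape, b))
    trimmed = arr[: nb[0] * b[0], : nb[1] * b[1], : nb[2] * b[2]]
    return trimmed.reshape(nb[0], b[0], nb[1], b[1], nb[2], b[2]).sum(axis=(1, 3, 5))


def _block_match(fixed: np.ndarray, moving: np.ndarray, geom: Geometry,
                 params: RegistrationParams,
                 radius_mm: float | None = None,
                 moving_valid: np.ndarray | None = None) -> VectorField:
    """Exhaustive integer-voxel block search maximizing per-block correlation.

    Ties are broken toward the smaller displacement magnitude; block
    displacements are blended into a dense field by normalized Gaussian
    splatting with the winning correlation as weight.
    """
    spacing = np.array(geom.spacing)
    b = tuple(int(np.clip(round(params.block_size_mm / s), 2, n))
              for s, n in zip(spacing, fixed.shape))
    radius = params.search_radius_mm if radius_mm is None else radius_mm
    r = tuple(max(1, int(round(radius / s))) for s in spacing)
    nb = tuple(n // bb for n, bb in zip(fixed.shape, b))
    if min(nb) < 1:
        return VectorField.zeros(geom)

    nblk = b[0] * b[1] * b[2]
    f_sum = _block_sums(fixed, b)
    f_sq = _block_sums(fixed * fixed, b)
    f_var = f_sq - f_sum ** 2 / nblk
    # blocks need real structure (std > ~10 HU) to vote
    valid = f_var > 100.0 * nblk

    pad = np.pad(moving, [(rr, rr) for rr in r], mode="edge")
    cube_shape = tuple(2 * rr + 1 for rr in r)
    corr_cube = np.zeros(cube_shape + nb)
    for ox in range(-r[0], r[0] + 1):
        for oy in range(-r[1], r[1] + 1):
            for oz in range(-r[2], r[2] + 1):
                sl = tuple(slice(rr + oo, rr + oo + n)
                           for rr, oo, n in zip(r, (ox, oy, oz), fixed.shape))
                m = pad[sl]
                m_sum = _block_sums(m, b)
                m_sq = _block_sums(m * m, b)
                cross = _block_sums(fixed * m, b)
                m_var = m_sq - m_sum ** 2 / nblk
                cov = cross - f_sum * m_sum / nblk
                denom = np.sqrt(np.maximum(f_var * m_var, 1e-12))
                corr = np.where((f_var > 1e-6 * nblk) & (m_var > 1e-6 * nblk),
                                np.clip(cov / denom, -1.0, 1.0), 0.0)
                corr_cube[ox + r[0], oy + r[1], oz + r[2]] = corr

    # argmax with a minute magnitude penalty: ties go to the smaller offset
    off_axes = [np.arange(-rr, rr + 1) * s for rr, s in zip(r, spacing)]
    mag2 = (off_axes[0][:, None, None] ** 2 + off_axes[1][None, :, None] ** 2
            + off_axes[2][None, None, :] ** 2)
    score = corr_cube - 1e-9 * mag2[..., None, None, None]
    flat = score.reshape(-1, *nb)
    best_idx = np.argmax(flat, axis=0)
    ii, jj, kk = np.unravel_index(best_idx, cube_shape)
    bi = np.indices(nb)
    best_corr = corr_cube[ii, jj, kk, bi[0], bi[1], bi[2]]

    # parabolic sub-voxel refinement of the correlation peak, per axis
    best_off = np.empty(nb + (3,))
    cube_idx = (ii, jj, kk)
    for a in range(3):
        center = cube_idx[a]
        lo = np.maximum(center - 1, 0)
        hi = np.minimum(center + 1, cube_shape[a] - 1)
        pick = list(cube_idx)
        pick[a] = lo
        c_lo = corr_cube[pick[0], pick[1], pick[2], bi[0], bi[1], bi[2]]
        pick[a] = hi
        c_hi = corr_cube[pick[0], pick[1], pick[2], bi[0], bi[1], bi[2]]
        curv = c_lo - 2.0 * best_corr + c_hi
        # a perfect-correlation peak is already exact; shifting it by the
        # asymmetry of its neighbors would only distort the identity
        refinable = (lo < center) & (hi > center) & (curv < -1e-12) \
            & (best_corr < 1.0 - 1e-9)
        delta = np.where(refinable,
                         0.5 * (c_lo - c_hi) / np.where(curv < -1e-12, curv, -1.0),
                         0.0)
        delta = np.clip(delta, -0.5, 0.5)
        best_off[..., a] = (center - r[a] + delta) * spacing[a]

    # low-correlation winners are noise votes; drop them
    weight = np.where(valid & (best_corr > 0.4), np.maximum(best_corr, 0.0), 0.0)
    if moving_valid is not None:
        # blocks fed by data from outside the moving volume cannot vote
        frac = _block_sums(moving_valid.astype(float), b) / nblk
        weight = np.where(frac > 0.99, weight, 0.0)
    if not np.any(weight > 0):
        return VectorField.zeros(geom)

    # splat block displacements onto the voxel lattice, then normalized blur
    w_full = np.zeros(fixed.shape)
    d_full = np.zeros(fixed.shape + (3,))
    cx = [(np.arange(nb[a]) * b[a] + b[a] // 2).astype(int) for a in range(3)]
    ix, iy, iz = np.meshgrid(*cx, indexing="ij")
    w_full[ix, iy, iz] = weight
    for c in range(3):
        d_full[ix, iy, iz, c] = weight * best_off[..., c]
    sigma = max(bb for bb in b)
    w_s = ndimage.gaussian_filter(w_full, sigma, mode="constant")
    disp = np.zeros(fixed.shape + (3,))
    for c in range(3):
        d_s = ndimage.gaussian_filter(d_full[..., c], sigma, mode="constant")
        disp[..., c] = np.where(w_s > 1e-9, d_s / np.maximum(w_s, 1e-9), 0.0)
    return VectorField(geom, disp)


def _geometries_overlap(a: Geometry, b: Geometry) -> bool:
    alo, ahi = a.extent()
    blo, bhi = b.extent()
    return bool(np.all(ahi >= blo) and np.all(bhi >= alo))


def register(fixed: ScalarGrid, moving: ScalarGrid,
             params: RegistrationParams = RegistrationParams(),
             fill: float = AIR_HU) -> RegistrationResult:
    """Two-stage deformable registration of ``moving`` onto ``fixed``.

    Returns the displacement field on the fixed geometry (fixed -> moving,
    pull convention) plus the per-iteration mean local correlation and
    convergence/divergence flags.
    """
    if not _geometries_overlap(fixed.geometry, moving.geometry):
        raise ValueError("fixed and moving volumes do not overlap in space")

    levels = params.pyramid_levels
    factors = [2 ** (levels - 1 - l) for l in range(levels)]
    objective: list[list[float]] = []
    field: VectorField | None = None
    diverged = False
    converged = False

    for li, factor in enumerate(factors):
        f_lvl = _downsample(fixed, factor, fill)
        m_lvl = _downsample(moving, factor, fill)
        if params.presmooth_vox > 0:
            f_lvl = f_lvl.with_values(ndimage.gaussian_filter(
                f_lvl.values, params.presmooth_vox, mode="nearest"))
            m_lvl = m_lvl.with_values(ndimage.gaussian_filter(
                m_lvl.values, params.presmooth_vox, mode="nearest"))
        geom = f_lvl.geometry
        spacing = np.array(geom.spacing)
        mean_sp = float(spacing.mean())

        if field is None:
            field = _block_match(f_lvl.values, m_lvl.values, geom, params)
        else:
            field = _resample_field(field, geom)
            # residual block matching: re-match the warped moving image in a
            # shrinking search window, then compose the correction in
            warped = warp_scalar(m_lvl, field, mode="nearest")
            ones = ScalarGrid(m_lvl.geometry, np.ones(m_lvl.geometry.size))
            m_valid = warp_scalar(ones, field, fill=0.0).values >= 0.999
            resid = _block_match(f_lvl.values, warped.values, geom, params,
                                 radius_mm=params.search_radius_mm / 4 ** li,
                                 moving_valid=m_valid)
            pts_lvl = geom.voxel_centers()
            moved = pts_lvl + resid.displacements
            composed = resid.displacements + sample_vector(field, moved,
                                                           mode="nearest")
            field = VectorField(geom, composed)

        sigma_n = float(params.lcc_radius_vox)
        f_norm = _local_normalize(f_lvl.values, sigma_n, params.norm_floor_hu)
        # structureless (uniform) fixed regions carry no registration signal;
        # gate the demons force by the local fixed-image variance
        f_mean = ndimage.gaussian_filter(f_lvl.values, sigma_n, mode="nearest")
        f_var = ndimage.gaussian_filter(f_lvl.values ** 2, sigma_n,
                                        mode="nearest") - f_mean ** 2
        confidence = f_var / (f_var + 15.0 ** 2)
        sig_fluid = params.sigma_fluid_mm / spacing
        sig_diff = params.sigma_diffusion_mm / spacing
        kappa = params.step_scale * mean_sp

        level_obj: list[float] = []
        prev_update = np.inf
        n_grow = 0
        for _ in range(params.max_iterations[li]):
            warped = warp_scalar(m_lvl, field, mode="nearest")
            w_norm = _local_normalize(warped.values, sigma_n, params.norm_floor_hu)
            level_obj.append(float(np.mean(
                ndimage.gaussian_filter(f_norm * w_norm, sigma_n, mode="nearest")
            )))
            diff = f_norm - w_norm
            grads = np.gradient(w_norm, *geom.spacing)
            g2 = sum(g * g for g in grads)
            denom = g2 + (diff / kappa) ** 2
            update = np.zeros(tuple(geom.size) + (3,))
            ok = denom > 1e-9
            for c in range(3):
                update[..., c] = np.where(
                    ok, confidence * diff * grads[c] / np.maximum(denom, 1e-9), 0.0)
            for c in range(3):
                update[..., c] = ndimage.gaussian_filter(
                    update[..., c], sig_fluid, mode="nearest")
            mean_update = float(np.mean(np.linalg.norm(update, axis=-1)))
            new_disp = field.displacements + update
            for c in range(3):
                new_disp[..., c] = ndimage.gaussian_filter(
                    new_disp[..., c], sig_diff, mode="nearest")
            field = VectorField(geom, new_disp)
            if mean_update < params.convergence_tol_mm:
                converged = True
                break
            if mean_update > prev_update * 1.02:
                n_grow += 1
                if n_grow >= 3:
                    # runaway updates: abandon this level, continue the pyramid
                    diverged = True
                    break
            else:
                n_grow = 0
            prev_update = mean_update
        objective.append(level_obj)

    if field.geometry != fixed.geometry:
        field = _resample_field(field, fixed.geometry)
    return RegistrationResult(field=field, objective=objective,
                              converged=converged, diverged=diverged)


# ---------------------------------------------------------------------------
# DVF expansion across the FOV boundary
# ---------------------------------------------------------------------------

def expand_dvf(dvf_cropped: VectorField, full_geometry: Geometry,
               crop: CropRecord, sigma_mm: float = 6.0) -> VectorField:
    """Expand a small-FOV DVF to the full CT FOV.

    The field (zeroed outside the FOV) is blurred with a Gaussian of
    ``sigma_mm`` so the displacement decays smoothly to zero outside; voxels
    deeper than 3 sigma inside the FOV keep their original values.
    """
    if crop.geometry != full_geometry:
        raise ValueError("crop record geometry does not match the full geometry")
    if dvf_cropped.geometry != full_geometry:
        dvf_cropped = _resample_field(dvf_cropped, full_geometry)
    inside = crop.fov.mask_on(full_geometry)
    disp = np.where(inside[..., None], dvf_cropped.displacements, 0.0)
    if sigma_mm <= 0.0:
        return VectorField(full_geometry, disp)
    spacing = np.array(full_geometry.spacing)
    sig_vox = sigma_mm / spacing
    out = np.empty_like(disp)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(disp[..., c], sig_vox, mode="constant")
    depth = ndimage.distance_transform_edt(inside, sampling=full_geometry.spacing)
    deep = depth > 3.0 * sigma_mm
    out[deep] = disp[deep]
    return VectorField(full_geometry, out)


# ---------------------------------------------------------------------------
# DVF inversion
# ---------------------------------------------------------------------------

@dataclass
class InversionStats:
    mean_residual_mm: float
    max_residual_mm: float
    iterations: int
    tol_mm: float
    converged: bool


@dataclass
class DVFPair:
    """Forward (CT->CBCT, on CT grid) and backward (CBCT->CT) fields."""

    forward: VectorField
    backward: VectorField
    inversion: InversionStats


def invert_dvf(forward: VectorField, target_geometry: Geometry | None = None,
               tol_mm: float = 0.1, max_iter: int = 50
               ) -> tuple[VectorField, InversionStats]:
    """Invert a displacement field by fixed-point iteration.

    Solves ``b(x) = -f(x + b(x))`` starting from ``b = 0``; stops when the mean
    composition residual ``|f(x + b(x)) + b(x)|`` drops below ``tol_mm``.
    Non-convergence sets a flag on the stats, it is not fatal.
    """
    geom = target_geometry or forward.geometry
    pts = geom.voxel_centers()
    b = np.zeros(tuple(geom.size) + (3,))
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        f_at = sample_vector(forward, pts + b, mode="nearest")
        res_vec = f_at + b
        residual = float(np.mean(np.linalg.norm(res_vec, axis=-1)))
        if residual <= tol_mm:
            b = -f_at
            break
        b = -f_at
    f_at = sample_vector(forward, pts + b, mode="nearest")
    res = np.linalg.norm(f_at + b, axis=-1)
    stats = InversionStats(
        mean_residual_mm=float(res.mean()),
        max_residual_mm=float(res.max()),
        iterations=it,
        tol_mm=tol_mm,
        converged=bool(res.mean() <= tol_mm),
    )
    return VectorField(geom, b), stats


def make_dvf_pair(forward: VectorField, target_geometry: Geometry | None = None,
                  tol_mm: float = 0.1, max_iter: int = 50) -> DVFPair:
    backward, stats = invert_dvf(forward, target_geometry, tol_mm, max_iter)
    return DVFPair(forward=forward, backward=backward, inversion=stats)
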