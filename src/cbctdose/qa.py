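"""Registration commissioning and dose QA metrics.

Target registration error (TRE) against landmark ground truth, contour
agreement (DICE, mean surface distance, volume change, center-of-mass shift
with clinical warning flags), and DVH metrics (D99/D95/D90, Vx, max, mean,
percent-of-plan deltas).

Conventions: D_q is the dose received by at least q% of the structure volume,
computed as the (1 - q/100) quantile of the voxel doses with linear
interpolation between sorted voxels, so D99 <= D95 <= D90 always holds.
Percent-of-plan values are ratios of like metrics times 100.  The QA flags
trip strictly above a 10% volume change and a 3 mm center-of-mass shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose import DoseGrid
from .grids import ROIMask, VectorField, sample_vector
from .landmarks import LandmarkSet

VOLUME_FLAG_THRESHOLD = 0.10   # fractional volume change
COM_FLAG_THRESHOLD_MM = 3.0    # target center-of-mass translation


@dataclass
class TREReport:
    errors_mm: np.ndarray
    per_case: list[tuple[float, float, int]] = dc_field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.errors_mm.size)

    @property
    def mean_mm(self) -> float:
        return float(self.errors_mm.mean())

    @property
    def std_mm(self) -> float:
        return float(self.errors_mm.std())


def compute_tre(landmarks: LandmarkSet | Sequence[LandmarkSet],
                dvf: VectorField | None = None) -> TREReport:
    """Target registration error of a DVF against landmark correspondences.

    Per pair: ``|p_moving - (p_fixed + d(p_fixed))|``; with no field the raw
    pair distance.  Multiple sets are pooled per-landmark (the pooled mean and
    std are over all pairs of all cases); per-case means are also reported.
    """
    sets = [landmarks] if isinstance(landmarks, LandmarkSet) else list(landmarks)
    per_case = []
    all_err = []
    for lm in sets:
        if dvf is None:
            err = lm.pair_distances()
        else:
            mapped = lm.points_fixed + sample_vector(dvf, lm.points_fixed)
            err = np.linalg.norm(lm.points_moving - mapped, axis=1)
        all_err.append(err)
        per_case.append((float(err.mean()), float(err.std()), int(err.size)))
    return TREReport(errors_mm=np.concatenate(all_err), per_case=per_case)


@dataclass
class ContourQAReport:
    dice: float
    msd_mm: float
    volume_change: float       # (|B| - |A|) / |A|
    com_shift_mm: float
    volume_flag: bool
    com_flag: bool


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def contour_metrics(mask_a: ROIMask, mask_b: ROIMask,
                    volume_threshold: float = VOLUME_FLAG_THRESHOLD,
                    com_threshold_mm: float = COM_FLAG_THRESHOLD_MM
                    ) -> ContourQAReport:
    """DICE, symmetric mean surface distance, volume/COM change with flags.

    A is the reference (e.g. planning) contour, B the propagated one; flags
    are set strictly above the thresholds.
    """
    if mask_a.grid.geometry != mask_b.grid.geometry:
        raise ValueError("contour masks must share one geometry")
    a = mask_a.mask
    b = mask_b.mask
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("both contours are empty")
    inter = int((a & b).sum())
    dice = 2.0 * inter / (na + nb)

    spacing = mask_a.grid.geometry.spacing
    if na == 0 or nb == 0:
        msd = float("inf")
        vol_change = float("inf") if na == 0 else -1.0
        com_shift = float("inf")
    else:
        sa, sb = _surface(a), _surface(b)
        dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
        dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
        msd = float((dist_to_b[sa].mean() + dist_to_a[sb].mean()) / 2.0)
        vol_change = (nb - na) / na
        com_shift = float(np.linalg.norm(
            mask_b.center_of_mass_mm() - mask_a.center_of_mass_mm()))
    return ContourQAReport(
        dice=float(dice),
        msd_mm=msd,
        volume_change=float(vol_change),
        com_shift_mm=com_shift,
        volume_flag=bool(abs(vol_change) > volume_threshold),
        com_flag=bool(com_shift > com_threshold_mm),
    )


@dataclass
class DVHMetrics:
    d_gy: dict[int, float]              # q -> D_q in Gy (q in {99, 95, 90})
    v_pct: dict[float, float]           # x Gy -> % of volume >= x
    max_gy: float
    mean_gy: float
    percent_of_plan: dict[str, float] = dc_field(default_factory=dict)
    percent_delta: dict[str, float] = dc_field(default_factory=dict)


def _d_quantile(doses_sorted: np.ndarray, q: float) -> float:
    """Dose received by >= q% of the volume: (1 - q/100) quantile, linear."""
    n = doses_sorted.size
    if n == 1:
        return float(doses_sorted[0])
    h = (n - 1) * (1.0 - q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return float(doses_sorted[lo] + (h - lo) * (doses_sorted[hi] - doses_sorted[lo]))


def dvh_metrics(dose: DoseGrid, roi: ROIMask,
                plan_dose: DoseGrid | None = None,
                q_levels: Sequence[int] = (99, 95, 90),
                x_levels_gy: Sequence[float] = (20.0,)) -> DVHMetrics:
    """DVH point metrics of a dose within an ROI, optionally vs the plan dose."""
    if dose.geometry != roi.grid.geometry:
        raise ValueError("dose and ROI must share one geometry")
    sel = roi.mask
    if not sel.any():
        raise ValueError(f"ROI {roi.name!r} is empty")
    vals = np.sort(dose.values[sel])
    metrics = DVHMetrics(
        d_gy={q: _d_quantile(vals, q) for q in q_levels},
        v_pct={x: float(100.0 * np.mean(vals >= x)) for x in x_levels_gy},
        max_gy=float(vals[-1]),
        mean_gy=float(vals.mean()),
    )
    if plan_dose is not None:
        plan = dvh_metrics(plan_dose, roi, None, q_levels, x_levels_gy)
        pairs: dict[str, tuple[float, float]] = {}
        for q in q_levels:
            pairs[f"D{q}"] = (metrics.d_gy[q], plan.d_gy[q])
        for x in x_levels_gy:
            pairs[f"V{x:g}"] = (metrics.v_pct[x], plan.v_pct[x])
        pairs["max"] = (metrics.max_gy, plan.max_gy)
        pairs["mean"] = (metrics.mean_gy, plan.mean_gy)
        for name, (tx, pl) in pairs.items():
            if pl != 0.0:
                metrics.percent_of_plan[name] = 100.0 * tx / pl
                metrics.percent_delta[name] = 100.0 * (tx - pl) / pl
    return metrics


def course_report(plan_dose: DoseGrid,
                  daily_doses: dict[int, DoseGrid],
                  cumulative_dose: DoseGrid | None,
                  rois: dict[str, ROIMask],
                  q_levels: Sequence[int] = (99, 95, 90),
                  x_levels_gy: Sequence[float] = (20.0,),
                  n_fractions_plan: int | None = None) -> pd.DataFrame:
    """Per-fraction and cumulative DVH metrics per ROI as a tidy table.

    Columns: fraction (int or 'cumulative'), roi, metric, plan, tx,
    percent_delta; rows in deterministic (fraction, roi name, metric) order.
    Daily doses are compared against the plan dose scaled to one fraction when
    ``n_fractions_plan`` is given.
    """
    rows = []
    n_frac = n_fractions_plan or max(len(daily_doses), 1)
    daily_plan = plan_dose.scaled(1.0 / n_frac)

    def add(fraction_label, dose: DoseGrid, reference: DoseGrid):
        for roi_name in sorted(rois):
            m = dvh_metrics(dose, rois[roi_name], reference, q_levels, x_levels_gy)
            ref = dvh_metrics(reference, rois[roi_name], None, q_levels, x_levels_gy)
            named = {f"D{q}": (m.d_gy[q], ref.d_gy[q]) for q in q_levels}
            named.update({f"V{x:g}": (m.v_pct[x], ref.v_pct[x]) for x in x_levels_gy})
            named["max"] = (m.max_gy, ref.max_gy)
            named["mean"] = (m.mean_gy, ref.mean_gy)
            for metric, (tx, pl) in named.items():
                rows.append({
                    "fraction": fraction_label,
                    "roi": roi_name,
                    "metric": metric,
                    "plan": pl,
                    "tx": tx,
                    "percent_delta": 100.0 * (tx - pl) / pl if pl else np.nan,
                })

    for idx in sorted(daily_doses):
        add(idx, daily_doses[idx], daily_plan)
    if cumulative_dose is not None:
        add("cumulative", cumulative_dose, plan_dose)
    return pd.DataFrame(rows, columns=["fraction", "roi", "metric",
                                       "plan", "tx", "percent_delta"])


def report_summary(df: pd.DataFrame) -> str:
    """Human-readable digest of a course report."""
    if df.empty:
        return "course report: no ROIs evaluated\n"
    lines = ["course report (tx vs plan):"]
    for (frac, roi), grp in df.groupby(["fraction", "roi"], sort=False):
        parts = [f"{r.metric}={r.tx:.2f} ({r.percent_delta:+.1f}%)"
                 for r in grp.itertuples()]
        lines.append(f"  fraction {frac} / {roi}: " + ", ".join(parts))
    return "\n".join(lines) + "\n"
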