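"""End-to-end course orchestration.

``run_course`` drives the full reconstruction chain for every fraction of a
(synthetic or fixture-backed) treatment course: phase matching, FOV crop,
deformable registration, DVF expansion/inversion, pseudo-CT synthesis, dose
computation, 4D accumulation to the reference phase, warping to the planning
CT, course accumulation and QA reporting — advancing each fraction through
the four-state schedule as artifacts become ready.  A stage failure marks the
fraction and the remaining fractions still run.

``make_fixtures`` writes a phantom course to disk (MetaImage volumes, landmark
text files, schedule XML) so the pipeline can also be driven from files, and
so fault injection (corrupt inputs) is testable.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Any

import numpy as np

from . import io as vio
from .dose import (
    BeamSpec,
    DoseGrid,
    PlanChain,
    accumulate_4d,
    accumulate_course,
    beam_from_gantry,
    compute_dose,
    warp_dose,
)
from .grids import FOVRegion, Phase4DSet, ROIMask, ScalarGrid, VectorField, warp_scalar
from .landmarks import write_landmarks
from .phantom import (
    CBCTDegradeSpec,
    CourseFixture,
    PhantomSpec,
    make_4dct,
    make_course,
)
from .phase_matching import match_phases
from .pseudo_ct import generate_pseudo_ct
from .qa import contour_metrics, course_report, report_summary
from .registration import (
    FAST_PARAMS,
    RegistrationParams,
    crop_to_fov,
    expand_dvf,
    invert_dvf,
    register,
)
from .schedule import (
    FractionRecord,
    TreatmentRecord,
    advance_status,
    read_schedule_xml,
    write_schedule_xml,
)

DEFAULT_CONFIG: dict[str, Any] = {
    "patient_id": "PHANTOM-001",
    "seed": 0,
    "mode": "3d",                 # "3d": reference phase only; "4d": all phases
    "n_fractions": 1,
    "start_date": "2024-01-08",
    "prescription_gy_per_fraction": 12.0,
    "shrink_per_fraction": 0.0,
    "drift_per_fraction_mm": [0.0, 0.0, 0.0],
    "phantom": {"size": [32, 32, 32], "spacing_mm": [5.0, 5.0, 5.0]},
    "cbct": {
        "noise_std_hu": 15.0,
        "intensity_scale": 0.95,
        "intensity_offset_hu": -10.0,
        "fov_diameter_mm": 120.0,
    },
    "registration": "fast",       # "fast", "default", or a parameter mapping
    "expand_sigma_mm": 6.0,
    "beams": [
        {"gantry_deg": 0.0, "field_size_mm": [50.0, 50.0]},
        {"gantry_deg": 90.0, "field_size_mm": [50.0, 50.0]},
        {"gantry_deg": 180.0, "field_size_mm": [50.0, 50.0]},
    ],
    "dose_step_mm": 2.0,
    "fixture_dir": None,
}


def _merged_config(config: dict[str, Any] | None) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def phantom_spec_from_config(cfg: dict[str, Any], seed: int) -> PhantomSpec:
    kwargs: dict[str, Any] = {"seed": seed}
    for key, val in dict(cfg.get("phantom", {})).items():
        kwargs[key] = tuple(val) if isinstance(val, (list, tuple)) else val
    return PhantomSpec(**kwargs)


def degrade_spec_from_config(cfg: dict[str, Any], seed: int) -> CBCTDegradeSpec:
    c = cfg["cbct"]
    fov = FOVRegion(shape="cylinder", center=(0.0, 0.0, 0.0),
                    diameter=float(c["fov_diameter_mm"]), axis=2)
    return CBCTDegradeSpec(
        noise_std_hu=float(c["noise_std_hu"]),
        intensity_scale=float(c["intensity_scale"]),
        intensity_offset_hu=float(c["intensity_offset_hu"]),
        fov=fov,
        seed=seed + 1000,
    )


def registration_params_from_config(cfg: dict[str, Any]) -> RegistrationParams:
    r = cfg.get("registration", "fast")
    if r == "fast":
        return FAST_PARAMS
    if r == "default":
        return RegistrationParams()
    if isinstance(r, dict):
        r = dict(r)
        if "max_iterations" in r:
            r["max_iterations"] = tuple(r["max_iterations"])
        return RegistrationParams(**r)
    raise ValueError(f"unrecognized registration config {r!r}")


def beams_from_config(cfg: dict[str, Any], isocenter: np.ndarray) -> list[BeamSpec]:
    beams = []
    for b in cfg["beams"]:
        beams.append(beam_from_gantry(
            gantry_deg=float(b.get("gantry_deg", 0.0)),
            isocenter_mm=tuple(isocenter),
            field_size_mm=tuple(b.get("field_size_mm", (50.0, 50.0))),
            weight=float(b.get("weight", 1.0)),
            mu_per_mm=float(b.get("mu_per_mm", 0.005)),
            sad_mm=float(b.get("sad_mm", 1000.0)),
        ))
    return beams


# ---------------------------------------------------------------------------
# Fixture IO
# ---------------------------------------------------------------------------

def make_fixtures(config: dict[str, Any] | None, out_dir: str | Path,
                  seed: int | None = None) -> Path:
    """Write a phantom course (volumes, landmarks, schedule XML) to disk."""
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg["seed"])
    out = Path(out_dir)
    (out / "plan").mkdir(parents=True, exist_ok=True)

    spec = phantom_spec_from_config(cfg, seed)
    degrade = degrade_spec_from_config(cfg, seed)
    course = make_course(
        spec, degrade,
        n_fractions=int(cfg["n_fractions"]),
        shrink_per_fraction=float(cfg["shrink_per_fraction"]),
        drift_per_fraction_mm=tuple(cfg["drift_per_fraction_mm"]),
        start_date=datetime.date.fromisoformat(cfg["start_date"]),
    )
    plan = course.plan
    for p, ph in enumerate(plan.ct4d):
        vio.write_volume(ph, out / "plan" / f"phase_{p:02d}.mha")
        vio.write_vector_field(plan.gt_fields[p],
                               out / "plan" / f"gt_dvf_phase_{p:02d}.mha")
    for name, roi in plan.rois.items():
        vio.write_volume(roi.grid, out / "plan" / f"roi_{name}.mha")
    geom = plan.ct4d.geometry
    for p, lm in enumerate(plan.landmarks):
        fixed_idx = geom.world_to_index(lm.points_fixed)
        moving_idx = geom.world_to_index(lm.points_moving)
        write_landmarks(out / "plan" / f"landmarks_phase_{p:02d}_fixed.txt", fixed_idx)
        write_landmarks(out / "plan" / f"landmarks_phase_{p:02d}_moving.txt", moving_idx)

    fractions = []
    for fx in course.fractions:
        fdir = out / f"fraction_{fx.index:02d}"
        fdir.mkdir(exist_ok=True)
        paths = []
        for p, ph in enumerate(fx.cbct4d):
            path = fdir / f"cbct_phase_{p:02d}.mha"
            vio.write_volume(ph, path)
            paths.append(str(path.relative_to(out)))
        fractions.append(FractionRecord(
            index=fx.index, date=fx.date, cbct_paths=tuple(paths),
            couch_correction_mm=tuple(-np.asarray(fx.degrade.setup_shift_mm)),
        ))
    record = TreatmentRecord(
        patient_id=str(cfg["patient_id"]),
        plan_chain=[("pretreatment", course.fractions[0].date)],
        fractions=fractions,
    )
    write_schedule_xml(record, out / "schedule.xml")
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    return out


class _FixtureFraction:
    """Duck-typed stand-in for FractionFixture when driving from files."""

    def __init__(self, index, date, cbct4d, couch):
        self.index = index
        self.date = date
        self.cbct4d = cbct4d
        self.truth = None
        self.couch_correction_mm = couch
        self.degrade = None


def _load_fixture_course(fixture_dir: Path, cfg: dict[str, Any],
                         seed: int) -> tuple[CourseFixture, TreatmentRecord]:
    record = read_schedule_xml(fixture_dir / "schedule.xml")
    spec = phantom_spec_from_config(cfg, seed)
    n = spec.n_phases
    phases = [vio.read_volume(fixture_dir / "plan" / f"phase_{p:02d}.mha", "HU")
              for p in range(n)]
    plan = make_4dct(spec)  # analytic ground truth (masks, DVFs, landmarks)
    plan.ct4d = Phase4DSet(phases, reference_index=0, n_expected=n)

    fractions = []
    for fr in record.fractions:
        # an unreadable CBCT must only fail its own fraction
        try:
            cbct_phases = [vio.read_volume(fixture_dir / rel, "HU")
                           for rel in fr.cbct_paths]
            cbct4d = Phase4DSet(cbct_phases, reference_index=0,
                                n_expected=len(cbct_phases))
        except Exception as exc:  # noqa: BLE001
            cbct4d = None
            fx = _FixtureFraction(fr.index, fr.date, None,
                                  tuple(fr.couch_correction_mm))
            fx.load_error = f"unreadable CBCT: {exc}"
            fractions.append(fx)
            continue
        fractions.append(_FixtureFraction(fr.index, fr.date, cbct4d,
                                          tuple(fr.couch_correction_mm)))
    return CourseFixture(plan=plan, fractions=fractions), record


# ---------------------------------------------------------------------------
# Course orchestration
# ---------------------------------------------------------------------------

def _propagate_roi(roi: ROIMask, backward: VectorField) -> ROIMask:
    warped = warp_scalar(roi.grid, backward, fill=0.0)
    return ROIMask(warped.with_values((warped.values >= 0.5).astype(float), "binary"),
                   roi.name + "_prop", roi.category)


def run_course(config: dict[str, Any] | None, output_dir: str | Path,
               seed: int | None = None) -> dict[str, Any]:
    """Run the whole reconstruction chain for a course; returns a result dict.

    Keys: ``record`` (final TreatmentRecord), ``report`` (DVH DataFrame),
    ``daily_doses``, ``cumulative`` and ``output_dir``.  Fully deterministic
    for a fixed seed.
    """
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg["seed"])
    out = Path(output_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if cfg.get("fixture_dir"):
        course, record = _load_fixture_course(Path(cfg["fixture_dir"]), cfg, seed)
    else:
        spec = phantom_spec_from_config(cfg, seed)
        degrade = degrade_spec_from_config(cfg, seed)
        course = make_course(
            spec, degrade,
            n_fractions=int(cfg["n_fractions"]),
            shrink_per_fraction=float(cfg["shrink_per_fraction"]),
            drift_per_fraction_mm=tuple(cfg["drift_per_fraction_mm"]),
            start_date=datetime.date.fromisoformat(cfg["start_date"]),
        )
        record = TreatmentRecord(
            patient_id=str(cfg["patient_id"]),
            plan_chain=[("pretreatment", course.fractions[0].date)],
            fractions=[FractionRecord(index=f.index, date=f.date,
                                      couch_correction_mm=tuple(
                                          -np.asarray(f.degrade.setup_shift_mm)))
                       for f in course.fractions],
        )

    plan = course.plan
    plan_ct = plan.ct4d.reference
    fov = degrade_spec_from_config(cfg, seed).fov
    params = registration_params_from_config(cfg)
    mode = cfg["mode"]
    n_frac = len(course.fractions)
    rx_per_fraction = float(cfg["prescription_gy_per_fraction"])

    gtv = plan.rois["GTV"]
    iso = gtv.center_of_mass_mm()
    beams = beams_from_config(cfg, iso)
    step_mm = float(cfg["dose_step_mm"])

    plan_dose_raw = compute_dose(plan_ct, beams, step_mm=step_mm, provenance="plan")
    gtv_mean = float(plan_dose_raw.values[gtv.mask].mean())
    norm = rx_per_fraction * n_frac / gtv_mean if gtv_mean > 0 else 1.0
    plan_dose = plan_dose_raw.scaled(norm)
    vio.write_volume(plan_dose.grid, out / "volumes" / "plan_dose.mha")
    daily_norm = norm / n_frac

    daily_doses: dict[int, DoseGrid] = {}
    contour_rows: list[dict[str, Any]] = []

    for fx in course.fractions:
        idx = fx.index
        try:
            if getattr(fx, "load_error", None):
                raise RuntimeError(fx.load_error)
            cbct4d = fx.cbct4d
            advance_status(record, idx, "cbct_arrived")
            couch = np.asarray(record.fraction(idx).couch_correction_mm)

            if mode == "4d":
                pairing = match_phases(plan.ct4d, cbct4d)
                phase_pairs = [(pairing.ct_phase_for(p), p)
                               for p in range(len(cbct4d))]
            else:
                ref = plan.ct4d.reference_index
                phase_pairs = [(ref, cbct4d.reference_index)]

            pseudo_cts: dict[int, ScalarGrid] = {}
            forwards: dict[int, VectorField] = {}
            for ct_p, cb_p in phase_pairs:
                ct_phase = plan.ct4d[ct_p]
                cropped, crop_rec = crop_to_fov(ct_phase, fov)
                reg = register(cropped, cbct4d[cb_p], params)
                forward = expand_dvf(reg.field, ct_phase.geometry, crop_rec,
                                     sigma_mm=float(cfg["expand_sigma_mm"]))
                backward, _ = invert_dvf(forward)
                pseudo_cts[cb_p] = generate_pseudo_ct(
                    ct_phase, backward, fov, patch_phase_ct=ct_phase,
                    couch_shift_mm=tuple(couch))
                forwards[cb_p] = forward
            advance_status(record, idx, "pseudo_ct_done")

            ref_cb = cbct4d.reference_index
            vio.write_volume(pseudo_cts[ref_cb],
                             out / "volumes" / f"pseudo_ct_f{idx:02d}.mha")

            if mode == "4d":
                phase_doses = []
                for p in range(len(cbct4d)):
                    d = compute_dose(pseudo_cts[p], beams, step_mm=step_mm,
                                     provenance="phase").scaled(daily_norm)
                    phase_doses.append(d)
                dvfs: list[VectorField | None] = []
                ref_img = pseudo_cts[ref_cb]
                for p in range(len(cbct4d)):
                    if p == ref_cb:
                        dvfs.append(None)
                    else:
                        r = register(ref_img, pseudo_cts[p], params)
                        dvfs.append(r.field)
                day_dose = accumulate_4d(phase_doses, dvfs)
            else:
                day_dose = compute_dose(pseudo_cts[ref_cb], beams, step_mm=step_mm,
                                        provenance="daily").scaled(daily_norm)

            daily_on_plan = warp_dose(day_dose, forwards[ref_cb])
            daily_on_plan.fraction_ids = (idx,)
            daily_doses[idx] = daily_on_plan
            vio.write_volume(daily_on_plan.grid,
                             out / "volumes" / f"daily_dose_f{idx:02d}.mha")
            advance_status(record, idx, "txdose_done")

            backward_ref, _ = invert_dvf(forwards[ref_cb])
            prop = _propagate_roi(gtv, backward_ref)
            cqa = contour_metrics(gtv, prop)
            contour_rows.append({
                "fraction": idx, "roi": "GTV", "dice": cqa.dice,
                "msd_mm": cqa.msd_mm, "volume_change": cqa.volume_change,
                "com_shift_mm": cqa.com_shift_mm,
                "volume_flag": cqa.volume_flag, "com_flag": cqa.com_flag,
            })
            log.append(f"fraction {idx}: ok")
        except Exception as exc:  # noqa: BLE001 - stage failures must not kill the course
            record.fraction(idx).note = f"failed: {exc}"
            log.append(f"fraction {idx}: FAILED ({exc})")
            continue

    cumulative = None
    if daily_doses:
        chain = PlanChain(plans=record.plan_chain)
        dated = [(record.fraction(i).date, d) for i, d in sorted(daily_doses.items())]
        cumulative = accumulate_course(dated, chain)
        vio.write_volume(cumulative.grid, out / "volumes" / "cumulative_dose.mha")
        for idx in sorted(daily_doses):
            if record.fraction(idx).status == "TXDOSE_READY":
                advance_status(record, idx, "cumulative_done")

    rois = {"GTV": plan.rois["GTV"], "LUNGS": plan.rois["LUNGS"],
            "CORD": plan.rois["CORD"]}
    report = course_report(plan_dose, daily_doses, cumulative, rois,
                           n_fractions_plan=n_frac)
    report.to_csv(out / "qa_report.csv", index=False, float_format="%.6f")
    if contour_rows:
        import pandas as pd

        pd.DataFrame(contour_rows).to_csv(out / "contour_qa.csv", index=False,
                                          float_format="%.6f")
    write_schedule_xml(record, out / "schedule.xml")
    (out / "summary.txt").write_text(report_summary(report))
    (out / "run_log.txt").write_text("\n".join(log) + "\n")

    return {
        "record": record,
        "report": report,
        "daily_doses": daily_doses,
        "cumulative": cumulative,
        "output_dir": out,
    }
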