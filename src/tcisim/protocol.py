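"""The bench-study protocol: induction, step-down at t0, per-case outcome extraction.

Each simulated case: induce at one of the study's effect-site targets from a
drug-naive state, find the plasma-concentration peak (end of the rate-capped
bolus), define t0 = peak + 60 s (the assumed moment of tracheal intubation
and surgical incision), lower the target to the 2.5 mcg/mL maintenance level
at t0, and record the quantities the study reports: cumulative dose at t0,
the infusion-pause duration, the dose at one-minute marks for ten minutes,
the dose at delivery (tD = t0 + the patient's incision-to-delivery time) and
whether delivery fell inside the pause.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .controller import NO_RESUME, PumpConfig, find_pause_end, run_tci
from .pk import (
    DEFAULT_KE0_MODE,
    PatientDemographics,
    PumpTrace,
    SchniderParams,
    Urgency,
    schnider_parameters,
)

STUDY_TARGETS = (4.0, 6.0, 8.0)
MAINTENANCE_TARGET = 2.5
T0_OFFSET_S = 60.0
DEFAULT_HORIZON_S = 1800.0
N_MINUTE_DOSES = 11  # t0 + 0..10 min

#: horizon of the induction-only pre-run used to locate the plasma peak
_INDUCTION_SCAN_S = 360.0


class NoPeakError(ValueError):
    """Raised when a trace contains no plasma-concentration peak."""


@dataclass(frozen=True)
class CaseResult:
    """Per-patient, per-target protocol outputs."""

    patient_id: str
    urgency: Urgency
    weight: float  # kg
    induction_target: float  # mcg/mL
    t_plasma_peak: float  # s
    t0: float  # s
    dose_at_t0: float  # mg
    dose_per_kg_at_t0: float  # mg/kg
    pause_duration: float  # s; inf when the pump never resumed
    minute_doses: tuple[float, ...]  # mg at t0 + 0..10 min
    peak_cp: float  # mcg/mL, plasma peak during induction
    tD_offset: float  # s from t0 (incision) to delivery
    dose_at_tD: float  # mg
    incremental_dose_t0_to_tD: float  # mg
    delivered_during_pause: bool
    flagged_no_resume: bool = False


def detect_plasma_peak(trace: PumpTrace) -> float:
    """Time (s) of the first local maximum of Cp on the trace grid.

    Under a rate-capped bolus this coincides with the end of the bolus to
    within one grid step.  A monotone Cp profile has no peak and raises.
    """
    cp = np.asarray(trace.cp)
    rising = np.diff(cp) > 0
    falling = np.diff(cp) < 0
    for i in range(1, len(cp) - 1):
        if falling[i] and rising[:i].any() and not rising[i]:
            return float(trace.t[i])
    raise NoPeakError("plasma concentration has no local maximum in this trace")


def run_case(
    demo: PatientDemographics,
    induction_target: float,
    cfg: PumpConfig | None = None,
    maintenance_target: float = MAINTENANCE_TARGET,
    t0_offset: float = T0_OFFSET_S,
    horizon: float = DEFAULT_HORIZON_S,
    ke0_mode: str = DEFAULT_KE0_MODE,
    patient_id: str = "case",
) -> CaseResult:
    """Simulate one patient at one induction target and extract all outcomes.

    Requires ``demo.incision_to_delivery``.  Delivery exactly at pump
    reactivation counts as *not* during the pause (strict inequality).
    """
    if demo.incision_to_delivery is None:
        raise ValueError("run_case needs demo.incision_to_delivery (minutes)")
    if induction_target not in STUDY_TARGETS:
        warnings.warn(
            f"induction target {induction_target} mcg/mL is outside the "
            f"study's set {STUDY_TARGETS}",
            stacklevel=2,
        )
    cfg = cfg or PumpConfig()
    params = schnider_parameters(demo, ke0_mode=ke0_mode)

    # the scan window must outlast the rate-capped bolus; extend it for
    # patients whose induction dose is large relative to the rate cap
    scan_s = _INDUCTION_SCAN_S
    while True:
        scan = run_tci(params, [(0.0, induction_target)], cfg, scan_s)
        try:
            t_peak = detect_plasma_peak(scan)
            break
        except NoPeakError:
            if scan_s >= horizon:
                raise
            scan_s = min(2 * scan_s, horizon)
    t0 = t_peak + t0_offset

    td_offset = demo.incision_to_delivery * 60.0
    duration = min(
        horizon,
        t0 + 60.0 * max(N_MINUTE_DOSES - 1, demo.incision_to_delivery) + 60.0,
    )
    trace = run_tci(
        params,
        [(0.0, induction_target), (t0, maintenance_target)],
        cfg,
        duration,
    )

    pause = find_pause_end(trace, t0)
    if not math.isfinite(pause) and duration < horizon:
        # pause outlasts the economical trace; rerun to the full horizon
        trace = run_tci(
            params,
            [(0.0, induction_target), (t0, maintenance_target)],
            cfg,
            horizon,
        )
        pause = find_pause_end(trace, t0)
    flagged = not math.isfinite(pause)
    dose_t0 = trace.cumulative_dose[trace.index_at(t0)]
    minute_doses = tuple(
        float(trace.cumulative_dose[trace.index_at(t0 + 60.0 * k)])
        for k in range(N_MINUTE_DOSES)
    )
    dose_td = trace.dose_at(t0 + td_offset)
    peak_cp = float(np.max(trace.cp[: trace.index_at(t0) + 1]))
    return CaseResult(
        patient_id=patient_id,
        urgency=demo.urgency,
        weight=demo.weight,
        induction_target=induction_target,
        t_plasma_peak=t_peak,
        t0=t0,
        dose_at_t0=float(dose_t0),
        dose_per_kg_at_t0=float(dose_t0 / demo.weight),
        pause_duration=pause,
        minute_doses=minute_doses,
        peak_cp=peak_cp,
        tD_offset=td_offset,
        dose_at_tD=float(dose_td),
        incremental_dose_t0_to_tD=float(dose_td - dose_t0),
        delivered_during_pause=bool(td_offset < pause),
        flagged_no_resume=flagged,
    )


def run_study(
    cohort: list[PatientDemographics],
    targets: tuple[float, ...] = STUDY_TARGETS,
    cfg: PumpConfig | None = None,
    **case_kwargs,
) -> dict[float, list[CaseResult]]:
    """One CaseResult per (patient, target); deterministic given cohort and config.

    Per-case flags (e.g. pump never resuming) are carried in the results
    rather than aborting the cohort.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    cfg = cfg or PumpConfig()
    return {
        target: [
            run_case(demo, target, cfg, patient_id=f"p{i:03d}", **case_kwargs)
            for i, demo in enumerate(cohort)
        ]
        for target in targets
    }


def results_table(results: dict[float, list[CaseResult]]) -> pd.DataFrame:
    """Flatten study results to one row per patient x target."""
    rows = []
    for target, cases in results.items():
        for c in cases:
            row = {
                "patient_id": c.patient_id,
                "urgency": c.urgency.value,
                "weight_kg": c.weight,
                "induction_target": target,
                "t_plasma_peak_s": c.t_plasma_peak,
                "t0_s": c.t0,
                "dose_at_t0_mg": c.dose_at_t0,
                "dose_per_kg_at_t0": c.dose_per_kg_at_t0,
                "pause_duration_s": c.pause_duration,
                "peak_cp": c.peak_cp,
                "tD_offset_s": c.tD_offset,
                "dose_at_tD_mg": c.dose_at_tD,
                "incremental_dose_mg": c.incremental_dose_t0_to_tD,
                "delivered_during_pause": c.delivered_during_pause,
                "flagged_no_resume": c.flagged_no_resume,
            }
            for k, d in enumerate(c.minute_doses):
                row[f"dose_t{k}_mg"] = d
            rows.append(row)
    return pd.DataFrame(rows)
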