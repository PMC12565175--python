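"""Study-level summaries: dose tables, pause statistics, proportions, regressions.

Produces machine-readable analogs of the study's two tables plus a summary
dict: per-target induction doses at t0 (mg and mg/kg), doses at delivery and
the t0→tD increments stratified by urgency, minute-by-minute cumulative
doses, infusion-pause durations, delivery-during-pause proportions with
Wilson CIs and 2x2 tests, a per-target logistic model of delivery-in-pause
on urgency/age/BMI, and a linear model of incision-to-delivery time.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import cohort_to_frame
from .pk import PatientDemographics
from .protocol import N_MINUTE_DOSES
from .stats import (
    DegenerateTestError,
    SeparationError,
    linear_fit,
    logistic_fit,
    two_by_two_test,
    two_sample_t,
    wilson_ci,
)


def _mean_sd(x) -> dict:
    x = np.asarray(x, dtype=float)
    return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0}


def analysis_frame(
    results: pd.DataFrame, cohort: list[PatientDemographics]
) -> pd.DataFrame:
    """Join per-case results with patient covariates (age, BMI, urgency)."""
    cov = cohort_to_frame(cohort)
    cov["bmi"] = cov.weight_kg / (cov.height_cm / 100.0) ** 2
    cov = cov.rename(columns={"id": "patient_id"})
    return results.merge(
        cov[["patient_id", "age_y", "bmi", "incision_to_delivery_min"]],
        on="patient_id",
    )


def minute_dose_table(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD cumulative dose (mg) at t0+0..10 min, one row pair per target."""
    rows = []
    for target, grp in results.groupby("induction_target"):
        for stat in ("mean", "sd"):
            row = {"induction_target": target, "stat": stat}
            for k in range(N_MINUTE_DOSES):
                col = grp[f"dose_t{k}_mg"]
                row[f"t{k}"] = float(col.mean() if stat == "mean" else col.std(ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)


def delivery_dose_table(results: pd.DataFrame) -> pd.DataFrame:
    """Dose at delivery and from t0 to delivery, total and by urgency."""
    rows = []
    for target, grp in results.groupby("induction_target"):
        el = grp[grp.urgency == "elective"]
        em = grp[grp.urgency == "emergency"]
        for metric, col in (
            ("dose_at_tD_mg", "dose_at_tD_mg"),
            ("dose_at_tD_mg_kg", None),
            ("incremental_dose_mg", "incremental_dose_mg"),
        ):
            def vals(g):
                if col is None:
                    return g.dose_at_tD_mg / g.weight_kg
                return g[col]

            row = {"induction_target": target, "metric": metric}
            for name, g in (("total", grp), ("elective", el), ("emergency", em)):
                s = _mean_sd(vals(g))
                row[f"{name}_mean"], row[f"{name}_sd"] = s["mean"], s["sd"]
            try:
                t = two_sample_t(vals(el).to_numpy(), vals(em).to_numpy())
                row["elective_vs_emergency_p"] = t.p_value
            except DegenerateTestError:
                row["elective_vs_emergency_p"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_study(
    results: pd.DataFrame, cohort: list[PatientDemographics], level: float = 0.95
) -> dict:
    """All headline statistics of a study run as one nested dict."""
    df = analysis_frame(results, cohort)
    cov = cohort_to_frame(cohort)
    el = cov[cov.urgency == "elective"]
    em = cov[cov.urgency == "emergency"]

    out: dict = {
        "cohort": {
            "n": len(cov),
            "n_elective": int((cov.urgency == "elective").sum()),
            "age_y": _mean_sd(cov.age_y),
            "height_cm": _mean_sd(cov.height_cm),
            "weight_kg": _mean_sd(cov.weight_kg),
            "bmi": _mean_sd(cov.weight_kg / (cov.height_cm / 100.0) ** 2),
            "incision_to_delivery_min": _mean_sd(cov.incision_to_delivery_min),
        },
        "targets": {},
    }
    if len(el) >= 2 and len(em) >= 2:
        t = two_sample_t(
            el.incision_to_delivery_min.to_numpy(), em.incision_to_delivery_min.to_numpy()
        )
        out["incision_to_delivery_elective_vs_emergency"] = {
            "difference_min": t.difference,
            "ci": [t.ci_low, t.ci_high],
            "p": t.p_value,
        }

    for target, grp in df.groupby("induction_target"):
        n = len(grp)
        k = int(grp.delivered_during_pause.sum())
        w = wilson_ci(k, n, level)
        tgt: dict = {
            "n": n,
            "dose_at_t0_mg": _mean_sd(grp.dose_at_t0_mg),
            "dose_per_kg_at_t0": _mean_sd(grp.dose_per_kg_at_t0),
            "pause_duration_s": _mean_sd(grp.pause_duration_s),
            "peak_cp": _mean_sd(grp.peak_cp),
            "peak_cp_over_target": _mean_sd(grp.peak_cp / target),
            "delivered_during_pause": {
                "k": k,
                "n": n,
                "proportion": w.proportion,
                "ci": [w.ci_low, w.ci_high],
            },
            "flagged_no_resume": int(grp.flagged_no_resume.sum()),
        }
        el_g = grp[grp.urgency == "elective"]
        em_g = grp[grp.urgency == "emergency"]
        if len(el_g) and len(em_g):
            tgt["delivered_during_pause_by_urgency"] = {
                "elective": float(el_g.delivered_during_pause.mean()),
                "emergency": float(em_g.delivered_during_pause.mean()),
            }
            table = [
                [
                    int(em_g.delivered_during_pause.sum()),
                    int((~em_g.delivered_during_pause).sum()),
                ],
                [
                    int(el_g.delivered_during_pause.sum()),
                    int((~el_g.delivered_during_pause).sum()),
                ],
            ]
            try:
                tt = two_by_two_test(table)
                tgt["delivered_during_pause_by_urgency"]["p"] = tt.p_value
                tgt["delivered_during_pause_by_urgency"]["method"] = tt.method
            except DegenerateTestError:
                pass
        reg = grp.rename(columns={"age_y": "age"}).assign(
            outcome=grp.delivered_during_pause.astype(int)
        )
        try:
            fit = logistic_fit(reg, "outcome", ["urgency", "age", "bmi"], level)
            tgt["logistic_delivery_in_pause"] = {
                pred: {
                    "or": float(row.estimate),
                    "ci": [float(row.ci_low), float(row.ci_high)],
                    "p": float(row.p_value),
                }
                for pred, row in fit.table.iterrows()
            }
        except (SeparationError, DegenerateTestError) as err:
            tgt["logistic_delivery_in_pause"] = {"flagged": str(err)}
        out["targets"][f"{target:g}"] = tgt

    lin_df = cov.assign(bmi=cov.weight_kg / (cov.height_cm / 100.0) ** 2).rename(
        columns={"age_y": "age"}
    )
    try:
        lin = linear_fit(lin_df, "incision_to_delivery_min", ["urgency", "age", "bmi"], level)
        out["linear_incision_to_delivery"] = {
            "r_squared": lin.r_squared,
            "coefficients": {
                pred: {
                    "estimate": float(row.estimate),
                    "ci": [float(row.ci_low), float(row.ci_high)],
                    "p": float(row.p_value),
                }
                for pred, row in lin.table.iterrows()
            },
        }
    except (ValueError, DegenerateTestError) as err:
        out["linear_incision_to_delivery"] = {"flagged": str(err)}
    return out
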