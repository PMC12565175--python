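"""Effect-site target-controlled infusion logic.

The controller implements the standard no-overshoot effect-site strategy: at
every decision instant it asks "what constant rate over the next update
interval keeps the *predicted future peak* of the effect-site concentration
at or below the target?" and applies the largest admissible rate, capped at
the pump's bolus rate.  Because the PK system is linear, the predicted peak
is affine in the candidate rate, so the admissible rate has a closed form —
no search is needed per step.

The same rule produces every phase of the study protocol:

* induction from a drug-naive state — the admissible rate is huge, so the
  pump runs at the rate cap until the predicted peak touches the target
  (a rate-capped bolus), then pauses while Ce coasts up to the target;
* maintenance — the rate settles to metabolic-plus-distributional
  replacement (≈ CL1·target once the peripheral compartments fill);
* target reduction — any infusion would push Ce above the lowered target,
  so the rate is zero (the infusion pause) until Ce decays to the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .pk import SEC_PER_MIN, PKState, PumpTrace, SchniderParams, _transition

#: sentinel returned by find_pause_end when the pump never resumes
NO_RESUME = float("inf")


@dataclass(frozen=True)
class PumpConfig:
    """Pump behavior knobs.

    ``max_rate_ml_h`` is the bolus/induction rate cap in mL/h of propofol
    solution; with 10 mg/mL propofol the default 720 mL/h is 120 mg/min.
    The default was calibrated once against the induction-dose targets of the
    study protocol and then frozen.  ``update_interval`` is the controller
    decision period; pause durations are resolved to this granularity.
    ``ce_tolerance`` is the fractional effect-site overshoot the controller
    tolerates before declaring a violation.
    """

    max_rate_ml_h: float = 720.0
    drug_mg_ml: float = 10.0
    update_interval: float = 1.0  # seconds
    ce_tolerance: float = 0.005

    def __post_init__(self) -> None:
        if self.max_rate_ml_h <= 0 or self.drug_mg_ml <= 0:
            raise ValueError("max_rate_ml_h and drug_mg_ml must be positive")
        if self.update_interval < 1.0:
            raise ValueError("update_interval must be >= 1 s")
        if not (0.0 <= self.ce_tolerance <= 0.05):
            raise ValueError("ce_tolerance must lie in [0, 0.05]")

    @property
    def max_rate(self) -> float:
        """Rate cap in mg/min."""
        return self.max_rate_ml_h * self.drug_mg_ml / 60.0


class _Predictor:
    """Cached linear-response machinery for peak-Ce prediction.

    For a candidate rate r held over one update interval and zero input
    afterwards, the future Ce trajectory is  u0(s) + r·u1(s)  where u0 is the
    zero-input response of the current state and u1 the unit-rate forced
    response — both evaluated on a fixed look-ahead grid by propagating the
    Ce read-out row through powers of the one-step propagator.
    """

    def __init__(
        self,
        params: SchniderParams,
        cfg: PumpConfig,
        horizon_s: float = 600.0,
        pred_dt_s: float = 1.0,
    ):
        self.params = params
        self.cfg = cfg
        dt_min = cfg.update_interval / SEC_PER_MIN
        f5, g5 = _transition(params, dt_min)
        self.f5, self.g5 = f5, g5
        f4, g4 = f5[:4, :4], g5[:4]

        a4 = params.system_matrix()
        e1 = expm(a4 * (pred_dt_s / SEC_PER_MIN))
        n = int(round(horizon_s / pred_dt_s)) + 1
        rows = np.empty((n, 4))
        v = np.zeros(4)
        v[3] = 1.0  # Ce read-out
        for i in range(n):
            rows[i] = v
            v = v @ e1
        # Ce at s seconds after the interval: rows @ (F4 x + r g4)
        self.ce_mat_f = rows @ f4  # (n, 4): maps current state -> u0
        self.u1 = rows @ g4  # (n,): unit-rate forced response
        pos = self.u1 > 1e-15
        self._mat_pos = np.ascontiguousarray(self.ce_mat_f[pos])
        self._u1_pos = self.u1[pos]

    def admissible_rate(self, x: np.ndarray, ce_target: float) -> float:
        """Largest rate whose predicted future Ce peak stays <= ce_target."""
        u0 = self._mat_pos @ x
        r = np.min((ce_target - u0) / self._u1_pos)
        return float(min(max(r, 0.0), self.cfg.max_rate))

    def peak_ce_after(self, x: np.ndarray, rate: float) -> float:
        """Predicted max Ce if ``rate`` is held one interval then input stops."""
        return float(np.max(self.ce_mat_f @ x + rate * self.u1))


def controller_step(
    params: SchniderParams,
    state: PKState,
    ce_target: float,
    cfg: PumpConfig,
    _predictor: _Predictor | None = None,
) -> float:
    """One pump decision: the infusion rate (mg/min) for the next interval.

    Returns 0 whenever any positive input would push the predicted future Ce
    peak above the target (the pause rule); a predicted peak exactly on
    target counts as resumable.  At steady state on target the rate tends to
    CL1·target (metabolic replacement).
    """
    pred = _predictor or _Predictor(params, cfg)
    return pred.admissible_rate(state.vector(), ce_target)


def induction_dose(
    params: SchniderParams,
    state: PKState,
    ce_target: float,
    cfg: PumpConfig | None = None,
) -> float:
    """Smallest dose (mg), delivered at the rate cap, whose peak Ce hits the target.

    Returns 0 when the target does not exceed the state's own predicted Ce
    peak (e.g. already at or above target).
    """
    cfg = cfg or PumpConfig()
    pred = _Predictor(params, cfg)
    x0 = state.vector()
    a4 = params.system_matrix()
    lam, vmat = np.linalg.eig(a4)
    lam, vmat = lam.real, vmat.real
    vinv = np.linalg.inv(vmat)
    b = np.array([1.0, 0.0, 0.0, 0.0])

    def peak_after_bolus(t_bolus_min: float) -> float:
        elt = np.exp(lam * t_bolus_min)
        f = (vmat * elt) @ vinv
        g = (vmat * ((elt - 1.0) / lam)) @ vinv @ b
        return pred.peak_ce_after(f @ x0 + cfg.max_rate * g, 0.0)

    # within tolerance of the state's own peak (e.g. already at steady state
    # on target) no bolus is due
    if peak_after_bolus(0.0) * (1 + cfg.ce_tolerance) >= ce_target:
        return 0.0
    t_hi = 1.0 / SEC_PER_MIN
    while peak_after_bolus(t_hi) < ce_target:
        t_hi *= 2.0
        if t_hi > 60.0:
            raise RuntimeError("induction bolus did not reach target within 60 min")
    t_star = brentq(
        lambda t: peak_after_bolus(t) - ce_target, 0.0, t_hi, xtol=1e-8
    )
    return cfg.max_rate * t_star


def run_tci(
    params: SchniderParams,
    target_schedule: list[tuple[float, float]],
    cfg: PumpConfig,
    duration_s: float,
    initial_state: PKState | None = None,
) -> PumpTrace:
    """Closed-loop pump run over a schedule of (time_s, ce_target) set-points.

    The schedule must start at t=0.  The controller re-predicts from the
    current state at every update interval, so mid-transient re-targeting
    (the study's step-down one minute after the plasma peak) needs no special
    casing.  Returns the dense trace including pump on/off status and the
    active target.
    """
    if not target_schedule or target_schedule[0][0] != 0.0:
        raise ValueError("target schedule must start at t=0")
    times = [t for t, _ in target_schedule]
    if times != sorted(times):
        raise ValueError("target schedule must be sorted")
    if duration_s < times[-1]:
        warnings.warn(
            "duration ends before the last target change; trace truncated",
            stacklevel=2,
        )

    dt = cfg.update_interval
    pred = _Predictor(params, cfg)
    n = int(round(duration_s / dt)) + 1
    t_grid = np.arange(n) * dt
    targets = np.empty(n)
    for start_s, tgt in target_schedule:
        targets[t_grid >= start_s - 1e-9] = tgt

    state0 = initial_state or PKState()
    y = np.array(
        [state0.a1, state0.a2, state0.a3, state0.ce, state0.cumulative_eliminated]
    )
    rate = np.zeros(n)
    out = np.zeros((n, 5))
    out[0] = y
    cum = np.zeros(n)
    cum[0] = state0.cumulative_dose
    f5, g5 = pred.f5, pred.g5
    dt_min = dt / SEC_PER_MIN
    for i in range(n - 1):
        r = pred.admissible_rate(out[i, :4], targets[i])
        rate[i] = r
        out[i + 1] = f5 @ out[i] + r * g5
        cum[i + 1] = cum[i] + r * dt_min
    return PumpTrace(
        t=t_grid + state0.t,
        rate=rate,
        cp=out[:, 0] / params.V1,
        ce=out[:, 3],
        cumulative_dose=cum,
        pump_on=rate > 0,
        target=targets,
    )


def find_pause_end(trace: PumpTrace, from_s: float) -> float:
    """Seconds from ``from_s`` until the pump next delivers drug.

    Returns 0 if the pump is already running at ``from_s`` and the sentinel
    ``NO_RESUME`` (inf) if it never resumes within the trace.
    """
    i0 = trace.index_at(from_s)
    on = np.flatnonzero(trace.rate[i0:] > 0)
    if len(on) == 0:
        return NO_RESUME
    return float(trace.t[i0 + on[0]] - from_s)
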