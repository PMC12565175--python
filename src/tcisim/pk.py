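"""Schnider three-compartment propofol pharmacokinetics with an effect compartment.

The model is the covariate-adjusted mammillary three-compartment system used by
effect-site TCI pumps: a central compartment (V1, plasma), a fast and a slow
peripheral compartment, and a massless effect-site compartment whose
concentration relaxes toward plasma at first-order rate ``ke0``.  Central
volume ``V1``, slow-compartment volume ``V3``, slow inter-compartmental
clearance ``CL3`` and ``ke0`` are demographic-independent constants; ``V2``
and ``CL2`` depend on age; metabolic clearance ``CL1`` depends on weight,
lean body mass (James formula) and height.

All state propagation is done with the closed-form solution of the linear ODE
system under piecewise-constant infusion (matrix exponential of an augmented
system), so results carry no step-size error beyond float round-off.

Units: amounts mg, volumes L, clearances L/min, rate constants 1/min,
concentrations mg/L == mcg/mL, infusion rates mg/min.  Public timestamps are
seconds; internal kinetics run in minutes.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

SEC_PER_MIN = 60.0

# Fixed constants of the covariate model.
V1_L = 4.27
V3_L = 238.0
CL3_L_MIN = 0.836
KE0_PER_MIN = 0.456
TTPE_MIN = 1.6  # time to peak effect after a bolus, minutes (tpeak ke0 variant)

#: effect-compartment variants: "fixed" uses ke0 = 0.456/min for every
#: patient; "tpeak" (the variant implemented in commercial effect-site TCI
#: pumps) solves a patient-specific ke0 so that the effect-site peak after an
#: intravenous bolus occurs at TTPE_MIN minutes.
KE0_MODES = ("tpeak", "fixed")
DEFAULT_KE0_MODE = "tpeak"

AGE_CENTER = 53.0
WEIGHT_CENTER = 77.0
LBM_CENTER = 59.0
HEIGHT_CENTER = 177.0


class InvalidDemographicsError(ValueError):
    """Raised when demographic covariates violate the model's preconditions."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Urgency(str, enum.Enum):
    ELECTIVE = "elective"
    EMERGENCY = "emergency"


@dataclass(frozen=True)
class PatientDemographics:
    """Covariate inputs to the PK model plus surgical context.

    ``incision_to_delivery`` (minutes) is optional until the case is run; the
    study cohort is all-female parturients.
    """

    age: float  # years
    height: float  # cm
    weight: float  # kg
    sex: Sex = Sex.FEMALE
    urgency: Urgency = Urgency.ELECTIVE
    incision_to_delivery: float | None = None  # minutes

    def __post_init__(self) -> None:
        if not (self.age > 0 and self.height > 0 and self.weight > 0):
            raise InvalidDemographicsError(
                f"age/height/weight must be positive, got "
                f"({self.age}, {self.height}, {self.weight})"
            )
        if self.incision_to_delivery is not None and self.incision_to_delivery <= 0:
            raise InvalidDemographicsError("incision_to_delivery must be positive minutes")
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "urgency", Urgency(self.urgency))

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


def lean_body_mass(demo: PatientDemographics) -> float:
    """James lean body mass in kg (sex-specific coefficients)."""
    w, h = demo.weight, demo.height
    if demo.sex is Sex.FEMALE:
        return 1.07 * w - 148.0 * (w / h) ** 2
    return 1.10 * w - 128.0 * (w / h) ** 2


@dataclass(frozen=True)
class SchniderParams:
    """Per-patient compartment volumes, clearances and rate constants."""

    V1: float
    V2: float
    V3: float
    CL1: float
    CL2: float
    CL3: float
    ke0: float
    lbm: float

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "V3", "CL1", "CL2", "CL3", "ke0", "lbm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SchniderParams.{name} must be strictly positive")

    # Micro rate constants are pure functions of volumes and clearances.
    @property
    def k10(self) -> float:
        return self.CL1 / self.V1

    @property
    def k12(self) -> float:
        return self.CL2 / self.V1

    @property
    def k21(self) -> float:
        return self.CL2 / self.V2

    @property
    def k13(self) -> float:
        return self.CL3 / self.V1

    @property
    def k31(self) -> float:
        return self.CL3 / self.V3

    def system_matrix(self) -> np.ndarray:
        """Drift matrix of the state (a1, a2, a3, ce); time unit minutes."""
        k10, k12, k21, k13, k31, ke0 = (
            self.k10, self.k12, self.k21, self.k13, self.k31, self.ke0,
        )
        return np.array(
            [
                [-(k10 + k12 + k13), k21, k31, 0.0],
                [k12, -k21, 0.0, 0.0],
                [k13, 0.0, -k31, 0.0],
                [ke0 / self.V1, 0.0, 0.0, -ke0],
            ]
        )


@lru_cache(maxsize=1024)
def _tpeak_ke0(k10: float, k12: float, k21: float, k13: float, k31: float) -> float:
    """ke0 (1/min) such that the post-bolus effect-site peak falls at TTPE_MIN.

    The effect-site concentration peaks when it crosses the plasma
    concentration (dCe/dt = ke0·(Cp − Ce) = 0), so for each candidate ke0 the
    peak time is located on the impulse response of the full linear system
    and ke0 is solved by bisection.  Larger ke0 means faster equilibration
    and an earlier peak, so the map is monotone.
    """
    from scipy.optimize import brentq

    a3x = np.array(
        [[-(k10 + k12 + k13), k21, k31], [k12, -k21, 0.0], [k13, 0.0, -k31]]
    )
    lam3, v3 = np.linalg.eig(a3x)
    lam3, v3 = lam3.real, v3.real
    w = np.linalg.solve(v3, np.array([1.0, 0.0, 0.0]))
    c_cp = v3[0] * w  # Cp(t)·V1 = Σ c_i e^{λ_i t} after a unit bolus
    t = np.linspace(0.05, 6.0, 1200)
    elt = np.exp(np.outer(t, lam3))

    def ttpe(ke0: float) -> float:
        # Ce impulse response: ke0/V1 · Σ c_i (e^{λ_i t} − e^{−ke0 t})/(λ_i + ke0);
        # terms with λ_i ≈ −ke0 degenerate to c_i · t · e^{λ_i t}
        den = lam3 + ke0
        ok = np.abs(den) > 1e-8
        coef = np.where(ok, c_cp / np.where(ok, den, 1.0), 0.0)
        ce = elt @ coef - np.exp(-ke0 * t) * coef.sum()
        if not ok.all():
            for j in np.flatnonzero(~ok):
                ce = ce + c_cp[j] * t * np.exp(lam3[j] * t)
        i = int(np.argmax(ce))
        if 0 < i < len(t) - 1:  # parabolic refinement of the grid argmax
            y0, y1, y2 = ce[i - 1], ce[i], ce[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                return t[i] + 0.5 * (y0 - y2) / denom * (t[1] - t[0])
        return t[i]

    return float(brentq(lambda k: ttpe(k) - TTPE_MIN, 0.05, 3.0, xtol=1e-8))


def schnider_parameters(
    demo: PatientDemographics, ke0_mode: str = DEFAULT_KE0_MODE
) -> SchniderParams:
    """Covariate parameterization of the Schnider propofol model.

    ``ke0_mode`` selects the effect-compartment variant: ``"tpeak"``
    (default; patient-specific ke0 fixing the post-bolus effect peak at
    1.6 min, as implemented in commercial effect-site pumps) or ``"fixed"``
    (ke0 = 0.456/min for everyone).  Emits a warning (not an error) for
    demographics outside the plausibility envelope the model was estimated
    on.
    """
    if ke0_mode not in KE0_MODES:
        raise ValueError(f"ke0_mode must be one of {KE0_MODES}, got {ke0_mode!r}")
    if not (16.0 <= demo.age <= 100.0):
        warnings.warn(
            f"age {demo.age} y outside the model's plausible range [16, 100]",
            stacklevel=2,
        )
    lbm = lean_body_mass(demo)
    if lbm <= 0:
        raise InvalidDemographicsError(
            f"James lean body mass is non-positive ({lbm:.1f} kg) for "
            f"weight {demo.weight} kg / height {demo.height} cm"
        )
    v2 = 18.9 - 0.391 * (demo.age - AGE_CENTER)
    cl1 = (
        1.89
        + 0.0456 * (demo.weight - WEIGHT_CENTER)
        - 0.0681 * (lbm - LBM_CENTER)
        + 0.0264 * (demo.height - HEIGHT_CENTER)
    )
    cl2 = 1.29 - 0.024 * (demo.age - AGE_CENTER)
    if ke0_mode == "fixed":
        ke0 = KE0_PER_MIN
    else:
        k10 = cl1 / V1_L
        k12 = cl2 / V1_L
        k21 = cl2 / v2
        k13 = CL3_L_MIN / V1_L
        k31 = CL3_L_MIN / V3_L
        ke0 = _tpeak_ke0(k10, k12, k21, k13, k31)
    return SchniderParams(
        V1=V1_L, V2=v2, V3=V3_L, CL1=cl1, CL2=cl2, CL3=CL3_L_MIN,
        ke0=ke0, lbm=lbm,
    )


@dataclass(frozen=True)
class PKState:
    """Instantaneous drug state: compartment amounts plus effect-site concentration."""

    t: float = 0.0  # seconds
    a1: float = 0.0  # mg
    a2: float = 0.0  # mg
    a3: float = 0.0  # mg
    ce: float = 0.0  # mcg/mL
    cumulative_dose: float = 0.0  # mg
    cumulative_eliminated: float = 0.0  # mg

    def cp(self, params: SchniderParams) -> float:
        """Plasma concentration, mcg/mL."""
        return self.a1 / params.V1

    def vector(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.ce])


@lru_cache(maxsize=256)
def _transition(params: SchniderParams, dt_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form propagator over dt for state (a1, a2, a3, ce, eliminated).

    Returns (F, g): y(dt) = F @ y0 + rate * g for constant infusion ``rate``
    (mg/min).  Built from the exponential of the augmented system
    [[A, b], [0, 0]], which yields the zero-input and forced responses in one
    call; the eliminated-mass row integrates k10*a1.
    """
    a4 = params.system_matrix()
    aug = np.zeros((6, 6))
    aug[:4, :4] = a4
    aug[4, 0] = params.k10  # d(eliminated)/dt = k10 * a1
    aug[:4, 5] = [1.0, 0.0, 0.0, 0.0]  # infusion enters the central compartment
    phi = expm(aug * dt_min)
    return phi[:5, :5].copy(), phi[:5, 5].copy()


def advance(
    state: PKState, params: SchniderParams, rate: float, dt: float
) -> PKState:
    """Propagate the state exactly over ``dt`` seconds of constant infusion.

    ``rate`` is mg/min.  Cumulative dose grows by rate*dt/60 and the
    mass-balance invariant (dose == a1+a2+a3+eliminated) is preserved to
    float precision.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if rate < 0:
        raise ValueError(f"infusion rate must be non-negative, got {rate}")
    dt_min = dt / SEC_PER_MIN
    f, g = _transition(params, dt_min)
    y0 = np.array([state.a1, state.a2, state.a3, state.ce, state.cumulative_eliminated])
    y1 = f @ y0 + rate * g
    return PKState(
        t=state.t + dt,
        a1=y1[0], a2=y1[1], a3=y1[2], ce=y1[3],
        cumulative_dose=state.cumulative_dose + rate * dt_min,
        cumulative_eliminated=y1[4],
    )


@dataclass
class PumpTrace:
    """Time-gridded record of a pump run.

    Arrays share one grid (``t`` seconds).  ``rate`` is the mg/min infusion
    rate applied over [t[i], t[i+1]); concentrations and cumulative dose are
    instantaneous values at t[i].
    """

    t: np.ndarray
    rate: np.ndarray
    cp: np.ndarray
    ce: np.ndarray
    cumulative_dose: np.ndarray
    pump_on: np.ndarray = None  # type: ignore[assignment]
    target: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pump_on is None:
            self.pump_on = self.rate > 0
        if self.target is None:
            self.target = np.full_like(self.t, np.nan)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else float("nan")

    def dose_at(self, t_s: float) -> float:
        """Cumulative dose (mg) at time t_s, linearly interpolated between grid points."""
        return float(np.interp(t_s, self.t, self.cumulative_dose))

    def index_at(self, t_s: float) -> int:
        i = int(np.searchsorted(self.t, t_s - 1e-9))
        if i >= len(self.t):
            raise IndexError(f"t={t_s}s beyond trace end {self.t[-1]}s")
        return i

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "rate_mg_min": self.rate,
                "cp": self.cp,
                "ce": self.ce,
                "cum_dose_mg": self.cumulative_dose,
                "pump_on": self.pump_on.astype(int),
                "target": self.target,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_profile(
    params: SchniderParams,
    schedule: list[tuple[float, float]],
    grid_dt: float = 1.0,
    duration: float = 600.0,
) -> PumpTrace:
    """Open-loop simulation of a piecewise-constant rate schedule.

    ``schedule`` is a sorted list of (start_s, rate_mg_min); each rate holds
    until the next entry's start.  An empty schedule gives an all-zero trace.
    Concentrations are exactly linear in the schedule's rates.
    """
    starts = [s for s, _ in schedule]
    if starts != sorted(starts) or len(set(starts)) != len(starts):
        raise ValueError("schedule must be sorted by start time with unique starts")
    n = int(round(duration / grid_dt)) + 1
    t = np.arange(n) * grid_dt
    rate = np.zeros(n)
    for start_s, r in schedule:
        if r < 0:
            raise ValueError("schedule rates must be non-negative")
        rate[t >= start_s - 1e-9] = r

    f, g = _transition(params, grid_dt / SEC_PER_MIN)
    y = np.zeros(5)
    out = np.zeros((n, 5))
    for i in range(1, n):
        y = f @ y + rate[i - 1] * g
        out[i] = y
    cum = np.concatenate([[0.0], np.cumsum(rate[:-1]) * grid_dt / SEC_PER_MIN])
    return PumpTrace(
        t=t,
        rate=rate,
        cp=out[:, 0] / params.V1,
        ce=out[:, 3],
        cumulative_dose=cum,
    )


def mean_cohort_demographics(
    urgency: Urgency = Urgency.ELECTIVE, incision_to_delivery: float | None = None
) -> PatientDemographics:
    """The study cohort's mean parturient: 32.3 y, 164.8 cm, 82.8 kg, female."""
    return PatientDemographics(
        age=32.3, height=164.8, weight=82.8, sex=Sex.FEMALE,
        urgency=urgency, incision_to_delivery=incision_to_delivery,
    )
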