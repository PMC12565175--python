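"""Seeded generator of virtual parturient cohorts.

The generator emulates the demographic and delivery-time structure of the
study population: 50 women, 29 elective / 21 emergency, age 32.3 ± 4.3 y,
height 164.8 ± 5.9 cm, weight 82.8 ± 17.5 kg, incision-to-delivery
7.2 ± 3.3 min (elective) vs 4.7 ± 2.6 min (emergency).  Each variable is an
independent truncated normal; truncation keeps every draw physiologic while
moving the realized moments only slightly.  A single master seed is split
into one child stream per variable so cohorts are bit-reproducible and
individual variables can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .pk import PatientDemographics, Sex, Urgency


class CohortConfigError(ValueError):
    """Raised for infeasible or inconsistent cohort configurations."""


@dataclass(frozen=True)
class Bounds:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise CohortConfigError(f"empty truncation interval [{self.low}, {self.high}]")


@dataclass(frozen=True)
class CohortConfig:
    """Moments, counts and truncation bounds of the virtual cohort."""

    n: int = 50
    n_elective: int = 29
    age_mean: float = 32.3
    age_sd: float = 4.3
    height_mean: float = 164.8
    height_sd: float = 5.9
    weight_mean: float = 82.8
    weight_sd: float = 17.5
    itd_elective_mean: float = 7.2  # incision-to-delivery, minutes
    itd_elective_sd: float = 3.3
    itd_emergency_mean: float = 4.7
    itd_emergency_sd: float = 2.6
    age_bounds: Bounds = field(default_factory=lambda: Bounds(16.0, 55.0))
    height_bounds: Bounds = field(default_factory=lambda: Bounds(140.0, 200.0))
    weight_bounds: Bounds = field(default_factory=lambda: Bounds(40.0, 160.0))
    itd_bounds: Bounds = field(default_factory=lambda: Bounds(0.5, 25.0))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0 or not (0 <= self.n_elective <= self.n):
            raise CohortConfigError(
                f"need 0 <= n_elective ({self.n_elective}) <= n ({self.n}) and n > 0"
            )
        for name in (
            "age_sd", "height_sd", "weight_sd", "itd_elective_sd", "itd_emergency_sd",
        ):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be non-negative")
        for mean_name, sd_name, bounds in (
            ("age_mean", "age_sd", self.age_bounds),
            ("height_mean", "height_sd", self.height_bounds),
            ("weight_mean", "weight_sd", self.weight_bounds),
            ("itd_elective_mean", "itd_elective_sd", self.itd_bounds),
            ("itd_emergency_mean", "itd_emergency_sd", self.itd_bounds),
        ):
            mean, sd = getattr(self, mean_name), getattr(self, sd_name)
            if bounds.high < mean - 4 * sd or bounds.low > mean + 4 * sd:
                raise CohortConfigError(
                    f"truncation bounds [{bounds.low}, {bounds.high}] exclude the "
                    f"mean±4sd region of {mean_name}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("age_bounds", "height_bounds", "weight_bounds", "itd_bounds"):
            d[key] = [d[key]["low"], d[key]["high"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise CohortConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        for key in ("age_bounds", "height_bounds", "weight_bounds", "itd_bounds"):
            if key in d and not isinstance(d[key], Bounds):
                d[key] = Bounds(*d[key])
        return cls(**d)


def default_config(seed: int | None = None) -> CohortConfig:
    """The study population's printed moments with n = 50, 29 elective."""
    return CohortConfig(seed=seed)


def _draw_truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: Bounds
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (bounds.low - mean) / sd, (bounds.high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[PatientDemographics]:
    """Draw one virtual cohort; reproducible given (config, seed).

    ``seed`` overrides ``config.seed``.  The master seed is split into five
    named streams (age, height, weight, elective and emergency delivery
    times) via ``SeedSequence.spawn``.
    """
    master = seed if seed is not None else config.seed
    streams = np.random.SeedSequence(master).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]
    n, n_el = config.n, config.n_elective

    age = _draw_truncnorm(rngs[0], n, config.age_mean, config.age_sd, config.age_bounds)
    height = _draw_truncnorm(
        rngs[1], n, config.height_mean, config.height_sd, config.height_bounds
    )
    weight = _draw_truncnorm(
        rngs[2], n, config.weight_mean, config.weight_sd, config.weight_bounds
    )
    itd_el = _draw_truncnorm(
        rngs[3], n_el, config.itd_elective_mean, config.itd_elective_sd, config.itd_bounds
    )
    itd_em = _draw_truncnorm(
        rngs[4], n - n_el, config.itd_emergency_mean, config.itd_emergency_sd,
        config.itd_bounds,
    )

    cohort = []
    for i in range(n):
        elective = i < n_el
        cohort.append(
            PatientDemographics(
                age=float(age[i]),
                height=float(height[i]),
                weight=float(weight[i]),
                sex=Sex.FEMALE,
                urgency=Urgency.ELECTIVE if elective else Urgency.EMERGENCY,
                incision_to_delivery=float(itd_el[i] if elective else itd_em[i - n_el]),
            )
        )
    return cohort


def cohort_to_frame(cohort: list[PatientDemographics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"p{i:03d}" for i in range(len(cohort))],
            "age_y": [p.age for p in cohort],
            "height_cm": [p.height for p in cohort],
            "weight_kg": [p.weight for p in cohort],
            "sex": [p.sex.value for p in cohort],
            "urgency": [p.urgency.value for p in cohort],
            "incision_to_delivery_min": [p.incision_to_delivery for p in cohort],
        }
    )


def write_cohort_csv(cohort: list[PatientDemographics], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientDemographics]:
    """Read a cohort CSV (columns id, age_y, height_cm, weight_kg, sex, urgency, incision_to_delivery_min)."""
    df = pd.read_csv(path)
    required = {
        "age_y", "height_cm", "weight_kg", "sex", "urgency", "incision_to_delivery_min",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    return [
        PatientDemographics(
            age=row.age_y,
            height=row.height_cm,
            weight=row.weight_kg,
            sex=Sex(row.sex),
            urgency=Urgency(row.urgency),
            incision_to_delivery=row.incision_to_delivery_min,
        )
        for row in df.itertuples()
    ]
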