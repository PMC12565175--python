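"""Study configuration: dataclass, validation, YAML/JSON round-tripping.

The default configuration is the study protocol itself: induction targets
4/6/8 mcg/mL, maintenance 2.5 mcg/mL, step-down 60 s after the plasma peak,
a 30-minute per-case horizon, and the printed cohort moments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .controller import PumpConfig
from .pk import DEFAULT_KE0_MODE, KE0_MODES


class ConfigError(ValueError):
    """Raised for malformed or inconsistent study configurations."""


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pump: PumpConfig = field(default_factory=PumpConfig)
    induction_targets: tuple[float, ...] = (4.0, 6.0, 8.0)
    maintenance_target: float = 2.5
    t0_offset: float = 60.0  # seconds
    horizon: float = 1800.0  # seconds
    ke0_mode: str = DEFAULT_KE0_MODE
    output_dir: str = "results"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ke0_mode not in KE0_MODES:
            raise ConfigError(f"ke0_mode must be one of {KE0_MODES}")
        if not self.induction_targets or min(self.induction_targets) <= 0:
            raise ConfigError("induction_targets must be non-empty and positive")
        if self.maintenance_target >= min(self.induction_targets):
            raise ConfigError(
                f"maintenance_target ({self.maintenance_target}) must be below the "
                f"smallest induction target ({min(self.induction_targets)})"
            )
        if self.t0_offset < 0 or self.horizon <= 0:
            raise ConfigError("t0_offset must be >= 0 and horizon > 0")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "pump": {
                "max_rate_ml_h": self.pump.max_rate_ml_h,
                "drug_mg_ml": self.pump.drug_mg_ml,
                "update_interval_s": self.pump.update_interval,
                "ce_tolerance": self.pump.ce_tolerance,
            },
            "induction_targets": list(self.induction_targets),
            "maintenance_target": self.maintenance_target,
            "t0_offset_s": self.t0_offset,
            "horizon_s": self.horizon,
            "ke0_mode": self.ke0_mode,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


_TOP_KEYS = {
    "cohort", "pump", "induction_targets", "maintenance_target",
    "t0_offset_s", "horizon_s", "ke0_mode", "output_dir", "seed",
}
_PUMP_KEYS = {"max_rate_ml_h", "drug_mg_ml", "update_interval_s", "ce_tolerance"}


def config_from_dict(raw: dict) -> StudyConfig:
    if raw is None:
        raw = {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    pump_raw = dict(raw.get("pump", {}) or {})
    unknown_pump = set(pump_raw) - _PUMP_KEYS
    if unknown_pump:
        raise ConfigError(f"unknown pump config keys: {sorted(unknown_pump)}")
    if "update_interval_s" in pump_raw:
        pump_raw["update_interval"] = pump_raw.pop("update_interval_s")
    try:
        pump = PumpConfig(**pump_raw)
        cohort = CohortConfig.from_dict(raw.get("cohort", {}) or {})
        kwargs = {}
        if "induction_targets" in raw:
            kwargs["induction_targets"] = tuple(raw["induction_targets"])
        for src, dst in (
            ("maintenance_target", "maintenance_target"),
            ("t0_offset_s", "t0_offset"),
            ("horizon_s", "horizon"),
            ("ke0_mode", "ke0_mode"),
            ("output_dir", "output_dir"),
            ("seed", "seed"),
        ):
            if src in raw:
                kwargs[dst] = raw[src]
        return StudyConfig(cohort=cohort, pump=pump, **kwargs)
    except (ValueError, TypeError) as err:
        if isinstance(err, ConfigError):
            raise
        raise ConfigError(str(err)) from err


def load_config(path) -> StudyConfig:
    """Load and validate a YAML (or JSON; JSON is a YAML subset) study config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw or {})


def dump_config(config: StudyConfig, path) -> None:
    path = Path(path)
    text = (
        json.dumps(config.to_dict(), indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(config.to_dict(), sort_keys=False)
    )
    path.write_text(text)
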