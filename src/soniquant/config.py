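"""Schema-validated run configuration (YAML).

A :class:`RunConfig` bundles the controller, plant, band-scheme, and
relaxometry settings plus the run seed. Defaults reproduce the clinical
operating point (0.16/0.39 W, [6, 7.5] dB goal band, gain 0.0167/dB,
3.2/3.9 SD event thresholds, 101.6 ms burst interval, 75 s duration,
relaxivity 4.44 s^-1 mM^-1), so an empty file is a complete, valid
configuration. Unknown keys and out-of-range values are rejected with
field-level messages.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .controller import ControllerConfig
from .emissions import BandScheme
from .plant import PlantConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


class ControllerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    p_start_w: float = 0.16
    p_max_w: float = 0.39
    p_min_w: float = 0.01
    goal_band_db: tuple[float, float] = (6.0, 7.5)
    p_gain_per_db: float = 0.0167
    baseline_duration_s: float = 3.5
    bubble_delay_s: float = 8.0
    control_end_s: float = 25.0
    total_duration_s: float = 75.0
    reduction_fraction: float = 0.25
    burst_length_s: float = 0.005
    burst_interval_s: float = 0.1016
    n_targets: int = 9
    k_subharmonic: float = 3.2
    k_broadband: float = 3.9
    h_setpoint_db: float | None = None
    global_freeze: bool = False

    @model_validator(mode="after")
    def _check(self):
        ControllerConfig(**self.model_dump())  # dataclass enforces invariants
        return self

    def to_dataclass(self) -> ControllerConfig:
        return ControllerConfig(**self.model_dump())


class PlantSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    arrival_time_s: float = 8.0
    arrival_ramp_s: float = 1.0
    clearance_half_life_s: float = 40.0
    harmonic_slope_db_per_kpa: float = 0.0414
    activation_pressure_kpa: float = 0.0
    anchor_power_w: float = 0.16
    anchor_pressure_kpa: float = 119.0
    inertial_threshold_kpa: float = 230.0
    event_sigmoid_width_kpa: float = 8.0
    subharmonic_threshold_kpa: float = 220.0
    event_boost_db: float = 25.0
    band_noise_sd_db: float = 0.5
    floor_db: float = -60.0
    per_target_sensitivity: tuple[float, ...] = (1.0,) * 9

    @model_validator(mode="after")
    def _check(self):
        PlantConfig(**self.model_dump())
        return self

    def to_dataclass(self) -> PlantConfig:
        return PlantConfig(**self.model_dump())


class BandSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fundamental_hz: float = 230e3
    subharmonic_center_hz: float = 115e3
    harmonic_centers_hz: tuple[float, float] = (460e3, 690e3)
    broadband_center_hz: float = 660e3
    narrow_bin_width_hz: float = 10e3
    broadband_bin_width_hz: float = 40e3

    @model_validator(mode="after")
    def _check(self):
        BandScheme(**self.model_dump())
        return self

    def to_dataclass(self) -> BandScheme:
        return BandScheme(**self.model_dump())


class RelaxometrySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    relaxivity_per_s_per_mm: float = 4.44
    molar_mass_g_per_mol: float = 604.71
    tissue_density_g_per_cm3: float = 1.0
    target_radius_mm: float = 1.5
    weighted_fit: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    controller: ControllerSettings = ControllerSettings()
    plant: PlantSettings = PlantSettings()
    bands: BandSettings = BandSettings()
    relaxometry: RelaxometrySettings = RelaxometrySettings()
    seed: int = 0
    verbosity: str = "info"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full default configuration. Unknown keys,
    type errors, or invariant violations raise :class:`ConfigError` with
    field-level messages.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration:\n" + "\n".join(lines)) from None
    except ValueError as exc:
        raise ConfigError(f"{path}: invalid configuration: {exc}") from None


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips via load_config)."""
    data = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
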