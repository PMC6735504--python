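"""Synthetic microbubble cavitation-emissions plant.

The plant stands in for the physical chain transducer -> tissue ->
microbubbles -> hydrophones during closed-loop simulation. It models, per
5 ms burst at a commanded acoustic power:

* pressure at the focus via square-root power scaling anchored at the
  calibrated operating point (0.16 W <-> 119 kPa in water);
* a microbubble bolus: zero concentration before arrival (~8 s after the
  start of the sonication), a smooth ramp to peak, then single-exponential
  circulatory clearance;
* harmonic enhancement linear in the effective in-situ drive
  (pressure x concentration x per-target sensitivity), matching the
  controller's working assumption that harmonic dB grows proportionally
  with pressure amplitude;
* rare stochastic inertial-cavitation events: one latent "instability"
  draw per burst, thresholded through band-specific sigmoids, adding a
  large boost to the subharmonic and/or broadband bands.

All clearance/threshold defaults are synthetic calibrations (no measured
kinetics exist for them); see ``docs/methods.md`` for the rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .emissions import BAND_NAMES, BandScheme, BurstSpectrum, compute_band_powers

__all__ = [
    "PlantConfig",
    "BubbleState",
    "CavitationPlant",
    "power_to_pressure",
    "bubble_concentration",
    "synthesize_waveform",
]

#: Calibrated operating point: acoustic power (W) -> peak pressure (kPa) in water.
DEFAULT_ANCHOR: tuple[float, float] = (0.16, 119.0)


@dataclass(frozen=True)
class PlantConfig:
    """Parameters of the synthetic cavitation plant.

    ``harmonic_slope_db_per_kpa`` is calibrated so that at peak bubble
    concentration the goal-band midpoint (6.75 dB) is reached near 0.30 W,
    i.e. comfortably inside the 0.16-0.39 W operating range.
    ``per_target_sensitivity`` scales the effective drive per target and
    emulates spatial variability (e.g. a location over a large vessel that
    needs less power for the same emissions).
    """

    arrival_time_s: float = 8.0
    arrival_ramp_s: float = 1.0
    clearance_half_life_s: float = 40.0
    harmonic_slope_db_per_kpa: float = 0.0414
    activation_pressure_kpa: float = 0.0
    anchor_power_w: float = DEFAULT_ANCHOR[0]
    anchor_pressure_kpa: float = DEFAULT_ANCHOR[1]
    inertial_threshold_kpa: float = 230.0
    event_sigmoid_width_kpa: float = 8.0
    subharmonic_threshold_kpa: float = 220.0
    event_boost_db: float = 25.0
    band_noise_sd_db: float = 0.5
    floor_db: float = -60.0
    per_target_sensitivity: tuple[float, ...] = (1.0,) * 9

    def __post_init__(self) -> None:
        for name in (
            "arrival_ramp_s",
            "clearance_half_life_s",
            "anchor_power_w",
            "anchor_pressure_kpa",
            "inertial_threshold_kpa",
            "event_sigmoid_width_kpa",
            "subharmonic_threshold_kpa",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arrival_time_s < 0 or self.band_noise_sd_db < 0:
            raise ValueError("arrival_time_s and band_noise_sd_db must be >= 0")
        if any(s <= 0 for s in self.per_target_sensitivity):
            raise ValueError("per_target_sensitivity entries must be positive")

    @classmethod
    def noise_free(cls, **overrides) -> "PlantConfig":
        """Idealized deterministic plant for controller verification.

        No band noise, no stochastic events, and constant peak
        concentration after arrival (infinite clearance half-life), so the
        frozen-phase harmonic level reflects the controller alone.
        """
        defaults = dict(
            band_noise_sd_db=0.0,
            clearance_half_life_s=math.inf,
            inertial_threshold_kpa=1e9,
            subharmonic_threshold_kpa=1e9,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def zero_response(cls, **overrides) -> "PlantConfig":
        """Adversarial plant with no harmonic response at any pressure.

        Drives the proportional controller upward for the whole control
        window; used to verify the power cap.
        """
        defaults = dict(harmonic_slope_db_per_kpa=0.0)
        return cls.noise_free(**{**defaults, **overrides})


@dataclass(frozen=True)
class BubbleState:
    """Relative microbubble concentration (1 at bolus peak) at a time."""

    relative_concentration: float
    time_s: float


def power_to_pressure(
    power_w: float,
    anchor: tuple[float, float] = DEFAULT_ANCHOR,
) -> float:
    """Peak pressure (kPa) at an acoustic power, via square-root scaling.

    Acoustic pressure amplitude scales with the square root of power;
    the curve is anchored at a calibrated (power, pressure) point.
    """
    anchor_power, anchor_pressure = anchor
    if power_w <= 0:
        raise ValueError("power must be positive")
    if anchor_power <= 0:
        raise ValueError("anchor power must be positive")
    return anchor_pressure * math.sqrt(power_w / anchor_power)


def bubble_concentration(t: float, config: PlantConfig) -> float:
    """Relative bolus concentration at time ``t`` seconds.

    Zero before arrival, a raised-cosine ramp to the peak over
    ``arrival_ramp_s``, then exponential decay with the configured
    circulatory half-life.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    t0 = config.arrival_time_s
    if t < t0:
        return 0.0
    ramp = config.arrival_ramp_s
    if t < t0 + ramp:
        return 0.5 * (1 - math.cos(math.pi * (t - t0) / ramp))
    if math.isinf(config.clearance_half_life_s):
        return 1.0
    return math.exp(-math.log(2) * (t - t0 - ramp) / config.clearance_half_life_s)


class CavitationPlant:
    """Burst-response model mapping commanded power to a burst spectrum."""

    def __init__(self, config: PlantConfig | None = None):
        self.config = config or PlantConfig()

    def respond(
        self,
        target_index: int,
        power_w: float,
        time_s: float,
        rng: np.random.Generator,
    ) -> BurstSpectrum:
        """Simulate one burst's band powers at a commanded acoustic power.

        The harmonic bands rise linearly (in dB) with the effective drive;
        a single latent uniform draw per burst is thresholded through the
        subharmonic and broadband sigmoids so both event types co-occur at
        unstable bursts, mirroring their spatial co-localization in vivo.
        """
        cfg = self.config
        if not 0 <= target_index < len(cfg.per_target_sensitivity):
            raise ValueError(f"target_index {target_index} out of range")
        pressure = power_to_pressure(power_w, (cfg.anchor_power_w, cfg.anchor_pressure_kpa))
        conc = bubble_concentration(time_s, cfg)
        drive = pressure * conc * cfg.per_target_sensitivity[target_index]
        enhancement = cfg.harmonic_slope_db_per_kpa * max(drive - cfg.activation_pressure_kpa, 0.0)

        noise = rng.normal(0.0, cfg.band_noise_sd_db, size=len(BAND_NAMES))
        bands = {name: cfg.floor_db + float(n) for name, n in zip(BAND_NAMES, noise)}
        bands["harmonic2"] += enhancement
        bands["harmonic3"] += enhancement

        u = rng.uniform()
        p_sub = float(expit((drive - cfg.subharmonic_threshold_kpa) / cfg.event_sigmoid_width_kpa))
        p_bb = float(expit((drive - cfg.inertial_threshold_kpa) / cfg.event_sigmoid_width_kpa))
        if u < p_sub:
            bands["subharmonic"] += cfg.event_boost_db
        if u < p_bb:
            bands["broadband"] += cfg.event_boost_db

        return BurstSpectrum(
            band_power_db=bands,
            target_index=target_index,
            time_s=max(time_s, 0.0),
            applied_power_w=power_w,
        )

    def event_probabilities(self, target_index: int, power_w: float, time_s: float) -> tuple[float, float]:
        """(subharmonic, broadband) event probability for a burst — the
        deterministic Bernoulli rates behind :meth:`respond`."""
        cfg = self.config
        pressure = power_to_pressure(power_w, (cfg.anchor_power_w, cfg.anchor_pressure_kpa))
        drive = pressure * bubble_concentration(time_s, cfg) * cfg.per_target_sensitivity[target_index]
        return (
            float(expit((drive - cfg.subharmonic_threshold_kpa) / cfg.event_sigmoid_width_kpa)),
            float(expit((drive - cfg.inertial_threshold_kpa) / cfg.event_sigmoid_width_kpa)),
        )


def synthesize_waveform(
    bands: BurstSpectrum | dict[str, float],
    sample_rate: float = 4e6,
    duration_s: float = 0.005,
    scheme: BandScheme | None = None,
    noise_floor_db: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a band table back into a sampled pressure trace.

    Each band is realized as a pure tone at its center frequency with
    amplitude ``sqrt(2 * 10^(dB/10))`` so that
    :func:`~soniquant.emissions.compute_band_powers` recovers the requested
    band powers (round-trip within 0.5 dB). Optional white noise realizes
    an out-of-band floor for end-to-end pipeline tests.

    Raises ``ValueError`` if ``duration_s`` spans fewer than two periods of
    the lowest band center.
    """
    scheme = scheme or BandScheme()
    table = bands.band_power_db if isinstance(bands, BurstSpectrum) else dict(bands)
    centers = scheme.band_centers()
    lowest = min(centers[b] for b in table)
    if duration_s < 2.0 / lowest:
        raise ValueError(
            f"duration {duration_s:g} s shorter than two periods of the lowest band ({lowest:g} Hz)"
        )
    for band, db in table.items():
        if not np.isfinite(db):
            raise ValueError(f"non-finite power for band {band!r}")

    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for band, db in table.items():
        amp = math.sqrt(2.0 * 10 ** (db / 10))
        x += amp * np.sin(2 * math.pi * centers[band] * t)
    if noise_floor_db is not None:
        rng = rng or np.random.default_rng(0)
        x += rng.normal(0.0, math.sqrt(10 ** (noise_floor_db / 10)), size=n)
    return x
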