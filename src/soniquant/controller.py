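"""Closed-loop per-target acoustic power control.

During a 75 s volumetric sonication, 5 ms bursts are interleaved across 9
targets every 101.6 ms (per-target pulse repetition frequency ~1.1 Hz).
Each target's acoustic power is modulated independently:

* **fixed_pre** (t < 8 s): power held at the 0.16 W starting level while
  the microbubble bolus reaches the brain; these bursts double as the
  early-burst noise-floor measurement for the event thresholds.
* **controlling** (8 s <= t < 25 s): a proportional controller steers the
  harmonic enhancement H (mean dB elevation of the 2nd/3rd harmonics over
  the pre-sonication floor) into the goal band [6.0, 7.5] dB. H is assumed
  proportional to pressure amplitude, and pressure scales with the square
  root of power, so the update acts multiplicatively on sqrt(power):

      a <- a * (1 + P_gain * (H_set - H)),   power = a^2

  with P_gain = 0.0167 per dB and H_set the goal-band midpoint, applied
  only when H falls outside the band. Power never exceeds 0.39 W.
* **frozen** (t >= 25 s): since microbubbles clear from circulation, the
  controller never raises power after 25 s; it freezes each target at the
  mean power of all its goal-band bursts (or holds the current power if
  the goal was never reached).

Safety rule: if a subharmonic or broadband emission event is detected on a
target's burst, that target's power is immediately reduced by 25% and
fixed for the remainder of the sonication; at most one reduction occurs.

The published description fixes the gain, the proportionality assumption,
and the goal band but not the algebraic form of the update; the law above
is a reconstruction from those constraints and is config-swappable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .emissions import (
    BurstSpectrum,
    DetectionResult,
    NoiseFloor,
    calibrate_noise_floor,
    detect_events,
)

__all__ = [
    "ControllerConfig",
    "TargetState",
    "SonicationLog",
    "proportional_update",
    "safety_reduce",
    "end_of_control_freeze",
    "run_sonication",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable parameters of the sonication controller.

    Defaults reproduce the clinical-system operating point: 0.16 W start,
    0.39 W cap, [6.0, 7.5] dB goal band, gain 0.0167 per dB, 3.5 s noise
    floor, 8 s bubble delay, control until 25 s, 75 s total, 25% safety
    reduction, 5 ms bursts every 101.6 ms over 9 targets, event thresholds
    at 3.2 (subharmonic) and 3.9 (broadband) SDs.
    """

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

    def __post_init__(self) -> None:
        if not 0 < self.p_start_w <= self.p_max_w:
            raise ValueError("need 0 < p_start_w <= p_max_w")
        if not 0 < self.p_min_w <= self.p_start_w:
            raise ValueError("need 0 < p_min_w <= p_start_w")
        lo, hi = self.goal_band_db
        if not lo < hi:
            raise ValueError("goal band lower edge must be below upper edge")
        if not 0 < self.reduction_fraction < 1:
            raise ValueError("reduction_fraction must be in (0, 1)")
        if not self.bubble_delay_s < self.control_end_s < self.total_duration_s:
            raise ValueError("need bubble_delay_s < control_end_s < total_duration_s")
        if self.burst_interval_s <= 0 or self.burst_length_s <= 0 or self.n_targets < 1:
            raise ValueError("burst timing and target count must be positive")

    @property
    def h_setpoint(self) -> float:
        """Setpoint for the proportional error: goal-band midpoint."""
        if self.h_setpoint_db is not None:
            return self.h_setpoint_db
        lo, hi = self.goal_band_db
        return 0.5 * (lo + hi)


PHASE_FIXED_PRE = "fixed_pre"
PHASE_CONTROLLING = "controlling"
PHASE_FROZEN = "frozen"


@dataclass
class TargetState:
    """Mutable per-target controller state across a sonication."""

    target_index: int
    power_w: float
    phase: str = PHASE_FIXED_PRE
    reduced: bool = False
    goal_hit_powers: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.power_w <= 0:
            raise ValueError("power_w must be positive")


def proportional_update(
    state: TargetState, detection: DetectionResult, config: ControllerConfig
) -> TargetState:
    """One proportional step for a controlling target (no events raised).

    If H lies inside the goal band the power is held and recorded as a
    goal hit (these powers feed the end-of-control freeze); otherwise the
    pressure-domain update is applied and the result clamped to
    (0, p_max_w]. A non-finite H skips the burst with the power held.
    """
    h = detection.harmonic_enhancement_db
    if not math.isfinite(h):
        logger.warning(
            "target %d: non-finite harmonic enhancement; burst skipped, power held",
            state.target_index,
        )
        return state
    lo, hi = config.goal_band_db
    if lo <= h <= hi:
        state.goal_hit_powers.append(state.power_w)
        return state
    amp = math.sqrt(state.power_w) * (1.0 + config.p_gain_per_db * (config.h_setpoint - h))
    if amp <= 0:
        new_power = config.p_min_w
    else:
        new_power = min(max(amp * amp, config.p_min_w), config.p_max_w)
    state.power_w = new_power
    return state


def safety_reduce(state: TargetState, config: ControllerConfig) -> TargetState:
    """Apply the one-shot 25% safety reduction and freeze the target.

    Triggered by a subharmonic or broadband detection on this target's
    burst. Idempotent: once a target has been reduced it never changes
    again, so consecutive flagged bursts cause a single reduction.
    """
    if state.reduced:
        return state
    state.power_w = max((1.0 - config.reduction_fraction) * state.power_w, 0.0)
    state.phase = PHASE_FROZEN
    state.reduced = True
    return state


def end_of_control_freeze(state: TargetState, config: ControllerConfig) -> TargetState:
    """Freeze a target when the sonication clock crosses the control end.

    Power is set to the arithmetic mean of all powers at goal-band bursts;
    if the goal was never achieved the current power is held (conservative
    fallback — the published procedure is silent on this case).
    """
    if state.phase == PHASE_FROZEN:
        return state
    if state.goal_hit_powers:
        state.power_w = float(np.mean(state.goal_hit_powers))
    state.phase = PHASE_FROZEN
    return state


@dataclass
class SonicationLog:
    """Full closed-loop trajectory of one volumetric sonication.

    ``records`` has one row per burst: burst_index, time_s, target_index,
    power_w (commanded), phase, H and event flags (NaN/False before the
    floors exist), and the raw band powers.
    """

    records: pd.DataFrame
    floor_pre: NoiseFloor | None
    floor_early: NoiseFloor | None
    config: ControllerConfig
    controller_enabled: bool
    seed: int
    error: str | None = None

    def summary(self) -> dict:
        """Deterministic end-of-run summary of powers and event counts."""
        rec = self.records
        frozen = rec[rec["time_s"] >= self.config.control_end_s]
        per_target_end = {
            int(t): float(g["power_w"].iloc[-1]) for t, g in rec.groupby("target_index")
        }
        n_detected = rec["subharmonic_flag"].notna().sum()
        n_sub = int(rec["subharmonic_flag"].eq(True).sum())
        n_bb = int(rec["broadband_flag"].eq(True).sum())
        return {
            "seed": self.seed,
            "controller_enabled": self.controller_enabled,
            "n_bursts": int(len(rec)),
            "end_power_w_per_target": per_target_end,
            "max_power_w": float(rec["power_w"].max()),
            "mean_power_w_frozen_phase": float(frozen["power_w"].mean()) if len(frozen) else None,
            "mean_h_db_frozen_phase": (
                float(frozen["h_db"].mean()) if len(frozen) and frozen["h_db"].notna().any() else None
            ),
            "n_subharmonic_events": n_sub,
            "n_broadband_events": n_bb,
            "fraction_bursts_flagged": (
                float(
                    (rec["subharmonic_flag"].eq(True) | rec["broadband_flag"].eq(True)).sum()
                    / n_detected
                )
                if n_detected
                else 0.0
            ),
            "error": self.error,
        }

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_hdf(self, path) -> None:
        """Write the per-burst records as flat datasets in an HDF5 file."""
        import h5py

        with h5py.File(path, "w") as f:
            for col in self.records.columns:
                data = self.records[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                elif data.dtype == bool:
                    data = data.astype(np.uint8)
                f.create_dataset(col, data=data)
            f.attrs["seed"] = self.seed
            f.attrs["controller_enabled"] = self.controller_enabled


def run_sonication(
    plant,
    config: ControllerConfig | None = None,
    *,
    controller_enabled: bool = True,
    seed: int = 0,
    fixed_power_w: float | None = None,
) -> SonicationLog:
    """Simulate one volumetric sonication against a plant model.

    Bursts are fired every ``burst_interval_s``, cycling targets 0..n-1.
    A 3.5 s pre-sonication ensemble calibrates the reference floor for H;
    the bursts before the bubble-delay gate calibrate the early floor for
    the event thresholds. With ``controller_enabled=False`` the power is
    held at ``fixed_power_w`` (default ``p_start_w``) throughout, which
    reproduces the uncontrolled exposure condition.

    All randomness flows from ``seed`` through named per-target streams,
    so identical seeds produce bit-identical logs and one target's noise
    never perturbs another's trajectory.
    """
    config = config or ControllerConfig()
    n_targets = config.n_targets
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_targets + 1)
    baseline_rng = np.random.default_rng(children[0])
    target_rngs = [np.random.default_rng(c) for c in children[1:]]

    # pre-sonication noise floor: baseline ensemble at zero bubble concentration
    n_base = max(2, int(round(config.baseline_duration_s / config.burst_interval_s)))
    baseline = [
        plant.respond(k % n_targets, config.p_start_w, 0.0, baseline_rng) for k in range(n_base)
    ]
    floor_pre = calibrate_noise_floor(baseline, source="pre_sonication")

    states = [TargetState(i, config.p_start_w) for i in range(n_targets)]
    fixed_power = fixed_power_w if fixed_power_w is not None else config.p_start_w

    n_bursts = int(math.floor(config.total_duration_s / config.burst_interval_s))
    early_spectra: list[BurstSpectrum] = []
    floor_early: NoiseFloor | None = None
    rows: list[dict] = []
    error: str | None = None

    for k in range(n_bursts):
        t = k * config.burst_interval_s
        tgt = k % n_targets
        st = states[tgt]

        if controller_enabled:
            if t >= config.bubble_delay_s and st.phase == PHASE_FIXED_PRE:
                st.phase = PHASE_CONTROLLING
            if t >= config.control_end_s and st.phase == PHASE_CONTROLLING:
                end_of_control_freeze(st, config)
            power = st.power_w
        else:
            power = fixed_power

        try:
            spectrum = plant.respond(tgt, power, t, target_rngs[tgt])
        except Exception as exc:  # plant failure mid-run: return partial log
            error = f"plant failure at burst {k} (t={t:.3f} s): {exc}"
            logger.error(error)
            break
        spectrum.burst_index = k

        if t < config.bubble_delay_s:
            early_spectra.append(spectrum)
        elif floor_early is None:
            floor_early = calibrate_noise_floor(early_spectra, source="early_burst")

        detection = None
        if floor_early is not None:
            detection = detect_events(
                spectrum, floor_early, floor_pre, config.k_subharmonic, config.k_broadband
            )

        if controller_enabled and detection is not None and st.phase != PHASE_FIXED_PRE:
            if detection.subharmonic_flag or detection.broadband_flag:
                if config.global_freeze:
                    for other in states:
                        safety_reduce(other, config)
                else:
                    safety_reduce(st, config)
            elif st.phase == PHASE_CONTROLLING:
                proportional_update(st, detection, config)

        rows.append(
            {
                "burst_index": k,
                "time_s": t,
                "target_index": tgt,
                "power_w": power,
                "phase": st.phase if controller_enabled else "fixed",
                "h_db": detection.harmonic_enhancement_db if detection else float("nan"),
                "subharmonic_flag": detection.subharmonic_flag if detection else None,
                "broadband_flag": detection.broadband_flag if detection else None,
                "reduced": st.reduced,
                **{f"power_db_{b}": spectrum.band_power_db[b] for b in spectrum.band_power_db},
            }
        )

    records = pd.DataFrame(rows)
    return SonicationLog(
        records=records,
        floor_pre=floor_pre,
        floor_early=floor_early,
        config=config,
        controller_enabled=controller_enabled,
        seed=seed,
        error=error,
    )
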