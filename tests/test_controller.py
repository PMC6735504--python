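"""Closed-loop controller: update law, safety logic, full trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from soniquant.controller import (
    ControllerConfig,
    TargetState,
    end_of_control_freeze,
    proportional_update,
    run_sonication,
    safety_reduce,
)
from soniquant.emissions import DetectionResult
from soniquant.plant import CavitationPlant, PlantConfig

CFG = ControllerConfig()


def det(h, sub=False, bb=False):
    return DetectionResult(harmonic_enhancement_db=h, subharmonic_flag=sub, broadband_flag=bb)


class TestProportionalUpdate:
    def test_in_band_holds_power_and_records_goal_hit(self):
        st = TargetState(0, 0.25, phase="controlling")
        proportional_update(st, det(6.75), CFG)
        assert st.power_w == 0.25
        assert st.goal_hit_powers == [0.25]

    def test_zero_enhancement_raises_power_within_cap(self):
        st = TargetState(0, 0.16, phase="controlling")
        proportional_update(st, det(0.0), CFG)
        assert 0.16 < st.power_w <= 0.39

    def test_persistent_zero_response_saturates_at_cap(self):
        """Iterating against H=0 follows the closed-form monotone sequence
        p_n = min(p0 * (1 + g*H_set)^(2n), p_max) and then sticks at the cap."""
        st = TargetState(0, 0.16, phase="controlling")
        g, h_set = CFG.p_gain_per_db, CFG.h_setpoint
        for n in range(1, 30):
            proportional_update(st, det(0.0), CFG)
            expected = min(0.16 * (1 + g * h_set) ** (2 * n), 0.39)
            assert st.power_w == pytest.approx(expected, rel=1e-12)
        assert st.power_w == 0.39

    def test_overshoot_steps_power_down(self):
        st = TargetState(0, 0.3, phase="controlling")
        proportional_update(st, det(10.0), CFG)
        assert st.power_w < 0.3

    def test_non_finite_h_holds_power(self, caplog):
        st = TargetState(0, 0.2, phase="controlling")
        with caplog.at_level("WARNING"):
            proportional_update(st, det(float("nan")), CFG)
        assert st.power_w == 0.2
        assert "skipped" in caplog.text


class TestSafetyReduce:
    @pytest.mark.parametrize("power,expected", [(0.32, 0.24), (0.16, 0.12)])
    def test_reduces_by_25_percent_and_freezes(self, power, expected):
        st = TargetState(0, power, phase="controlling")
        safety_reduce(st, CFG)
        assert st.power_w == pytest.approx(expected)
        assert st.phase == "frozen" and st.reduced

    def test_consecutive_flags_reduce_only_once(self):
        st = TargetState(0, 0.32, phase="controlling")
        safety_reduce(st, CFG)
        safety_reduce(st, CFG)
        assert st.power_w == pytest.approx(0.24)


class TestEndOfControlFreeze:
    def test_freezes_at_mean_goal_power(self):
        st = TargetState(0, 0.30, phase="controlling", goal_hit_powers=[0.30, 0.34])
        end_of_control_freeze(st, CFG)
        assert st.power_w == pytest.approx(0.32)
        assert st.phase == "frozen"

    def test_goal_never_hit_holds_current_power(self):
        st = TargetState(0, 0.22, phase="controlling")
        end_of_control_freeze(st, CFG)
        assert st.power_w == 0.22 and st.phase == "frozen"

    def test_single_goal_hit(self):
        st = TargetState(0, 0.36, phase="controlling", goal_hit_powers=[0.38])
        end_of_control_freeze(st, CFG)
        assert st.power_w == pytest.approx(0.38)


class TestRunSonication:
    def test_identical_seeds_give_bit_identical_logs(self):
        a = run_sonication(CavitationPlant(), seed=11).records
        b = run_sonication(CavitationPlant(), seed=11).records
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    @pytest.mark.parametrize(
        "plant_cfg",
        [PlantConfig(), PlantConfig.noise_free(), PlantConfig.zero_response()],
        ids=["stochastic", "noise_free", "zero_response"],
    )
    def test_power_always_in_clamp(self, plant_cfg):
        rec = run_sonication(CavitationPlant(plant_cfg), seed=3).records
        assert (rec.power_w > 0).all()
        assert (rec.power_w <= CFG.p_max_w + 1e-12).all()

    def test_no_modulation_before_bubble_delay(self):
        rec = run_sonication(CavitationPlant(), seed=4).records
        assert (rec[rec.time_s < CFG.bubble_delay_s].power_w == CFG.p_start_w).all()

    def test_no_power_increase_after_control_end(self):
        rec = run_sonication(CavitationPlant(), seed=5).records
        for _, g in rec[rec.time_s >= CFG.control_end_s].groupby("target_index"):
            assert (np.diff(g.power_w) <= 1e-12).all()

    def test_burst_schedule_cycles_targets(self):
        rec = run_sonication(CavitationPlant(PlantConfig.noise_free()), seed=0).records
        assert (rec.target_index == rec.burst_index % 9).all()
        assert np.allclose(np.diff(rec.time_s), CFG.burst_interval_s)

    def test_per_target_independence(self):
        """Perturbing one target's plant response leaves the others' power
        trajectories bit-identical (independent per-target noise streams)."""
        base = PlantConfig()
        sens = list(base.per_target_sensitivity)
        sens[0] = 0.5
        perturbed = PlantConfig(per_target_sensitivity=tuple(sens))
        ra = run_sonication(CavitationPlant(base), seed=21).records
        rb = run_sonication(CavitationPlant(perturbed), seed=21).records
        for tgt in range(1, 9):
            pd.testing.assert_series_equal(
                ra[ra.target_index == tgt].power_w.reset_index(drop=True),
                rb[rb.target_index == tgt].power_w.reset_index(drop=True),
                check_exact=True,
            )

    def test_noise_free_plant_settles_inside_goal_band(self):
        log = run_sonication(CavitationPlant(PlantConfig.noise_free()), seed=1)
        frozen = log.records[log.records.time_s >= CFG.control_end_s]
        lo, hi = CFG.goal_band_db
        assert lo <= frozen.h_db.mean() <= hi

    def test_steady_power_matches_analytic_goal_interval(self):
        """With a dead-band law the fixed-point set is the power interval
        mapping onto the goal band; the settle point must land in it."""
        cfg = PlantConfig.noise_free()
        log = run_sonication(CavitationPlant(cfg), seed=0)
        rec = log.records
        steady = rec[rec.time_s >= CFG.control_end_s].groupby("target_index").power_w.first()

        def power_for_h(h):
            pressure = h / cfg.harmonic_slope_db_per_kpa
            return cfg.anchor_power_w * (pressure / cfg.anchor_pressure_kpa) ** 2

        lo, hi = CFG.goal_band_db
        assert (steady >= power_for_h(lo) * 0.98).all()
        assert (steady <= power_for_h(hi) * 1.02).all()

    def test_detection_event_reduces_once_then_freezes(self):
        """Each flagged target shows exactly one 25% cut, then constant power."""
        risky = PlantConfig(
            inertial_threshold_kpa=150.0,
            subharmonic_threshold_kpa=145.0,
            event_sigmoid_width_kpa=5.0,
            clearance_half_life_s=math.inf,
        )
        rec = run_sonication(CavitationPlant(risky), seed=2).records
        flagged = rec.subharmonic_flag.eq(True) | rec.broadband_flag.eq(True)
        assert flagged.any(), "fixture must raise at least one event"
        for _, g in rec.groupby("target_index"):
            g = g.reset_index(drop=True)
            f = (g.subharmonic_flag.eq(True) | g.broadband_flag.eq(True))
            if not f.any():
                continue
            i = int(f.idxmax())
            after = g.power_w.iloc[i + 1 :]
            if len(after):
                assert after.iloc[0] == pytest.approx(0.75 * g.power_w.iloc[i])
                assert np.allclose(after, after.iloc[0])

    def test_controller_off_holds_fixed_power_and_sustains_wideband(self):
        """Uncontrolled high-power exposure of a fragile plant shows
        persistent wideband emission — the hallmark of inertial cavitation."""
        risky = PlantConfig(
            inertial_threshold_kpa=150.0,
            subharmonic_threshold_kpa=145.0,
            event_sigmoid_width_kpa=5.0,
            clearance_half_life_s=math.inf,
        )
        log = run_sonication(
            CavitationPlant(risky), seed=2, controller_enabled=False, fixed_power_w=0.39
        )
        rec = log.records
        assert (rec.power_w == 0.39).all()
        post = rec[rec.time_s >= 9.0]
        assert post.broadband_flag.eq(True).mean() > 0.5

    def test_plant_failure_returns_partial_log_with_marker(self):
        class FailingPlant(CavitationPlant):
            def respond(self, tgt, p, t, rng):
                if t > 30:
                    raise RuntimeError("hydrophone dropout")
                return super().respond(tgt, p, t, rng)

        log = run_sonication(FailingPlant(PlantConfig.noise_free()), seed=0)
        assert log.error is not None and "dropout" in log.error
        assert 0 < len(log.records) < 738

    def test_summary_reports_per_target_end_powers(self):
        log = run_sonication(CavitationPlant(PlantConfig.noise_free()), seed=1)
        s = log.summary()
        assert set(s["end_power_w_per_target"]) == set(range(9))
        assert s["n_bursts"] == 738
        assert s["error"] is None


class TestConfigInvariants:
    def test_goal_band_order_enforced(self):
        with pytest.raises(ValueError, match="goal band"):
            ControllerConfig(goal_band_db=(7.5, 6.0))

    def test_start_above_cap_rejected(self):
        with pytest.raises(ValueError, match="p_max"):
            ControllerConfig(p_start_w=0.5, p_max_w=0.39)

    def test_phase_schedule_ordering_enforced(self):
        with pytest.raises(ValueError, match="control_end"):
            ControllerConfig(control_end_s=80.0)

    def test_setpoint_defaults_to_band_midpoint(self):
        assert ControllerConfig().h_setpoint == pytest.approx(6.75)
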