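"""Configuration loading, report writing, and CLI smoke tests."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from soniquant.cli import main
from soniquant.config import ConfigError, RunConfig, load_config, save_config
from soniquant.phantoms import make_growth_table, make_survival_table
from soniquant.report import build_report, write_report


class TestConfig:
    def test_empty_file_yields_all_defaults(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        cfg = load_config(p)
        assert cfg.controller.p_start_w == 0.16
        assert cfg.controller.p_max_w == 0.39
        assert cfg.controller.goal_band_db == (6.0, 7.5)
        assert cfg.controller.p_gain_per_db == 0.0167
        assert cfg.controller.k_subharmonic == 3.2
        assert cfg.controller.k_broadband == 3.9
        assert cfg.controller.burst_interval_s == 0.1016
        assert cfg.controller.total_duration_s == 75.0
        assert cfg.relaxometry.relaxivity_per_s_per_mm == 4.44

    def test_cap_below_start_rejected_with_field_message(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("controller:\n  p_max_w: 0.1\n")
        with pytest.raises(ConfigError, match="p_max"):
            load_config(p)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "unknown.yaml"
        p.write_text("controller:\n  warp_drive: 9\n")
        with pytest.raises(ConfigError, match="warp_drive"):
            load_config(p)

    def test_round_trip(self, tmp_path):
        cfg = RunConfig(seed=42)
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        assert load_config(p) == cfg

    def test_dataclass_conversion(self):
        cfg = RunConfig()
        assert cfg.controller.to_dataclass().p_max_w == 0.39
        assert cfg.plant.to_dataclass().anchor_pressure_kpa == 119.0
        assert cfg.bands.to_dataclass().fundamental_hz == 230e3


class TestReport:
    def test_partial_report_omits_missing_sections(self):
        text, doc = build_report(sonication_summary={"max_power_w": 0.39})
        assert "sonication" in doc and "growth" not in doc
        assert "max_power_w" in text

    def test_byte_identical_for_identical_inputs(self, tmp_path):
        sections = dict(
            sonication_summary={"max_power_w": 0.2412345678},
            survival={"median": 41.5},
        )
        t1, j1 = write_report(tmp_path / "a", **sections)
        t2, j2 = write_report(tmp_path / "b", **sections)
        assert t1.read_bytes() == t2.read_bytes()
        assert j1.read_bytes() == j2.read_bytes()

    def test_json_is_machine_readable(self, tmp_path):
        _, j = write_report(tmp_path / "r", survival={"median": 41.5})
        assert json.loads(j.read_text())["survival"]["median"] == 41.5


@pytest.fixture(scope="module")
def runner():
    return CliRunner()


class TestCli:
    def test_simulate_writes_log_and_summary(self, runner, tmp_path):
        out = tmp_path / "log.csv"
        summary = tmp_path / "summary.json"
        res = runner.invoke(
            main, ["simulate", "--seed", "1", "--out", str(out), "--summary", str(summary)]
        )
        assert res.exit_code == 0, res.output
        rec = pd.read_csv(out)
        assert len(rec) == 738
        s = json.loads(summary.read_text())
        assert s["max_power_w"] <= 0.39

    def test_simulate_hdf_output(self, runner, tmp_path):
        import h5py

        out = tmp_path / "log.h5"
        res = runner.invoke(main, ["simulate", "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        with h5py.File(out) as f:
            assert f["power_w"].shape == (738,)

    def test_simulate_invalid_config_exits_1(self, runner, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("controller:\n  p_max_w: 0.01\n")
        res = runner.invoke(
            main,
            ["simulate", "--config", str(bad), "--out", str(tmp_path / "x.csv")],
        )
        assert res.exit_code == 1

    @pytest.mark.parametrize("kind", ["emissions", "mri", "outcomes"])
    def test_make_fixtures(self, runner, tmp_path, kind):
        res = runner.invoke(
            main, ["make-fixtures", "--kind", kind, "--out", str(tmp_path), "--seed", "0"]
        )
        assert res.exit_code == 0, res.output
        assert any(tmp_path.iterdir())

    def test_fit_r1_and_quantify_gad(self, runner, tmp_path):
        import nibabel as nib

        from soniquant.phantoms import make_relaxometry_series

        truth = np.full((10, 10, 1), 0.6)
        truth[6:, :, :] = 0.9
        series = make_relaxometry_series(truth, noise_fraction=0.0)
        nib.save(
            nib.Nifti1Image(np.moveaxis(series.signal, 0, -1).astype(np.float32), np.eye(4)),
            tmp_path / "series.nii.gz",
        )
        r1_out = tmp_path / "r1.nii.gz"
        res = runner.invoke(
            main,
            [
                "fit-r1",
                "--series", str(tmp_path / "series.nii.gz"),
                "--trs", ",".join(str(t) for t in series.tr_values_s),
                "--out", str(r1_out),
            ],
        )
        assert res.exit_code == 0, res.output
        fitted = np.asarray(nib.load(r1_out).dataobj)
        assert fitted[0, 0, 0] == pytest.approx(0.6, rel=1e-3)

        nib.save(
            nib.Nifti1Image(np.ones((10, 10, 1), dtype=np.int16), np.eye(4)),
            tmp_path / "labels.nii.gz",
        )
        pd.DataFrame([[7.0, 5.0, 0.0]]).to_csv(tmp_path / "targets.csv", index=False)
        res = runner.invoke(
            main,
            [
                "quantify-gad",
                "--r1-map", str(r1_out),
                "--labels", str(tmp_path / "labels.nii.gz"),
                "--targets", str(tmp_path / "targets.csv"),
                "--midline", "4.5",
                "--out", str(tmp_path / "rois.csv"),
            ],
        )
        assert res.exit_code == 0, res.output
        rois = pd.read_csv(tmp_path / "rois.csv")
        agg = rois[rois.structure == "aggregate"].iloc[0]
        assert agg.delta_r1_per_s == pytest.approx(0.3, abs=0.01)

    def test_fit_growth(self, runner, tmp_path):
        tbl = pd.concat(
            [
                make_growth_table(doubling_days=3.5, group="control", seed=1),
                make_growth_table(doubling_days=7.0, group="fus_drug", seed=2),
            ]
        )
        tbl.rename(columns={"volume_mm3": "volume_mm3"}).to_csv(
            tmp_path / "growth.csv", index=False
        )
        res = runner.invoke(
            main,
            ["fit-growth", "--table", str(tmp_path / "growth.csv"), "--out", str(tmp_path / "td.csv")],
        )
        assert res.exit_code == 0, res.output
        td = pd.read_csv(tmp_path / "td.csv")
        assert set(td.group) == {"control", "fus_drug"}

    def test_survival_command(self, runner, tmp_path):
        tbl = pd.concat(
            [
                make_survival_table(median_days=25, group="control", seed=1),
                make_survival_table(median_days=41.5, group="fus_drug", seed=2),
            ]
        )
        tbl.to_csv(tmp_path / "surv.csv", index=False)
        res = runner.invoke(
            main,
            ["survival", "--table", str(tmp_path / "surv.csv"), "--out", str(tmp_path / "km.json")],
        )
        assert res.exit_code == 0, res.output
        out = json.loads((tmp_path / "km.json").read_text())
        assert "control_vs_fus_drug" in out["logrank"]

    def test_summarize_conc(self, runner, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "compartment": ["tumor"] * 6,
                "condition": ["sonicated"] * 3 + ["control"] * 3,
                "value": rng.lognormal(3, 0.2, 6),
            }
        )
        df.to_csv(tmp_path / "conc.csv", index=False)
        res = runner.invoke(
            main,
            ["summarize-conc", "--table", str(tmp_path / "conc.csv"), "--out", str(tmp_path / "gm.csv")],
        )
        assert res.exit_code == 0, res.output
        gm = pd.read_csv(tmp_path / "gm.csv")
        assert len(gm) == 2 and (gm.geometric_mean > 0).all()

    def test_report_command(self, runner, tmp_path):
        res = runner.invoke(main, ["report", "--out", str(tmp_path / "rep")])
        assert res.exit_code == 0, res.output
        doc = json.loads((tmp_path / "rep.json").read_text())
        assert "headline_ratios" in doc
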