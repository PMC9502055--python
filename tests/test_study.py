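"""Cohort-level studies, configuration round trips, file I/O and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import fetlock.io as fio
from fetlock import (CohortConfig, RunConfig, run_demo_study,
                     run_validation_study, run_variability_study,
                     simulate_cohort)
from fetlock.cli import main as cli_main
from fetlock.study import _simulate_trials

ZERO_NOISE = dict(gyro_noise_sd_dps=0.0, marker_noise_sd_m=0.0,
                  soft_tissue_amp_m=0.0, orientation_noise_sd_deg=0.0)


def small_config(**kw):
    base = dict(seed=21, n_sound=1, n_lame=1, n_strides_sim=5)
    base.update(kw)
    return RunConfig(**base)


class TestValidationStudy:
    def test_zero_noise_cohort_near_perfect_agreement(self):
        """With identical underlying kinematics both channels agree almost
        exactly: RMSE < 0.5° and PCC > 0.9999 for every limb trial."""
        cfg = small_config(**ZERO_NOISE)
        study = run_validation_study(cfg)
        assert study.exclusions == []
        assert len(study.runs) == 16  # 2 horses × 2 gaits × 4 limbs
        for r in study.runs:
            assert r.agreement.rmse_deg < 0.5
            assert r.agreement.pcc > 0.9999

    def test_zero_noise_fjrom_recovery_all_limbs(self):
        cfg = small_config(**ZERO_NOISE)
        trials = _simulate_trials(cfg)
        study = run_validation_study(cfg, trials)
        planted = {(t.gait, t.horse_id, limb): rec.planted_rom_deg
                   for gait, ts in trials.items() for t in ts
                   for limb, rec in t.recordings.items()}
        for r in study.runs:
            key = (r.gait, r.horse_id, r.limb_id)
            # 0.5° at study-default amplitudes; the residual error is the
            # filter's proportional pass-band loss, so extreme ROM draws are
            # held to the same relative accuracy
            assert r.fjrom_imu.mean_rom == pytest.approx(planted[key], abs=0.5, rel=0.007)
            assert r.fjrom_omc.mean_rom == pytest.approx(planted[key], abs=0.5, rel=0.007)

    def test_default_noise_granger_agreement(self):
        study = run_validation_study(small_config())
        assert all(r.agreement.granger.agree for r in study.runs)

    def test_report_embeds_config_and_per_limb_rows(self):
        study = run_validation_study(small_config(**ZERO_NOISE))
        rep = study.to_report()
        assert rep["config"]["seed"] == 21
        assert len(rep["per_limb"]) == len(study.runs)
        assert {"rmse_deg", "pcc", "granger_agree"} <= set(rep["per_limb"][0])


class TestVariabilityStudy:
    def test_lame_horses_contribute_only_lame_pair(self):
        cfg = small_config(n_sound=2, n_lame=2)
        study = run_variability_study(cfg)
        rec = study.records
        sound = rec[rec.lameness == "sound"]
        lame = rec[rec.lameness == "lame"]
        # sound: front+hind per gait; lame: one pair per gait
        assert len(sound) == 2 * 2 * 2
        assert len(lame) == 2 * 2

    def test_no_planted_lameness_effect_gives_small_share(self):
        """With lameness_factor = 1 everywhere the lame pairs behave like
        sound pairs: the lameness share of variation is small and not
        significant."""
        cfg = small_config(n_sound=7, n_lame=7)
        trials = {}
        for gait in cfg.gaits:
            cc = CohortConfig(gait=gait, n_strides=cfg.n_strides_sim,
                              lameness_factor_range=(1.0, 1.0))
            trials[gait] = simulate_cohort(cfg.n_sound, cfg.n_lame, cc, seed=cfg.seed)
        study = run_variability_study(cfg, trials)
        part = study.anova.partition
        assert part.percent_of_total["lameness"] < 15.0
        assert part.table.loc["lameness", "p"] > 0.01

    def test_study_shaped_cohort_lameness_dominates(self):
        cfg = RunConfig(seed=42)
        study = run_variability_study(cfg)
        assert study.anova.dominant_factor == "lameness"
        sound_cv = study.records.query("lameness == 'sound'").cv_percent
        lame_cv = study.records.query("lameness == 'lame'").cv_percent
        assert lame_cv.mean() > sound_cv.mean()

    def test_single_gait_drops_factor_with_warning(self):
        cfg = small_config(n_sound=2, n_lame=2, gaits=("trot",))
        with pytest.warns(UserWarning, match="gait"):
            study = run_variability_study(cfg)
        assert "gait" in study.anova.partition.dropped_factors


class TestDeterminismAndProvenance:
    def test_same_seed_bit_identical_reports(self):
        cfg = small_config(**ZERO_NOISE)
        a = run_demo_study(cfg)
        b = run_demo_study(small_config(**ZERO_NOISE))
        assert json.dumps(a, default=str) == json.dumps(b, default=str)

    def test_reports_embed_full_config(self):
        rep = run_demo_study(small_config(**ZERO_NOISE))
        for key in ("validation", "variability"):
            assert rep[key]["config"] == small_config(**ZERO_NOISE).to_dict()


class TestConfigAndIo:
    def test_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=9, stance_low_frac=0.07, gaits=("walk",))
        path = tmp_path / "cfg.yaml"
        cfg.save(path)
        assert RunConfig.load(path) == cfg

    def test_config_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            RunConfig.from_dict({"seed": 1, "bogus": 2})

    def test_cohort_csv_round_trip_full_precision(self, tmp_path):
        trials = simulate_cohort(1, 1, CohortConfig(gait="trot", n_strides=4), seed=13)
        fio.write_cohort(trials, tmp_path)
        back = fio.read_cohort(tmp_path)
        assert len(back) == len(trials)
        for t0, t1 in zip(trials, back):
            assert (t0.horse_id, t0.is_lame, t0.lame_limb) == \
                   (t1.horse_id, t1.is_lame, t1.lame_limb)
            for limb in t0.recordings:
                a, b = t0.recordings[limb], t1.recordings[limb]
                assert np.array_equal(a.quat_pastern, b.quat_pastern)
                assert np.array_equal(a.gyro_pastern, b.gyro_pastern)
                assert np.array_equal(a.markers["distal"], b.markers["distal"])
                assert np.array_equal(a.truth_fja.values, b.truth_fja.values)

    def test_angle_csv_round_trip(self, tmp_path, clean_trot_recording):
        path = tmp_path / "angle.csv"
        fio.write_angle_csv(clean_trot_recording.truth_fja, path)
        back = fio.read_angle_csv(path)
        assert np.array_equal(back.values, clean_trot_recording.truth_fja.values)
        assert back.rate_hz == pytest.approx(200.0)


class TestCli:
    def test_simulate_report_variability_chain(self, tmp_path):
        runner = CliRunner()
        cohort = tmp_path / "cohort"
        r = runner.invoke(cli_main, ["simulate", "--gait", "trot", "--n-sound", "2",
                                     "--n-lame", "2", "--seed", "5",
                                     "--out", str(cohort)])
        assert r.exit_code == 0, r.output
        assert (cohort / "cohort.yaml").exists()

        out = tmp_path / "report.json"
        r = runner.invoke(cli_main, ["report", "--cohort", str(cohort),
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        rep = json.loads(out.read_text())
        assert rep["summary"]["overall"]["n_runs"] == 16

        out2 = tmp_path / "anova.json"
        r = runner.invoke(cli_main, ["variability", "--cohort", str(cohort),
                                     "--out", str(out2)])
        assert r.exit_code == 0, r.output
        assert out2.with_suffix(".cv_records.csv").exists()

    def test_validate_on_angle_csvs(self, tmp_path, clean_trot_recording):
        from fetlock.angles import apply_calibration, relative_sagittal_angle
        rec = clean_trot_recording
        imu = relative_sagittal_angle(rec.quat_cannon, rec.quat_pastern)
        imu, _ = apply_calibration(imu, 1.0)
        imu_csv, omc_csv = tmp_path / "imu.csv", tmp_path / "omc.csv"
        fio.write_angle_csv(imu, imu_csv)
        fio.write_angle_csv(imu.with_values(imu.values + 7.0), omc_csv)
        out = tmp_path / "agree.json"
        r = CliRunner().invoke(cli_main, ["validate", "--imu", str(imu_csv),
                                          "--omc", str(omc_csv), "--out", str(out)])
        assert r.exit_code == 0, r.output
        rep = json.loads(out.read_text())
        assert rep["sync"]["y_offset_deg"] == pytest.approx(7.0, abs=1e-6)
        assert rep["rmse_deg"] < 1e-6

    def test_missing_cohort_dir_clean_error(self, tmp_path):
        r = CliRunner().invoke(cli_main, ["report", "--cohort",
                                          str(tmp_path / "nope"), "--out",
                                          str(tmp_path / "x.json")])
        assert r.exit_code != 0
        assert "nope" in r.output

    def test_demo_smoke(self, tmp_path):
        cfg = small_config()
        cfg_path = tmp_path / "cfg.yaml"
        cfg.save(cfg_path)
        out = tmp_path / "demo.json"
        r = CliRunner().invoke(cli_main, ["demo", "--seed", "21", "--config",
                                          str(cfg_path), "--out", str(out)])
        assert r.exit_code == 0, r.output
        rep = json.loads(out.read_text())
        assert "validation" in rep and "variability" in rep
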