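"""Study orchestration: full per-limb pipeline runs and cohort-level reports.

``run_validation_study`` mirrors the agreement analysis — every horse × gait
× limb trial is pushed through both measurement chains, synchronised, and
scored (RMSE, PCC, Granger, Bland–Altman); per-gait and per-group summaries
are aggregated.  ``run_variability_study`` assembles the left–right FJROM
coefficient-of-variation table and runs the three-way ANOVA partition.
``run_demo_study`` runs both at the study-shaped default of 7 sound + 7 lame
horses at walk and trot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import (MethodAgreement, MethodAgreementResults,
                        RomVariabilityAnova, RomVariabilityResults,
                        bland_altman_rm, cv_percent)
from .angles import (apply_calibration, fja_from_markers,
                     relative_sagittal_angle, resultant_angular_velocity)
from .config import RunConfig
from .pipeline import (butter_lowpass, compute_fjrom, resample_spline,
                       segment_strides, synchronize_and_align)
from .series import AngleSeries, FJROMSummary, StrideEvents, SyncResult
from .simulate import CohortConfig, HorseTrial, LimbRecording, limb_pair, simulate_cohort

log = logging.getLogger("fetlock")

PAIRS = {"front": ("LF", "RF"), "hind": ("LH", "RH")}


@dataclass
class LimbRun:
    """Everything the pipeline produced for one limb of one trial."""

    horse_id: str
    gait: str
    limb_id: str
    horse_lame: bool
    limb_lame: bool
    imu_aligned: AngleSeries
    omc_aligned: AngleSeries
    sync: SyncResult
    events: StrideEvents
    fjrom_imu: FJROMSummary
    fjrom_omc: FJROMSummary
    agreement: MethodAgreementResults


def process_limb(rec: LimbRecording, config: RunConfig) -> dict:
    """Run both measurement chains for one limb and score their agreement.

    Returns the aligned traces, the stride events, IMU- and OMC-derived
    FJROM summaries and the per-trial agreement statistics.
    """
    imu_raw = relative_sagittal_angle(rec.quat_cannon, rec.quat_pastern,
                                      rate_hz=rec.imu_rate_hz)
    imu_cal, calib = apply_calibration(imu_raw, config.calib_window_s)
    imu_f = butter_lowpass(imu_cal, config.filter_cutoff_hz, config.filter_order)

    omc_raw = fja_from_markers(rec.markers, rate_hz=rec.omc_rate_hz)
    omc_rs = resample_spline(omc_raw, config.resample_rate_hz)
    omc_f = butter_lowpass(omc_rs, config.filter_cutoff_hz, config.filter_order)

    imu_a, omc_a, sync = synchronize_and_align(
        imu_f, omc_f, config.sync_prominence_frac)

    resultant = resultant_angular_velocity(rec.gyro_pastern)
    events = segment_strides(resultant, rec.imu_rate_hz,
                             config.stance_low_frac, config.stance_high_frac,
                             config.min_stance_s,
                             smooth_cutoff_hz=config.filter_cutoff_hz)
    fjrom_imu = compute_fjrom(imu_f, events, config.n_strides_rom)
    fjrom_omc = compute_fjrom(omc_f, events, config.n_strides_rom)

    agreement = MethodAgreement(imu_a, omc_a).fit(
        max_lag=config.granger_max_lag, alpha=config.granger_alpha,
        granger_rule=config.granger_rule,
        granger_decimate=config.granger_decimate, ba_method="pooled")
    return {"imu_aligned": imu_a, "omc_aligned": omc_a, "sync": sync,
            "calibration": calib, "events": events,
            "fjrom_imu": fjrom_imu, "fjrom_omc": fjrom_omc,
            "agreement": agreement, "imu_filtered": imu_f, "omc_filtered": omc_f}


def _simulate_trials(config: RunConfig) -> dict[str, list[HorseTrial]]:
    out = {}
    for gait in config.gaits:
        cc = CohortConfig(gait=gait, n_strides=config.n_strides_sim,
                          gyro_noise_sd_dps=config.gyro_noise_sd_dps,
                          marker_noise_sd_m=config.marker_noise_sd_m,
                          soft_tissue_amp_m=config.soft_tissue_amp_m,
                          orientation_noise_sd_deg=config.orientation_noise_sd_deg)
        out[gait] = simulate_cohort(config.n_sound, config.n_lame, cc,
                                    seed=config.seed)
    return out


@dataclass
class ValidationStudy:
    """Outcome of the cohort-level agreement study."""

    runs: list[LimbRun]
    exclusions: list[dict]
    summary: dict
    config: RunConfig

    def to_report(self) -> dict:
        rep = {"config": self.config.to_dict(), "summary": self.summary,
               "exclusions": self.exclusions, "per_limb": []}
        for r in self.runs:
            a = r.agreement
            rep["per_limb"].append({
                "horse_id": r.horse_id, "gait": r.gait, "limb": r.limb_id,
                "horse_lame": r.horse_lame, "limb_lame": r.limb_lame,
                "rmse_deg": a.rmse_deg, "pcc": a.pcc, "pcc_p": a.pcc_p,
                "granger_lag": a.granger.lag_order,
                "granger_p_fwd": a.granger.p_fwd,
                "granger_p_rev": a.granger.p_rev,
                "granger_agree": a.granger.agree,
                "ba_bias_deg": a.bland_altman.bias,
                "ba_loa": [a.bland_altman.loa_low, a.bland_altman.loa_high],
                "fjrom_imu_deg": r.fjrom_imu.mean_rom,
                "fjrom_omc_deg": r.fjrom_omc.mean_rom,
                "sync_lag_samples": r.sync.lag_samples,
            })
        return rep


def run_validation_study(config: RunConfig,
                         trials_by_gait: dict[str, list[HorseTrial]] | None = None
                         ) -> ValidationStudy:
    """Agreement study over a cohort: full pipeline on every horse × gait ×
    limb, with per-gait / per-group aggregate statistics.

    Per-trial failures are logged as exclusions and skipped, not fatal.
    """
    if trials_by_gait is None:
        trials_by_gait = _simulate_trials(config)
    runs: list[LimbRun] = []
    exclusions: list[dict] = []
    for gait, trials in trials_by_gait.items():
        for trial in trials:
            for limb, rec in trial.recordings.items():
                try:
                    out = process_limb(rec, config)
                except Exception as exc:  # noqa: BLE001 — mirror trial rejection
                    log.warning("excluded %s %s %s: %s", trial.horse_id, gait, limb, exc)
                    exclusions.append({"horse_id": trial.horse_id, "gait": gait,
                                       "limb": limb, "reason": str(exc)})
                    continue
                runs.append(LimbRun(
                    horse_id=trial.horse_id, gait=gait, limb_id=limb,
                    horse_lame=trial.is_lame,
                    limb_lame=trial.lame_limb == limb,
                    imu_aligned=out["imu_aligned"], omc_aligned=out["omc_aligned"],
                    sync=out["sync"], events=out["events"],
                    fjrom_imu=out["fjrom_imu"], fjrom_omc=out["fjrom_omc"],
                    agreement=out["agreement"]))
    summary = _summarize_runs(runs, config)
    return ValidationStudy(runs=runs, exclusions=exclusions, summary=summary,
                           config=config)


def _mean_sd(vals: list[float]) -> dict:
    arr = np.asarray(vals, dtype=float)
    return {"mean": float(arr.mean()) if arr.size else float("nan"),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size)}


def _summarize_runs(runs: list[LimbRun], config: RunConfig) -> dict:
    summary: dict = {"by_gait": {}, "by_group": {}, "overall": {}}
    if not runs:
        return summary

    def agg(sel: list[LimbRun]) -> dict:
        return {"rmse_deg": _mean_sd([r.agreement.rmse_deg for r in sel]),
                "pcc": _mean_sd([r.agreement.pcc for r in sel]),
                "granger_agree_frac": float(np.mean(
                    [r.agreement.granger.agree for r in sel])) if sel else float("nan")}

    for gait in sorted({r.gait for r in runs}):
        sel = [r for r in runs if r.gait == gait]
        summary["by_gait"][gait] = agg(sel)
        # study-level Bland–Altman, repeated measures by horse
        fja_d_x = np.concatenate([r.imu_aligned.values for r in sel])
        fja_d_y = np.concatenate([r.omc_aligned.values for r in sel])
        subj = np.concatenate([[r.horse_id] * len(r.imu_aligned) for r in sel])
        ba_fja = bland_altman_rm(fja_d_x, fja_d_y, subject=subj,
                                 method=config.ba_method)
        ba_rom = bland_altman_rm(
            np.array([r.fjrom_imu.mean_rom for r in sel]),
            np.array([r.fjrom_omc.mean_rom for r in sel]),
            subject=np.array([r.horse_id for r in sel]), method=config.ba_method)
        summary["by_gait"][gait]["bland_altman_fja"] = {
            "bias": ba_fja.bias, "loa": [ba_fja.loa_low, ba_fja.loa_high],
            "method": ba_fja.method, "n": ba_fja.n}
        summary["by_gait"][gait]["bland_altman_fjrom"] = {
            "bias": ba_rom.bias, "loa": [ba_rom.loa_low, ba_rom.loa_high],
            "method": ba_rom.method, "n": ba_rom.n}
    for name, lame in (("sound", False), ("lame", True)):
        summary["by_group"][name] = agg([r for r in runs if r.horse_lame == lame])
    summary["overall"] = agg(runs)
    summary["overall"]["granger_agree_percent"] = (
        100.0 * summary["overall"]["granger_agree_frac"])
    summary["overall"]["n_runs"] = len(runs)
    return summary


def imu_fjrom(rec: LimbRecording, config: RunConfig) -> FJROMSummary:
    """IMU-chain FJROM only (no optical channel): angle, filter, segment."""
    imu_raw = relative_sagittal_angle(rec.quat_cannon, rec.quat_pastern,
                                      rate_hz=rec.imu_rate_hz)
    imu_cal, _ = apply_calibration(imu_raw, config.calib_window_s)
    imu_f = butter_lowpass(imu_cal, config.filter_cutoff_hz, config.filter_order)
    resultant = resultant_angular_velocity(rec.gyro_pastern)
    events = segment_strides(resultant, rec.imu_rate_hz,
                             config.stance_low_frac, config.stance_high_frac,
                             config.min_stance_s,
                             smooth_cutoff_hz=config.filter_cutoff_hz)
    return compute_fjrom(imu_f, events, config.n_strides_rom)


@dataclass
class VariabilityStudy:
    """Left–right FJROM CV table plus its ANOVA partition."""

    records: pd.DataFrame
    anova: RomVariabilityResults
    config: RunConfig
    warnings: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        part = self.anova.partition
        return {"config": self.config.to_dict(),
                "records": self.records.to_dict(orient="records"),
                "anova": {
                    "table": {str(k): {c: (None if pd.isna(v) else float(v))
                                       for c, v in row.items()}
                              for k, row in part.table.iterrows()},
                    "total_ss": part.total_ss,
                    "shapiro_p": part.shapiro_p,
                    "dropped_factors": list(part.dropped_factors),
                    "dominant_factor": self.anova.dominant_factor,
                },
                "warnings": self.warnings}


def run_variability_study(config: RunConfig,
                          trials_by_gait: dict[str, list[HorseTrial]] | None = None
                          ) -> VariabilityStudy:
    """Assemble left–right FJROM CVs (IMU chain) and run the three-way ANOVA.

    Sound horses contribute a front and a hind left–right pair per gait;
    lame horses contribute only the lame limb and its contralateral.
    """
    if trials_by_gait is None:
        trials_by_gait = _simulate_trials(config)
    rows = []
    warns: list[str] = []
    for gait, trials in trials_by_gait.items():
        for trial in trials:
            pairs = ([limb_pair(trial.lame_limb)] if trial.is_lame
                     else ["front", "hind"])
            for pair in pairs:
                left, right = PAIRS[pair]
                try:
                    rom_l = imu_fjrom(trial.recordings[left], config).mean_rom
                    rom_r = imu_fjrom(trial.recordings[right], config).mean_rom
                    cv = cv_percent([rom_l, rom_r])
                except Exception as exc:  # noqa: BLE001
                    warns.append(f"{trial.horse_id} {gait} {pair}: {exc}")
                    continue
                rows.append({"horse_id": trial.horse_id, "gait": gait,
                             "limb_pair": pair,
                             "lameness": "lame" if trial.is_lame else "sound",
                             "cv_percent": cv,
                             "rom_left_deg": rom_l, "rom_right_deg": rom_r})
    records = pd.DataFrame(rows)
    if records.empty:
        raise ValueError("no usable left–right pairs in the cohort")
    anova = RomVariabilityAnova(records).fit(alpha=config.anova_alpha)
    return VariabilityStudy(records=records, anova=anova, config=config,
                            warnings=warns)


def run_demo_study(config: RunConfig | None = None) -> dict:
    """The full study-shaped demonstration: simulate the 7 sound + 7 lame
    cohort at walk and trot, run the agreement and variability studies, and
    return a combined report."""
    config = config or RunConfig()
    trials = _simulate_trials(config)
    validation = run_validation_study(config, trials)
    variability = run_variability_study(config, trials)
    return {"validation": validation.to_report(),
            "variability": variability.to_report(),
            "config": config.to_dict(), "seed": config.seed}
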