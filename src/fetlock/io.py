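"""Plain-text readers and writers for the pipeline's CSV dialects.

One CSV per limb per channel: quaternions (time_s, qw, qx, qy, qz), gyroscope
(time_s, wx, wy, wz), markers (time_s, then px/py per marker) and angle
traces (time_s, fja_deg plus the convention tag).  Cohorts get a YAML
manifest naming the horses, their lameness assignment and the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import AngleSeries
from .simulate import LIMB_IDS, HorseTrial, LimbRecording

MARKER_NAMES = ("proximal", "fetlock", "distal")


def write_angle_csv(series: AngleSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": series.times, "fja_deg": series.values})
    df["convention"] = series.convention
    df.to_csv(path, index=False, float_format="%.17g")


def read_angle_csv(path: str | Path) -> AngleSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: time axis is not uniformly sampled")
    conv = str(df["convention"].iloc[0]) if "convention" in df else "common"
    return AngleSeries(df["fja_deg"].to_numpy(dtype=float), rate_hz=1.0 / dt.mean(),
                       t0=float(t[0]), convention=conv)


def write_quat_csv(quat: np.ndarray, rate_hz: float, path: str | Path) -> None:
    t = np.arange(quat.shape[0]) / rate_hz
    pd.DataFrame({"time_s": t, "qw": quat[:, 0], "qx": quat[:, 1],
                  "qy": quat[:, 2], "qz": quat[:, 3]}).to_csv(
        path, index=False, float_format="%.17g")


def read_quat_csv(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path, float_precision="round_trip")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    rate = 1.0 / float(np.mean(np.diff(df["time_s"].to_numpy(dtype=float))))
    return q, rate


def write_gyro_csv(gyro: np.ndarray, rate_hz: float, path: str | Path) -> None:
    t = np.arange(gyro.shape[0]) / rate_hz
    pd.DataFrame({"time_s": t, "wx": gyro[:, 0], "wy": gyro[:, 1],
                  "wz": gyro[:, 2]}).to_csv(path, index=False, float_format="%.17g")


def read_gyro_csv(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path, float_precision="round_trip")
    g = df[["wx", "wy", "wz"]].to_numpy(dtype=float)
    rate = 1.0 / float(np.mean(np.diff(df["time_s"].to_numpy(dtype=float))))
    return g, rate


def write_markers_csv(markers: dict[str, np.ndarray], rate_hz: float,
                      path: str | Path) -> None:
    n = markers[MARKER_NAMES[0]].shape[0]
    cols: dict[str, np.ndarray] = {"time_s": np.arange(n) / rate_hz}
    for name in MARKER_NAMES:
        cols[f"{name}_px"] = markers[name][:, 0]
        cols[f"{name}_py"] = markers[name][:, 1]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_markers_csv(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    df = pd.read_csv(path, float_precision="round_trip")
    markers = {name: df[[f"{name}_px", f"{name}_py"]].to_numpy(dtype=float)
               for name in MARKER_NAMES}
    rate = 1.0 / float(np.mean(np.diff(df["time_s"].to_numpy(dtype=float))))
    return markers, rate


def write_cohort(trials: list[HorseTrial], out_dir: str | Path) -> Path:
    """Write per-limb channel CSVs plus a YAML manifest for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"trials": []}
    for trial in trials:
        stem = f"{trial.horse_id}_{trial.gait}"
        entry = {"horse_id": trial.horse_id, "gait": trial.gait,
                 "is_lame": trial.is_lame, "lame_limb": trial.lame_limb,
                 "meta": {k: (float(v) if isinstance(v, (int, float, np.floating))
                              else v) for k, v in trial.meta.items()},
                 "limbs": {}}
        for limb, rec in trial.recordings.items():
            base = f"{stem}_{limb}"
            write_quat_csv(rec.quat_cannon, rec.imu_rate_hz, out / f"{base}_quat_cannon.csv")
            write_quat_csv(rec.quat_pastern, rec.imu_rate_hz, out / f"{base}_quat_pastern.csv")
            write_gyro_csv(rec.gyro_pastern, rec.imu_rate_hz, out / f"{base}_gyro.csv")
            write_markers_csv(rec.markers, rec.omc_rate_hz, out / f"{base}_markers.csv")
            write_angle_csv(rec.truth_fja, out / f"{base}_truth_fja.csv")
            entry["limbs"][limb] = {
                "imu_rate_hz": float(rec.imu_rate_hz),
                "omc_rate_hz": float(rec.omc_rate_hz),
                "files": {
                    "quat_cannon": f"{base}_quat_cannon.csv",
                    "quat_pastern": f"{base}_quat_pastern.csv",
                    "gyro": f"{base}_gyro.csv",
                    "markers": f"{base}_markers.csv",
                    "truth_fja": f"{base}_truth_fja.csv",
                },
            }
        manifest["trials"].append(entry)
    manifest_path = out / "cohort.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> list[HorseTrial]:
    """Rebuild HorseTrial objects from a cohort manifest and its CSVs."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "cohort.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"cohort manifest not found: {manifest_path}")
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    trials = []
    for entry in manifest["trials"]:
        recordings = {}
        for limb, spec in entry["limbs"].items():
            files = spec["files"]
            quat_cannon, imu_rate = read_quat_csv(root / files["quat_cannon"])
            quat_pastern, _ = read_quat_csv(root / files["quat_pastern"])
            gyro, _ = read_gyro_csv(root / files["gyro"])
            markers, omc_rate = read_markers_csv(root / files["markers"])
            truth = read_angle_csv(root / files["truth_fja"])
            recordings[limb] = LimbRecording(
                limb_id=limb, quat_cannon=quat_cannon, quat_pastern=quat_pastern,
                gyro_pastern=gyro, markers=markers,
                imu_rate_hz=float(spec["imu_rate_hz"]),
                omc_rate_hz=float(spec["omc_rate_hz"]), truth_fja=truth)
        trials.append(HorseTrial(
            horse_id=entry["horse_id"], is_lame=bool(entry["is_lame"]),
            lame_limb=entry["lame_limb"], gait=entry["gait"],
            recordings=recordings, meta=dict(entry.get("meta", {}))))
    return trials


def write_json_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
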