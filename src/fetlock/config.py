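"""Run configuration: every pipeline threshold in one serialisable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of the simulation and analysis pipeline.

    Round-trips through YAML unchanged; every report embeds the resolved
    configuration for provenance.
    """

    # cohort / simulation
    seed: int = 42
    n_sound: int = 7
    n_lame: int = 7
    gaits: tuple[str, ...] = ("walk", "trot")
    n_strides_sim: int = 5
    gyro_noise_sd_dps: float = 2.0
    marker_noise_sd_m: float = 0.001
    soft_tissue_amp_m: float = 0.002
    orientation_noise_sd_deg: float = 0.3
    # signal pipeline
    filter_cutoff_hz: float = 10.0
    filter_order: int = 4
    resample_rate_hz: float = 200.0
    calib_window_s: float = 1.0
    sync_prominence_frac: float = 0.2
    stance_low_frac: float = 0.08
    stance_high_frac: float = 0.15
    min_stance_s: float = 0.08
    n_strides_rom: int = 3
    # statistics
    granger_max_lag: int = 20      # samples at the native 200 Hz rate (100 ms)
    granger_decimate: int = 4      # run the Granger regressions at 200/4 = 50 Hz
    granger_alpha: float = 0.01
    granger_rule: str = "either"
    anova_alpha: float = 0.05
    ba_method: str = "rm_corrected"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gaits"] = list(self.gaits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "gaits" in d:
            d["gaits"] = tuple(d["gaits"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
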