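"""Synthetic equine distal-limb gait generator.

Produces ground-truth fetlock joint angle (FJA) kinematics for walk and trot
together with the two observation channels the analysis pipeline consumes:

* an IMU channel — unit-quaternion orientations of the cannon
  (metacarpus/metatarsus) and pastern segments plus the triaxial pastern
  gyroscope, at 200 Hz;
* an OMC channel — planar trajectories of three reflective markers (carpus/
  tarsus, fetlock and coffin joint centres) on a two-link chain, at 60 Hz.

The stride-cycle FJA template is a sum of wrapped Gaussian bumps on the
stride-phase circle: flexion peaks positive, extension troughs negative,
renormalised so the peak-to-peak range equals the requested range of motion
exactly.  At walk the cycle shows a double flexion peak and two extension
peaks; at trot a double flexion peak and a single extension peak.

Kinematic chain: the *pastern global orientation* is modelled as quiet during
stance (the hoof is planted) with a smooth protraction excursion during
swing, and the cannon orientation is whatever makes the joint angle come out
as the planted FJA (``cannon = pastern − FJA``).  The stance extension is
therefore absorbed by the cannon rotating over the planted hoof, which is
also why the pastern-mounted gyroscope shows the low-velocity stance troughs
used for stride segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .series import AngleSeries

LIMB_IDS = ("LF", "RF", "LH", "RH")

#: group-mean planted range of motion (degrees) by (gait, limb pair)
DEFAULT_ROM_MEAN = {
    ("walk", "front"): 57.79,
    ("walk", "hind"): 60.48,
    ("trot", "front"): 82.83,
    ("trot", "hind"): 89.40,
}
#: between-horse SD of the planted range of motion (degrees)
DEFAULT_ROM_SD = {
    ("walk", "front"): 4.50,
    ("walk", "hind"): 6.10,
    ("trot", "front"): 6.64,
    ("trot", "hind"): 4.89,
}
DEFAULT_SPEED = {"walk": 1.53, "trot": 3.56}
DEFAULT_STRIDE_LENGTH = {"walk": 1.8, "trot": 2.5}
DEFAULT_STANCE_FRACTION = {"walk": 0.6, "trot": 0.4}

#: stride-phase offset of each limb relative to LF, by gait
GAIT_PHASE_OFFSETS = {
    # 4-beat lateral-sequence walk: LH, LF, RH, RF at quarter-cycle intervals
    "walk": {"LF": 0.0, "RH": 0.25, "RF": 0.5, "LH": 0.75},
    # 2-beat diagonal trot: LF+RH together, RF+LH half a cycle later
    "trot": {"LF": 0.0, "RH": 0.0, "RF": 0.5, "LH": 0.5},
}


def limb_pair(limb_id: str) -> str:
    """'front' for LF/RF, 'hind' for LH/RH."""
    if limb_id not in LIMB_IDS:
        raise ValueError(f"unknown limb id {limb_id!r}")
    return "front" if limb_id in ("LF", "RF") else "hind"


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_deriv(u: np.ndarray) -> np.ndarray:
    out = 6.0 * u * (1.0 - u)
    return np.where((u < 0.0) | (u > 1.0), 0.0, out)


class FjaWaveform:
    """One-stride FJA template on the unit phase circle (toe-on at phase 0).

    ``rom_deg`` is enforced exactly as the template's peak-to-peak range and
    the template is shifted so the angle at toe-on is zero.  The template is
    smooth and periodic by construction (wrapped Gaussians), so value and
    derivative match at phase 0 and 1.
    """

    _N_WRAP = 3
    _N_NORM = 8192

    def __init__(self, gait: str, rom_deg: float, flexion_peak_ratio: float = 0.9,
                 stance_fraction: float | None = None):
        if gait not in ("walk", "trot"):
            raise ValueError(f"unknown gait {gait!r}; expected 'walk' or 'trot'")
        if not np.isfinite(rom_deg) or rom_deg <= 0:
            raise ValueError("rom_deg must be positive and finite")
        if not 0 < flexion_peak_ratio <= 1:
            raise ValueError("flexion_peak_ratio must be in (0, 1]")
        f = DEFAULT_STANCE_FRACTION[gait] if stance_fraction is None else float(stance_fraction)
        if not 0.2 <= f <= 0.8:
            raise ValueError("stance_fraction must lie in [0.2, 0.8]")
        self.gait = gait
        self.rom_deg = float(rom_deg)
        self.flexion_peak_ratio = float(flexion_peak_ratio)
        self.stance_fraction = f

        swing = 1.0 - f
        r = self.flexion_peak_ratio
        if gait == "walk":
            # two extension peaks in stance (the late-stance, push-off one is
            # the deeper, hence the cycle's absolute minimum), double flexion
            # peak in swing
            self._centers = np.array([0.2 * f, 0.8 * f, f + 0.3 * swing, f + 0.7 * swing])
            self._sigmas = np.array([0.12 * f, 0.12 * f, 0.1625 * swing, 0.1625 * swing])
            self._amps = np.array([-0.22, -0.34, 0.72, 0.72 * r])
            self.quiet_phase = 0.5 * f
        else:
            # single extension peak mid-stance, double flexion peak in swing
            self._centers = np.array([0.5 * f, f + swing / 3.0, f + 2.0 * swing / 3.0])
            self._sigmas = np.array([0.175 * f, 0.4 * swing / 3.0, 0.4 * swing / 3.0])
            self._amps = np.array([-0.18, 0.82, 0.82 * r])
            self.quiet_phase = 0.85 * f

        grid = np.arange(self._N_NORM) / self._N_NORM
        raw = self._raw(grid)
        self._scale = self.rom_deg / (raw.max() - raw.min())
        self._shift = self._scale * self._raw(np.array([0.0]))[0]

    def _raw(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float) % 1.0
        out = np.zeros_like(phase)
        for c, s, a in zip(self._centers, self._sigmas, self._amps):
            for k in range(-self._N_WRAP, self._N_WRAP + 1):
                d = phase - c + k
                out += a * np.exp(-0.5 * (d / s) ** 2)
        return out

    def _raw_deriv(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float) % 1.0
        out = np.zeros_like(phase)
        for c, s, a in zip(self._centers, self._sigmas, self._amps):
            for k in range(-self._N_WRAP, self._N_WRAP + 1):
                d = phase - c + k
                out += a * (-d / s**2) * np.exp(-0.5 * (d / s) ** 2)
        return out

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        """Template value (degrees) at the given stride phase(s)."""
        return self._scale * self._raw(phase) - self._shift

    def derivative(self, phase: np.ndarray) -> np.ndarray:
        """d(template)/d(phase), degrees per stride."""
        return self._scale * self._raw_deriv(phase)

    def sample(self, n: int = 2048) -> np.ndarray:
        """Template sampled on ``n`` uniform phases over one cycle."""
        return self(np.arange(n) / n)

    def extrema_counts(self, prominence_frac: float = 0.02,
                       value_frac: float = 0.2,
                       n: int = 2400) -> tuple[int, int]:
        """Counts of (flexion peaks, extension peaks) over one cycle.

        A flexion peak is a local maximum at a substantially positive angle
        (value ≥ ``value_frac`` × the template maximum), an extension peak a
        local minimum at a substantially negative angle (value ≤
        ``value_frac`` × the template minimum); both need a prominence of at
        least ``prominence_frac`` × the template range.  Counting by sign is
        what distinguishes the shallow dip between a double flexion peak —
        still strongly positive — from a true extension peak, and the partial
        mid-stance rebound between two extension peaks from a flexion peak.
        """
        v = self.sample(n)
        prom = prominence_frac * (v.max() - v.min())
        tiled = np.concatenate([v, v, v])
        peaks = find_peaks(tiled, prominence=prom)[0]
        peaks = peaks[(peaks >= n) & (peaks < 2 * n)]
        n_flex = int(np.sum(tiled[peaks] >= value_frac * v.max()))
        troughs = find_peaks(-tiled, prominence=prom)[0]
        troughs = troughs[(troughs >= n) & (troughs < 2 * n)]
        n_ext = int(np.sum(tiled[troughs] <= value_frac * v.min()))
        return n_flex, n_ext


def make_fja_waveform(gait: str, rom_deg: float, flexion_peak_ratio: float = 0.9,
                      stance_fraction: float | None = None) -> FjaWaveform:
    """Build the one-stride FJA template for a gait.

    Walk templates carry a symmetric double flexion peak and two extension
    peaks per cycle; trot templates a double flexion peak and a single
    extension peak.  ``flexion_peak_ratio`` sets the height of the second
    flexion peak relative to the first.
    """
    return FjaWaveform(gait, rom_deg, flexion_peak_ratio, stance_fraction)


@dataclass
class GaitParams:
    """Everything that defines one simulated limb trial.

    Units: speeds m/s, lengths m, angles degrees, rates Hz.
    ``lameness_factor`` scales the FJA amplitude of a lame limb (1 = sound).
    """

    gait: str = "trot"
    speed_mps: float | None = None
    stride_length_m: float | None = None
    n_strides: int = 5
    rom_deg: float | None = None
    lameness_factor: float = 1.0
    flexion_peak_ratio: float = 0.9
    imu_rate_hz: float = 200.0
    omc_rate_hz: float = 60.0
    gyro_noise_sd_dps: float = 2.0
    marker_noise_sd_m: float = 0.001
    seed: int = 0
    # artifact-level knobs beyond the headline study conditions
    stance_fraction: float | None = None
    standing_s: float = 1.0
    trailing_s: float = 0.5
    swing_excursion_deg: float = 40.0
    soft_tissue_amp_m: float = 0.002
    soft_tissue_cutoff_hz: float = 3.0
    orientation_noise_sd_deg: float = 0.3
    standing_angle_deg: float = -10.0
    segment_lengths_m: tuple[float, float] = (0.25, 0.10)

    def __post_init__(self) -> None:
        if self.gait not in ("walk", "trot"):
            raise ValueError(f"unknown gait {self.gait!r}")
        if self.speed_mps is None:
            self.speed_mps = DEFAULT_SPEED[self.gait]
        if self.stride_length_m is None:
            self.stride_length_m = DEFAULT_STRIDE_LENGTH[self.gait]
        if self.rom_deg is None:
            self.rom_deg = DEFAULT_ROM_MEAN[(self.gait, "front")]
        if self.stance_fraction is None:
            self.stance_fraction = DEFAULT_STANCE_FRACTION[self.gait]
        numeric = [self.speed_mps, self.stride_length_m, self.rom_deg,
                   self.lameness_factor, self.flexion_peak_ratio,
                   self.gyro_noise_sd_dps, self.marker_noise_sd_m]
        if not all(np.isfinite(v) for v in numeric):
            raise ValueError("GaitParams values must be finite")
        if self.speed_mps <= 0 or self.stride_length_m <= 0:
            raise ValueError("speed and stride length must be positive")
        if self.rom_deg <= 0:
            raise ValueError("rom_deg must be positive")
        if not 0 < self.lameness_factor <= 1:
            raise ValueError("lameness_factor must be in (0, 1]")
        if self.n_strides < 3:
            raise ValueError("n_strides must be at least 3")
        if self.imu_rate_hz <= self.omc_rate_hz:
            raise ValueError("IMU rate must exceed OMC rate")

    @property
    def stride_duration_s(self) -> float:
        return self.stride_length_m / self.speed_mps


def default_gait_params(gait: str, pair: str = "front", **overrides: Any) -> GaitParams:
    """Study-default parameters for one gait and limb pair."""
    if pair not in ("front", "hind"):
        raise ValueError("pair must be 'front' or 'hind'")
    kw: dict[str, Any] = {"gait": gait, "rom_deg": DEFAULT_ROM_MEAN[(gait, pair)]}
    kw.update(overrides)
    return GaitParams(**kw)


@dataclass
class LimbRecording:
    """One limb's paired raw observations plus the planted ground truth."""

    limb_id: str
    quat_cannon: np.ndarray     # (n, 4) unit quaternions, scalar-first (w, x, y, z), 200 Hz
    quat_pastern: np.ndarray
    gyro_pastern: np.ndarray    # (n, 3) angular velocity, deg/s
    markers: dict[str, np.ndarray]  # {'proximal','fetlock','distal'} -> (m, 2) metres, 60 Hz
    imu_rate_hz: float
    omc_rate_hz: float
    truth_fja: AngleSeries
    truth_toe_on_s: np.ndarray = field(default_factory=lambda: np.array([]))
    truth_toe_off_s: np.ndarray = field(default_factory=lambda: np.array([]))
    planted_rom_deg: float | None = None  # lameness_factor × rom_deg, exact
    params: GaitParams | None = None

    def __post_init__(self) -> None:
        for q in (self.quat_cannon, self.quat_pastern):
            norms = np.linalg.norm(q, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("segment quaternions must be unit-norm within 1e-9")
        imu_span = (len(self.truth_fja) - 1) / self.imu_rate_hz
        omc_span = (self.markers["fetlock"].shape[0] - 1) / self.omc_rate_hz
        if abs(imu_span - omc_span) > 1.0 / self.omc_rate_hz:
            raise ValueError("IMU and OMC streams must cover the same span "
                             "within one OMC frame")


def _angles_to_quat_y(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation about the mediolateral (y) axis -> scalar-first quaternions."""
    half = 0.5 * np.deg2rad(np.asarray(angles_deg, dtype=float))
    zeros = np.zeros_like(half)
    return np.column_stack([np.cos(half), zeros, np.sin(half), zeros])


def _lowpass_noise(rng: np.random.Generator, n: int, rate_hz: float,
                   cutoff_hz: float, sd: float) -> np.ndarray:
    """Gaussian noise band-limited below ``cutoff_hz`` and rescaled to ``sd``."""
    white = rng.standard_normal(n)
    if n < 30 or cutoff_hz >= rate_hz / 2:
        return sd * white
    b, a = butter(2, cutoff_hz / (rate_hz / 2))
    smooth = filtfilt(b, a, white)
    s = smooth.std()
    return sd * smooth / s if s > 0 else smooth


class _LimbKinematics:
    """Analytic time-course of the planted limb motion (no noise)."""

    def __init__(self, params: GaitParams, phase_offset: float):
        self.p = params
        self.phi0 = float(phase_offset) % 1.0
        self.T = params.stride_duration_s
        self.wave = make_fja_waveform(params.gait, params.rom_deg,
                                      params.flexion_peak_ratio, params.stance_fraction)
        self.f = self.wave.stance_fraction
        self.t_gait0 = params.standing_s
        # gait runs until a quiet mid-stance phase so it can blend into standing
        self.gait_dur = (params.n_strides + self.wave.quiet_phase - self.phi0) * self.T
        self.t_gait1 = self.t_gait0 + self.gait_dur
        self.ramp_in_s = 0.5 * (1.0 - self.phi0) * self.T
        self.ramp_out_s = 0.2
        self.total_s = self.t_gait1 + self.ramp_out_s + params.trailing_s

    def phase(self, t: np.ndarray) -> np.ndarray:
        return self.phi0 + (t - self.t_gait0) / self.T

    def _ramp_in(self, t: np.ndarray) -> np.ndarray:
        return _smoothstep((t - self.t_gait0) / self.ramp_in_s)

    def fja(self, t: np.ndarray) -> np.ndarray:
        """Planted FJA (deg), lameness scaling included."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        gait = (t >= self.t_gait0) & (t < self.t_gait1)
        out[gait] = self._ramp_in(t[gait]) * self.wave(self.phase(t[gait]))
        tail = (t >= self.t_gait1) & (t < self.t_gait1 + self.ramp_out_s)
        resid = self.wave(np.array([self.wave.quiet_phase]))[0]
        out[tail] = resid * (1.0 - _smoothstep((t[tail] - self.t_gait1) / self.ramp_out_s))
        return self.p.lameness_factor * out

    def _swing_bump(self, ph: np.ndarray) -> np.ndarray:
        """sin^2 protraction profile, compact support on the swing phase."""
        frac = ph % 1.0
        u = (frac - self.f) / (1.0 - self.f)
        out = np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2
        out[(u < 0.0) | (u > 1.0)] = 0.0
        return out

    def _swing_bump_deriv(self, ph: np.ndarray) -> np.ndarray:
        frac = ph % 1.0
        u = (frac - self.f) / (1.0 - self.f)
        out = np.pi * np.sin(2.0 * np.pi * u) / (1.0 - self.f)
        out[(u < 0.0) | (u > 1.0)] = 0.0
        return out

    def pastern_angle(self, t: np.ndarray) -> np.ndarray:
        """Pastern global orientation (deg): quiet in stance, swing excursion."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        gait = (t >= self.t_gait0) & (t < self.t_gait1)
        out[gait] = (self._ramp_in(t[gait]) * self.p.swing_excursion_deg
                     * self._swing_bump(self.phase(t[gait])))
        return out

    def pastern_rate(self, t: np.ndarray) -> np.ndarray:
        """Analytic d/dt of the pastern global orientation (deg/s)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        gait = (t >= self.t_gait0) & (t < self.t_gait1)
        tg = t[gait]
        ph = self.phase(tg)
        r = self._ramp_in(tg)
        dr = _smoothstep_deriv((tg - self.t_gait0) / self.ramp_in_s) / self.ramp_in_s
        P = self.p.swing_excursion_deg
        out[gait] = dr * P * self._swing_bump(ph) + r * P * self._swing_bump_deriv(ph) / self.T
        return out

    def toe_events(self) -> tuple[np.ndarray, np.ndarray]:
        """Planted toe-on and toe-off times (s)."""
        n = self.p.n_strides
        end_phase = n + self.wave.quiet_phase
        toe_on_ph = np.arange(np.floor(self.phi0) + 1, np.floor(end_phase) + 1)
        toe_on_ph = toe_on_ph[(toe_on_ph > self.phi0) & (toe_on_ph <= end_phase)]
        k = np.arange(0, n)
        toe_off_ph = k + self.f
        toe_off_ph = toe_off_ph[(toe_off_ph > self.phi0) & (toe_off_ph <= end_phase)]
        to_t = self.t_gait0 + (toe_on_ph - self.phi0) * self.T
        tf_t = self.t_gait0 + (toe_off_ph - self.phi0) * self.T
        return to_t, tf_t


def simulate_limb(params: GaitParams, limb_id: str = "LF", phase_offset: float = 0.0,
                  seed: int | None = None) -> LimbRecording:
    """Simulate one limb's IMU and OMC observations for a gait trial.

    The record is a standing prelude (used by the IMU standing calibration),
    ``n_strides`` gait cycles blending smoothly in and out of standing, and a
    short trailing standing window.  Noise-free when all noise SDs are zero.
    """
    if limb_id not in LIMB_IDS:
        raise ValueError(f"unknown limb id {limb_id!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    kin = _LimbKinematics(params, phase_offset)

    n_imu = int(round(kin.total_s * params.imu_rate_hz)) + 1
    t_imu = np.arange(n_imu) / params.imu_rate_hz
    n_omc = int(kin.total_s * params.omc_rate_hz) + 1
    t_omc = np.arange(n_omc) / params.omc_rate_hz

    fja = kin.fja(t_imu)
    pastern = kin.pastern_angle(t_imu)
    delta0 = params.standing_angle_deg
    cannon = pastern - (delta0 + fja)

    jitter = (rng.standard_normal(n_imu) * params.orientation_noise_sd_deg
              if params.orientation_noise_sd_deg > 0 else np.zeros(n_imu))
    quat_cannon = _angles_to_quat_y(cannon)
    quat_pastern = _angles_to_quat_y(pastern + jitter)

    gyro = np.zeros((n_imu, 3))
    gyro[:, 1] = kin.pastern_rate(t_imu)
    if params.gyro_noise_sd_dps > 0:
        gyro += rng.standard_normal((n_imu, 3)) * params.gyro_noise_sd_dps

    # OMC two-link marker chain (left-side view: x forward, y up)
    fja_o = kin.fja(t_omc)
    pastern_o = kin.pastern_angle(t_omc)
    cannon_o = pastern_o - (delta0 + fja_o)
    L_c, L_p = params.segment_lengths_m
    travel = params.speed_mps * np.clip(t_omc - kin.t_gait0, 0.0, kin.gait_dur)
    bob = 0.02 * np.sin(2.0 * np.pi * kin.phase(np.clip(t_omc, kin.t_gait0, kin.t_gait1)))
    fet = np.column_stack([travel, 0.12 + bob])
    rad_c = np.deg2rad(cannon_o)
    prox = fet + L_c * np.column_stack([-np.sin(rad_c), np.cos(rad_c)])
    rad_p = np.deg2rad(cannon_o + delta0 + fja_o)  # equals the pastern global angle
    dist = fet + L_p * np.column_stack([np.sin(rad_p), -np.cos(rad_p)])

    markers = {"proximal": prox, "fetlock": fet, "distal": dist}
    for name, pos in markers.items():
        noisy = pos.copy()
        if params.soft_tissue_amp_m > 0:
            # amplitude = excursion envelope (~2 SD) of the band-limited process
            for j in range(2):
                noisy[:, j] += _lowpass_noise(rng, n_omc, params.omc_rate_hz,
                                              params.soft_tissue_cutoff_hz,
                                              params.soft_tissue_amp_m / 2.0)
        if params.marker_noise_sd_m > 0:
            noisy += rng.standard_normal((n_omc, 2)) * params.marker_noise_sd_m
        markers[name] = noisy

    truth = AngleSeries(fja, params.imu_rate_hz, t0=0.0, convention="common",
                        meta={"limb_id": limb_id, "gait": params.gait, "source": "truth"})
    toe_on, toe_off = kin.toe_events()
    return LimbRecording(
        limb_id=limb_id,
        quat_cannon=quat_cannon,
        quat_pastern=quat_pastern,
        gyro_pastern=gyro,
        markers=markers,
        imu_rate_hz=params.imu_rate_hz,
        omc_rate_hz=params.omc_rate_hz,
        truth_fja=truth,
        truth_toe_on_s=toe_on,
        truth_toe_off_s=toe_off,
        planted_rom_deg=params.lameness_factor * params.rom_deg,
        params=params,
    )


@dataclass
class HorseTrial:
    """One horse × gait trial: four limb recordings plus lameness metadata."""

    horse_id: str
    is_lame: bool
    lame_limb: str | None
    gait: str
    recordings: dict[str, LimbRecording]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_lame and (self.lame_limb not in LIMB_IDS):
            raise ValueError("a lame trial must name exactly one lame limb")
        if not self.is_lame and self.lame_limb is not None:
            raise ValueError("a sound trial cannot name a lame limb")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (one gait per call).

    Defaults target the reported group structure: sound left–right FJROM
    asymmetry giving ~3% (front) and ~4% (hind) coefficients of variation,
    and a lame-limb amplitude reduction whose left–right CV lands near 15%
    at walk and near 7% at trot (the reduction is halved at trot).
    """

    gait: str = "trot"
    n_strides: int = 5
    # log-scale left-right asymmetry SDs: a pair CV of c% needs
    # sigma ≈ c / (100·sqrt(2)·sqrt(2/pi)); 0.053 → ~3% (front), 0.069 → ~3.9% (hind)
    asym_sd_front: float = 0.053
    asym_sd_hind: float = 0.069
    lameness_factor_range: tuple[float, float] = (0.70, 0.85)
    trot_lameness_attenuation: float = 0.5
    rom_mean: dict = field(default_factory=lambda: dict(DEFAULT_ROM_MEAN))
    rom_sd: dict = field(default_factory=lambda: dict(DEFAULT_ROM_SD))
    gyro_noise_sd_dps: float = 2.0
    marker_noise_sd_m: float = 0.001
    soft_tissue_amp_m: float = 0.002
    orientation_noise_sd_deg: float = 0.3

    def limb_params(self, gait: str, pair: str, rom: float, factor: float,
                    seed: int) -> GaitParams:
        return GaitParams(
            gait=gait, n_strides=self.n_strides, rom_deg=rom,
            lameness_factor=factor, seed=seed,
            gyro_noise_sd_dps=self.gyro_noise_sd_dps,
            marker_noise_sd_m=self.marker_noise_sd_m,
            soft_tissue_amp_m=self.soft_tissue_amp_m,
            orientation_noise_sd_deg=self.orientation_noise_sd_deg,
        )


def _horse_draws(config: CohortConfig, seed: int, idx: int, lame: bool) -> dict[str, Any]:
    """Per-horse random morphology, independent of gait so that walk and trot
    cohorts generated from the same seed share horses."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), idx]))
    z = {"front": rng.standard_normal(), "hind": rng.standard_normal()}
    asym = {
        "front": float(np.exp(rng.normal(0.0, config.asym_sd_front))),
        "hind": float(np.exp(rng.normal(0.0, config.asym_sd_hind))),
    }
    lo, hi = config.lameness_factor_range
    return {
        "rom_z": z,
        "asym": asym,
        "lame_limb": str(rng.choice(LIMB_IDS)) if lame else None,
        "lameness_factor_walk": float(rng.uniform(lo, hi)) if lame else 1.0,
    }


def simulate_cohort(n_sound: int, n_lame: int, config: CohortConfig | None = None,
                    seed: int = 0) -> list[HorseTrial]:
    """Simulate a cohort of sound and single-limb-lame horses at one gait.

    Sound horses get per-horse limb-pair ROMs drawn around the group means
    with a small left–right asymmetry; each lame horse gets one randomly
    assigned lame limb whose FJA amplitude is scaled down, the contralateral
    limb carrying exactly the unscaled amplitude so the planted lame-to-
    contralateral ROM ratio equals the lameness factor.
    """
    if n_sound < 0 or n_lame < 0 or n_sound + n_lame < 1:
        raise ValueError("cohort must contain at least one horse")
    config = config or CohortConfig()
    gait = config.gait
    gait_code = 0 if gait == "walk" else 1
    trials: list[HorseTrial] = []
    for idx in range(n_sound + n_lame):
        lame = idx >= n_sound
        horse_id = f"h{idx + 1:02d}"
        draws = _horse_draws(config, seed, idx, lame)
        factor = draws["lameness_factor_walk"]
        if lame and gait == "trot":
            factor = 1.0 - config.trot_lameness_attenuation * (1.0 - factor)
        realized_factor = factor
        if lame:
            # the realized lame/contralateral amplitude ratio includes the
            # pair's natural left-right asymmetry, so factor=1 reproduces a
            # sound pair; the planted ROM ratio equals realized_factor exactly
            pair_asym = draws["asym"][limb_pair(draws["lame_limb"])]
            direction = pair_asym if draws["lame_limb"].startswith("R") else 1.0 / pair_asym
            realized_factor = factor * direction
        recordings: dict[str, LimbRecording] = {}
        for l_idx, limb in enumerate(LIMB_IDS):
            pair = limb_pair(limb)
            base_rom = (config.rom_mean[(gait, pair)]
                        + draws["rom_z"][pair] * config.rom_sd[(gait, pair)])
            base_rom = max(base_rom, 10.0)
            rom = base_rom * (draws["asym"][pair] if limb.startswith("R") else 1.0)
            limb_factor = factor if limb == draws["lame_limb"] else 1.0
            limb_seed = ((int(seed) % (2**20)) * 1024 + idx * 16 + l_idx * 4
                         + gait_code) % (2**31)
            params = config.limb_params(gait, pair, rom, limb_factor, limb_seed)
            recordings[limb] = simulate_limb(
                params, limb, GAIT_PHASE_OFFSETS[gait][limb], seed=limb_seed)
        trials.append(HorseTrial(
            horse_id=horse_id, is_lame=lame, lame_limb=draws["lame_limb"],
            gait=gait, recordings=recordings,
            meta={"seed": seed,
                  "lameness_factor": realized_factor if lame else 1.0,
                  "drawn_lameness_factor": factor if lame else 1.0},
        ))
    return trials
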