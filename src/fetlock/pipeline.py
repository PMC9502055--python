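"""End-to-end processing of the paired angle traces.

The processing chain, applied per limb and gait trial: resample the 60 Hz
optical trace to the 200 Hz sensor grid with a cubic spline, low-pass both
channels with a zero-phase 4th-order Butterworth at 10 Hz, synchronise the
two traces at the absolute minimum between their first two prominent maxima,
align them vertically at that point, segment strides from the resultant
angular velocity of the pastern gyroscope, and report the mean fetlock range
of motion over three strides.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks, periodogram

from .series import AngleSeries, FJROMSummary, StrideEvents, SyncResult


def resample_spline(series: AngleSeries, target_rate_hz: float = 200.0) -> AngleSeries:
    """Resample an angle trace onto a faster uniform grid with a cubic spline.

    Uses a not-a-knot cubic spline evaluated on the target grid spanning the
    original time range only (no extrapolation); the first sample is shared
    with the original grid, so the starting endpoint is preserved exactly.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 samples for cubic spline resampling")
    t = series.times
    spline = CubicSpline(t, series.values, bc_type="not-a-knot")
    n_new = int(np.floor((t[-1] - t[0]) * target_rate_hz + 1e-9)) + 1
    t_new = t[0] + np.arange(n_new) / target_rate_hz
    vals = spline(t_new)
    return AngleSeries(vals, target_rate_hz, t0=series.t0,
                       convention=series.convention,
                       meta=dict(series.meta, resampled_from=series.rate_hz))


def butter_lowpass(series: AngleSeries, cutoff_hz: float = 10.0,
                   order: int = 4) -> AngleSeries:
    """Zero-phase (forward–backward) Butterworth low-pass of an angle trace.

    Zero-phase application squares the magnitude response and cancels the
    phase, so pass-band timing is untouched — a requirement for the
    synchronisation step, which compares waveform timing between channels.
    DC gain is unity.
    """
    if series.rate_hz <= 2.0 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff frequency")
    b, a = butter(order, cutoff_hz / (series.rate_hz / 2.0))
    padlen = 3 * max(len(a), len(b))
    if len(series) <= 3 * padlen:
        raise ValueError(f"series too short to filter stably "
                         f"(need > {3 * padlen} samples, got {len(series)})")
    return series.with_values(filtfilt(b, a, series.values))


def _dominant_period_s(values: np.ndarray, rate_hz: float) -> float | None:
    """Period of the strongest non-DC spectral component, if any."""
    freqs, power = periodogram(values - values.mean(), fs=rate_hz)
    if freqs.size < 3:
        return None
    k = int(np.argmax(power[1:])) + 1
    return None if freqs[k] <= 0 else 1.0 / freqs[k]


def find_sync_point(series: AngleSeries, prominence_frac: float = 0.2,
                    min_separation_s: float | None = None,
                    height_frac: float = 0.5) -> int:
    """Index of the absolute minimum between the first two prominent maxima.

    Maxima qualify with prominence ≥ ``prominence_frac`` of the series'
    peak-to-peak range, height within the top ``1 − height_frac`` of the
    range (the flexion peaks; a partial mid-stance rebound sits near
    mid-range and must not count), and mutual separation ≥
    ``min_separation_s`` (default 0.2 × the dominant period, which keeps the
    two flexion peaks of one stride from counting as separate
    synchronisation maxima).
    """
    v = series.values
    ptp = float(v.max() - v.min())
    if ptp <= 0:
        raise ValueError("series is constant; no synchronisation maxima exist")
    if min_separation_s is None:
        period = _dominant_period_s(v, series.rate_hz)
        min_separation_s = 0.2 * period if period else 0.0
    distance = max(1, int(round(min_separation_s * series.rate_hz)))
    peaks, _ = find_peaks(v, prominence=prominence_frac * ptp, distance=distance,
                          height=v.min() + height_frac * ptp)
    if peaks.size < 2:
        raise ValueError(
            f"need at least two prominent maxima for synchronisation; "
            f"found peak indices {peaks.tolist()}")
    lo, hi = int(peaks[0]), int(peaks[1])
    if hi - lo < 2:
        raise ValueError("first two maxima are adjacent; no interior minimum")
    return lo + 1 + int(np.argmin(v[lo + 1:hi]))


def synchronize_and_align(imu: AngleSeries, omc: AngleSeries,
                          prominence_frac: float = 0.2,
                          min_separation_s: float | None = None
                          ) -> tuple[AngleSeries, AngleSeries, SyncResult]:
    """Synchronise the two channels in time and align them vertically.

    Both series must share the sampling rate (resample the optical trace
    first).  Each is cropped to the overlapping window in which their
    synchronisation points coincide; the optical trace is then shifted on
    the angle axis by the difference of the two at the synchronisation
    sample, so the channels are equal there.
    """
    if imu.rate_hz != omc.rate_hz:
        raise ValueError("synchronisation requires a common sampling rate")
    i_sync = find_sync_point(imu, prominence_frac, min_separation_s)
    o_sync = find_sync_point(omc, prominence_frac, min_separation_s)
    shift = i_sync - o_sync
    i_start, o_start = max(0, shift), max(0, -shift)
    n = min(len(imu) - i_start, len(omc) - o_start)
    if n < 2:
        raise ValueError("series do not overlap after synchronisation")
    imu_c = imu.crop(i_start, i_start + n)
    omc_c = omc.crop(o_start, o_start + n)
    y_offset = float(omc.values[o_sync] - imu.values[i_sync])
    omc_c = omc_c.with_values(omc_c.values - y_offset, convention=imu_c.convention)
    omc_c.t0 = imu_c.t0  # channels now share the sensor clock
    return imu_c, omc_c, SyncResult(
        imu_sync_index=i_sync, omc_sync_index=o_sync, y_offset_deg=y_offset,
        imu_start=i_start, omc_start=o_start, n_overlap=n)


def segment_strides(gyro_resultant: np.ndarray, rate_hz: float = 200.0,
                    low_frac: float = 0.08, high_frac: float = 0.15,
                    min_stance_s: float = 0.08,
                    smooth_cutoff_hz: float | None = 10.0) -> StrideEvents:
    """Detect toe-on/toe-off events from the resultant angular velocity.

    Stance is a sustained low-velocity interval found by hysteresis
    thresholding: enter stance when the (optionally low-passed) resultant
    falls below ``low_frac`` × the robust maximum, leave when it rises above
    ``high_frac`` × the robust maximum.  Stances shorter than
    ``min_stance_s`` are discarded, as is a stance already in progress when
    the record starts (its toe-on was not observed).  Toe-on is the stance
    entry, toe-off the stance exit; the final toe-on may lack a toe-off when
    the record ends inside a stance.
    """
    v = np.asarray(gyro_resultant, dtype=float)
    if v.ndim != 1:
        raise ValueError("gyro resultant must be one-dimensional")
    if v.size < int(rate_hz):
        raise ValueError("need at least 1 s of data for stride segmentation")
    if smooth_cutoff_hz is not None and rate_hz > 2.0 * smooth_cutoff_hz:
        b, a = butter(4, smooth_cutoff_hz / (rate_hz / 2.0))
        v = np.abs(filtfilt(b, a, v))
    robust_max = float(np.percentile(v, 98))
    if robust_max <= 0 or v.max() - v.min() <= 1e-12:
        raise ValueError("no swing activity detected in the resultant velocity")
    th_low, th_high = low_frac * robust_max, high_frac * robust_max
    if th_high <= v.min():
        raise ValueError("no swing activity detected in the resultant velocity")

    min_len = max(1, int(round(min_stance_s * rate_hz)))
    toe_on: list[int] = []
    toe_off: list[int] = []
    in_stance = bool(v[0] < th_low)
    entry = 0 if in_stance else -1
    opening = in_stance  # stance in progress at record start: entry unseen
    for i in range(1, v.size):
        if not in_stance and v[i] < th_low:
            in_stance, entry = True, i
        elif in_stance and v[i] > th_high:
            if not opening and i - entry >= min_len:
                toe_on.append(entry)
                toe_off.append(i)
            in_stance, opening = False, False
    if in_stance and not opening and v.size - entry >= min_len:
        toe_on.append(entry)  # record ends mid-stance: keep toe-on only
    if not toe_on:
        raise ValueError("no stance interval found")
    return StrideEvents(np.array(toe_on), np.array(toe_off))


def compute_fjrom(fja: AngleSeries, events: StrideEvents,
                  n_strides: int = 3) -> FJROMSummary:
    """Mean fetlock range of motion over the first ``n_strides`` strides.

    Per stride (toe-on to next toe-on) the range of motion is
    ``|max(FJA) − min(FJA)|`` over that stride's samples; the summary mean
    is taken over the first ``n_strides`` complete strides.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be at least 1")
    slices = [s for s in events.stride_slices() if s.stop <= len(fja)]
    if len(slices) < n_strides:
        raise ValueError(f"found only {len(slices)} complete strides, "
                         f"need {n_strides}")
    roms = [float(np.abs(fja.values[s].max() - fja.values[s].min()))
            for s in slices[:n_strides]]
    return FJROMSummary(per_stride_rom=np.array(roms), n_strides_used=n_strides)
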