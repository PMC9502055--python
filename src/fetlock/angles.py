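"""Sagittal fetlock joint angle extraction from the two observation channels.

IMU channel: the relative orientation of the cannon- and pastern-mounted
sensors (``conjugate(cannon) ∘ pastern``), reduced to the signed rotation
about the mediolateral axis, and zeroed at the standing calibration pose so
flexion is positive and extension negative.

OMC channel: the dorsal angle of the pastern axis relative to the
prolongation of the metacarpus/metatarsus axis, from the three joint-centre
markers; the sign is remapped so flexion increases the angle, matching the
IMU convention up to the standing offset.
"""

from __future__ import annotations

import warnings

import numpy as np

from .series import AngleSeries, CalibrationState

ML_AXIS = np.array([0.0, 1.0, 0.0])  # mediolateral = y in the sensor frame


def _check_quaternions(q: np.ndarray, name: str) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError(f"{name} must be an (n, 4) array of (w, x, y, z) quaternions")
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms == 0) or not np.all(np.isfinite(norms)):
        raise ValueError(f"{name} contains zero-norm or non-finite quaternions")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        warnings.warn(f"{name} quaternions deviate from unit norm; renormalizing",
                      stacklevel=3)
    return q / norms[:, None]


def relative_sagittal_angle(quat_cannon: np.ndarray, quat_pastern: np.ndarray,
                            rate_hz: float = 200.0, t0: float = 0.0,
                            meta: dict | None = None) -> AngleSeries:
    """Signed sagittal joint angle from two segment orientation streams.

    Per sample the relative rotation is ``conjugate(cannon) ∘ pastern``; its
    twist about the mediolateral axis is extracted (swing–twist
    decomposition), wrapped to (−180°, 180°] and then unwrapped across
    samples.  The result is offset by the standing pose; use
    :func:`apply_calibration` to zero it.
    """
    qa = _check_quaternions(quat_cannon, "quat_cannon")
    qb = _check_quaternions(quat_pastern, "quat_pastern")
    if qa.shape[0] != qb.shape[0]:
        raise ValueError("quaternion sequences must have the same length")

    # Hamilton product conjugate(qa) * qb, scalar-first components
    wa, xa, ya, za = qa[:, 0], -qa[:, 1], -qa[:, 2], -qa[:, 3]
    wb, xb, yb, zb = qb[:, 0], qb[:, 1], qb[:, 2], qb[:, 3]
    w = wa * wb - xa * xb - ya * yb - za * zb
    x = wa * xb + xa * wb + ya * zb - za * yb
    y = wa * yb - xa * zb + ya * wb + za * xb
    z = wa * zb + xa * yb - ya * xb + za * wb

    # twist about the mediolateral axis: 2*atan2(q·axis, q_w)
    proj = x * ML_AXIS[0] + y * ML_AXIS[1] + z * ML_AXIS[2]
    angle = 2.0 * np.arctan2(proj, w)
    angle = (angle + np.pi) % (2.0 * np.pi) - np.pi  # (−180°, 180°] before unwrapping
    angle = np.unwrap(angle)
    return AngleSeries(np.rad2deg(angle), rate_hz, t0=t0, convention="imu_raw",
                       meta=dict(meta or {}, source="imu"))


def apply_calibration(series: AngleSeries,
                      calib_window: float | tuple[float, float]
                      ) -> tuple[AngleSeries, CalibrationState]:
    """Zero an IMU angle trace at the standing calibration pose.

    ``calib_window`` is either a duration in seconds measured from the start
    of the series, or an explicit ``(start_s, stop_s)`` pair on the series'
    own time axis.  The window must cover at least 0.5 s of data; its mean
    angle becomes the zero offset.
    """
    if isinstance(calib_window, (tuple, list)):
        start_s, stop_s = float(calib_window[0]), float(calib_window[1])
    else:
        start_s, stop_s = series.t0, series.t0 + float(calib_window)
    if stop_s - start_s < 0.5:
        raise ValueError("calibration window must cover at least 0.5 s")
    i0 = int(round((start_s - series.t0) * series.rate_hz))
    i1 = int(round((stop_s - series.t0) * series.rate_hz))
    if i0 < 0 or i1 > len(series) or i1 - i0 < 2:
        raise ValueError("calibration window lies outside the series")
    offset = float(np.mean(series.values[i0:i1]))
    zeroed = series.with_values(series.values - offset, convention="imu_zeroed")
    return zeroed, CalibrationState(zero_offset_deg=offset)


def fja_from_markers(markers: dict[str, np.ndarray], rate_hz: float = 60.0,
                     t0: float = 0.0, max_bad_frac: float = 0.10,
                     meta: dict | None = None) -> AngleSeries:
    """Dorsal fetlock angle from the three planar joint-centre markers.

    The metacarpus axis runs fetlock→proximal and the pastern axis
    fetlock→distal; the returned angle is the signed planar angle between the
    pastern axis and the prolongation of the metacarpus axis, with dorsal
    rotation of the pastern (fetlock flexion) positive.  Frames in which two
    markers coincide are interpolated from their neighbours; more than
    ``max_bad_frac`` such frames rejects the input.
    """
    try:
        prox = np.asarray(markers["proximal"], dtype=float)
        fet = np.asarray(markers["fetlock"], dtype=float)
        dist = np.asarray(markers["distal"], dtype=float)
    except KeyError as exc:
        raise ValueError(f"markers missing {exc} positions") from exc
    if prox.shape != fet.shape or dist.shape != fet.shape or fet.ndim != 2 or fet.shape[1] != 2:
        raise ValueError("marker arrays must share shape (n, 2)")
    n = fet.shape[0]
    if n < 3:
        raise ValueError("need at least 3 marker frames")

    m_axis = prox - fet
    p_axis = dist - fet
    bad = (np.linalg.norm(m_axis, axis=1) < 1e-9) | (np.linalg.norm(p_axis, axis=1) < 1e-9)
    if bad.mean() > max_bad_frac:
        raise ValueError(f"{bad.sum()}/{n} frames have coincident markers "
                         f"(> {max_bad_frac:.0%} allowed)")

    prolong = -m_axis
    cross = prolong[:, 0] * p_axis[:, 1] - prolong[:, 1] * p_axis[:, 0]
    dot = np.sum(prolong * p_axis, axis=1)
    angle = np.arctan2(cross, dot)

    good = ~bad
    if bad.any():
        idx = np.arange(n)
        # unwrap over good frames first so interpolation crosses no wrap jump
        angle_good = np.unwrap(angle[good])
        angle = np.interp(idx, idx[good], angle_good)
    else:
        angle = np.unwrap(angle)
    return AngleSeries(np.rad2deg(angle), rate_hz, t0=t0, convention="omc_dorsal",
                       meta=dict(meta or {}, source="omc"))


def resultant_angular_velocity(gyro: np.ndarray) -> np.ndarray:
    """Euclidean norm of the triaxial gyroscope signal, per sample (deg/s)."""
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim != 2 or gyro.shape[1] != 3:
        raise ValueError("gyro must be an (n, 3) array")
    if not np.all(np.isfinite(gyro)):
        raise ValueError("gyro samples must be finite")
    return np.linalg.norm(gyro, axis=1)
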