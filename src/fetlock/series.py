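"""Light-weight containers shared across the pipeline.

The canonical angle convention of this package ("common") is the one the IMU
channel produces after standing calibration: 0° at the square standing pose,
fetlock flexion positive, extension negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Recognised angle sign/offset conventions.
CONVENTIONS = ("imu_raw", "imu_zeroed", "omc_dorsal", "common")


@dataclass
class AngleSeries:
    """A uniformly sampled joint-angle trace.

    Samples live on the implicit grid ``t0 + k / rate_hz``.  ``convention``
    tags whether the series is zeroed at the standing pose (IMU channel) or
    expressed as the optical dorsal angle (which differs by the standing
    offset only).
    """

    values: np.ndarray
    rate_hz: float
    t0: float = 0.0
    convention: str = "common"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AngleSeries values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AngleSeries values must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.convention!r}; expected one of {CONVENTIONS}"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate_hz

    @property
    def duration(self) -> float:
        """Time span from first to last sample, in seconds."""
        return (self.values.size - 1) / self.rate_hz

    def crop(self, start: int, stop: int) -> "AngleSeries":
        """Return the sample slice ``[start, stop)`` as a new series."""
        if not 0 <= start < stop <= self.values.size:
            raise ValueError(f"crop [{start}, {stop}) outside series of length {len(self)}")
        return replace(
            self,
            values=self.values[start:stop].copy(),
            t0=self.t0 + start / self.rate_hz,
            meta=dict(self.meta),
        )

    def with_values(self, values: np.ndarray, convention: str | None = None) -> "AngleSeries":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            convention=convention or self.convention,
            meta=dict(self.meta),
        )


@dataclass
class CalibrationState:
    """Standing-pose zero offset removed from an IMU angle trace."""

    zero_offset_deg: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.zero_offset_deg):
            raise ValueError("zero offset must be finite")


@dataclass
class StrideEvents:
    """Toe-on / toe-off sample indices on a 200 Hz grid.

    A complete stride is ``toe_on[k] .. toe_on[k+1]``.  The final toe-on may
    lack a matching toe-off when the recording ends inside a stance.
    """

    toe_on: np.ndarray
    toe_off: np.ndarray

    def __post_init__(self) -> None:
        self.toe_on = np.asarray(self.toe_on, dtype=int)
        self.toe_off = np.asarray(self.toe_off, dtype=int)
        for name, idx in (("toe_on", self.toe_on), ("toe_off", self.toe_off)):
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} indices must be strictly increasing")
        if self.toe_off.size not in (self.toe_on.size, self.toe_on.size - 1):
            raise ValueError("toe_off count must equal toe_on count or be one short")
        n = self.toe_off.size
        if n and not np.all(self.toe_off > self.toe_on[:n]):
            raise ValueError("each toe_off must follow its toe_on")
        m = min(n, self.toe_on.size - 1)
        if m and not np.all(self.toe_off[:m] < self.toe_on[1 : 1 + m]):
            raise ValueError("toe_on and toe_off events must alternate")

    @property
    def n_complete_strides(self) -> int:
        return max(0, self.toe_on.size - 1)

    def stride_slices(self) -> list[slice]:
        """Sample slices of the complete strides, in temporal order."""
        return [
            slice(int(a), int(b) + 1)
            for a, b in zip(self.toe_on[:-1], self.toe_on[1:])
        ]


@dataclass
class SyncResult:
    """Outcome of synchronising the IMU and OMC angle traces.

    ``imu_sync_index`` / ``omc_sync_index`` are indices into the *original*
    series; ``imu_start`` / ``omc_start`` locate the returned overlapping
    window in the originals (useful to crop auxiliary streams, e.g. the
    gyroscope, onto the same window).
    """

    imu_sync_index: int
    omc_sync_index: int
    y_offset_deg: float
    imu_start: int = 0
    omc_start: int = 0
    n_overlap: int = 0

    @property
    def lag_samples(self) -> int:
        """IMU sync index minus OMC sync index."""
        return self.imu_sync_index - self.omc_sync_index


@dataclass
class FJROMSummary:
    """Per-stride fetlock range of motion and its mean over the strides used."""

    per_stride_rom: np.ndarray
    n_strides_used: int

    def __post_init__(self) -> None:
        self.per_stride_rom = np.asarray(self.per_stride_rom, dtype=float)
        if np.any(self.per_stride_rom < 0):
            raise ValueError("per-stride ROM must be non-negative")

    @property
    def mean_rom(self) -> float:
        return float(np.mean(self.per_stride_rom))
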