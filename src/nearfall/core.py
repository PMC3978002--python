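"""Core data model and shared signal operations.

A :class:`SensorRecording` holds the six synchronously sampled channels of a
lower-back inertial sensor: vertical, medio-lateral and anterior-posterior
acceleration (units of g) and yaw, pitch and roll angular velocity (deg/s).
All downstream stages operate on fixed-length :class:`SignalWindow` views and
on band-pass filtered, mean-subtracted per-window signals produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CHANNELS",
    "ACC_CHANNELS",
    "GYRO_CHANNELS",
    "FilterSpec",
    "SensorRecording",
    "SignalWindow",
    "LOCOMOTION_BAND",
    "WIDE_BAND",
    "IMPACT_BAND",
    "bandpass",
    "make_windows",
    "demean",
]

ACC_CHANNELS = ("acc_v", "acc_ml", "acc_ap")
GYRO_CHANNELS = ("gyr_yaw", "gyr_pitch", "gyr_roll")
CHANNELS = ACC_CHANNELS + GYRO_CHANNELS


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass passband edges in Hz and Butterworth design order.

    The effective filter is applied forward-backward (zero phase), so the
    magnitude response is the squared design response and event timing is
    preserved for the peak-position logic downstream.
    """

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid passband: need 0 < low ({self.low_hz}) < high ({self.high_hz})"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_for(self, sample_rate: float) -> None:
        if self.high_hz >= sample_rate / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz must be below Nyquist "
                f"({sample_rate / 2} Hz at {sample_rate} Hz sampling)"
            )

    def sos(self, sample_rate: float) -> np.ndarray:
        self.validate_for(sample_rate)
        return sps.butter(
            self.order,
            (self.low_hz, self.high_hz),
            btype="bandpass",
            fs=sample_rate,
            output="sos",
        )


#: Locomotion band: human stepping frequencies, used to gate gait.
LOCOMOTION_BAND = FilterSpec(0.5, 3.0)
#: Wide band used before the peak-ratio (suspicious-window) test.
WIDE_BAND = FilterSpec(0.5, 20.0)
#: High-frequency band carrying misstep impact content, used for the
#: spectral-entropy / frequency-count features on the vertical axis.
IMPACT_BAND = FilterSpec(7.0, 10.0)


@dataclass
class SensorRecording:
    """Six-channel IMU time series at a fixed sampling rate.

    Accelerations are in g, angular velocities in deg/s. All channels must
    have equal length and contain no missing values; recordings with gaps
    must be split upstream.
    """

    acc_v: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    gyr_yaw: np.ndarray
    gyr_pitch: np.ndarray
    gyr_roll: np.ndarray
    sample_rate: float = 100.0
    start_time: float = 0.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        arrays = {}
        n = None
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"channel {name} must be one-dimensional")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError(
                    f"channel {name} has length {arr.size}, expected {n}: "
                    "all six channels must have equal length"
                )
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"channel {name} contains non-finite values")
            arrays[name] = arr
        if n is None or n < 1:
            raise ValueError("channels must contain at least one sample")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.acc_v.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def replace_channels(self, **channels: np.ndarray) -> "SensorRecording":
        """Return a copy with the given channels substituted."""
        data = {name: self.channel(name) for name in CHANNELS}
        for name, arr in channels.items():
            if name not in CHANNELS:
                raise KeyError(f"unknown channel {name!r}")
            data[name] = np.asarray(arr, dtype=float)
        return SensorRecording(
            sample_rate=self.sample_rate,
            start_time=self.start_time,
            subject_id=self.subject_id,
            **data,
        )


@dataclass(frozen=True)
class SignalWindow:
    """A fixed-length view into one recording, the unit of classification."""

    recording: SensorRecording = field(repr=False)
    start_index: int
    length_samples: int

    def __post_init__(self) -> None:
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")
        if self.length_samples < 1:
            raise ValueError("length_samples must be >= 1")
        if self.start_index + self.length_samples > len(self.recording):
            raise ValueError(
                f"window [{self.start_index}, "
                f"{self.start_index + self.length_samples}) exceeds recording "
                f"length {len(self.recording)}"
            )

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length_samples

    @property
    def start_s(self) -> float:
        return self.recording.start_time + self.start_index / self.recording.sample_rate

    @property
    def duration_s(self) -> float:
        return self.length_samples / self.recording.sample_rate

    @property
    def stop_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def sample_rate(self) -> float:
        return self.recording.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.recording.channel(name)[self.start_index : self.stop_index]


def _min_length_for(sos: np.ndarray) -> int:
    # sosfiltfilt edge padding requires strictly more samples than padlen
    return 3 * (2 * sos.shape[0] + 1) + 1


def bandpass(x: np.ndarray, spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    Applied forward-backward so no group delay is introduced: a peak in the
    input stays at the same sample index in the output, which the half-window
    and third-peak comparisons downstream rely on.

    Raises
    ------
    ValueError
        If the signal is too short for stable edge handling; the message
        names the minimum length.
    """
    x = np.asarray(x, dtype=float)
    sos = spec.sos(sample_rate)
    n_min = _min_length_for(sos)
    if x.size < n_min:
        raise ValueError(
            f"signal of length {x.size} too short for band-pass filtering; "
            f"need at least {n_min} samples"
        )
    return sps.sosfiltfilt(sos, x)


def make_windows(
    recording: SensorRecording,
    window_s: float = 5.0,
    stride_s: float | None = None,
) -> list[SignalWindow]:
    """Tile a recording into fixed-length windows in temporal order.

    The default stride equals the window length (non-overlapping tiling);
    trailing samples shorter than one window are dropped rather than padded.
    A recording shorter than one window yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if stride_s is None:
        stride_s = window_s
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    length = int(round(window_s * recording.sample_rate))
    stride = int(round(stride_s * recording.sample_rate))
    if stride < 1 or length < 1:
        raise ValueError("window and stride must span at least one sample")
    n = len(recording)
    return [
        SignalWindow(recording, start, length)
        for start in range(0, n - length + 1, stride)
    ]


def demean(x: np.ndarray) -> np.ndarray:
    """Subtract the window mean.

    Removes the constant offset introduced by sensor tilt or shifted
    placement, making all amplitude comparisons offset-invariant.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot demean an empty sequence")
    return x - x.mean()
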