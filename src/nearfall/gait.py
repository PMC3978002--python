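"""Gait gating: decide which windows contain walking.

Missteps can only happen during locomotion, so the first stage of the
pipeline extracts gait windows and everything downstream sees only those.
Each window of the vertical and anterior-posterior acceleration is filtered
to the locomotion band (0.5-3.0 Hz), convolved with one cycle of a 2 Hz
sinusoid that stands in for a single gait cycle, and the local maxima of the
response are counted. A window is gait when the count on both axes falls in
the physiologic 2-15 cycles-per-5-s range (0.5 Hz = a stride every two
seconds up to 3 steps per second).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (
    LOCOMOTION_BAND,
    FilterSpec,
    SensorRecording,
    SignalWindow,
    bandpass,
    demean,
    make_windows,
)

__all__ = [
    "GaitParams",
    "GaitWindowResult",
    "gait_template",
    "count_peaks",
    "count_cycles",
    "is_gait_window",
    "detect_gait",
    "gait_windows_to_hours",
]

#: Maximum physiologic step rate in Hz; sets the minimum peak separation.
MAX_STEP_RATE_HZ = 3.0
#: Minimum peak prominence, as a fraction of the response maximum.
PEAK_PROMINENCE_FRACTION = 0.1


@dataclass(frozen=True)
class GaitParams:
    """Parameters of the gait gate."""

    template_freq: float = 2.0
    min_cycles: int = 2
    max_cycles: int = 15
    locomotion_band: FilterSpec = LOCOMOTION_BAND
    window_s: float = 5.0
    stride_s: float | None = None
    #: "and": both vertical and AP counts must be in range; "or": either.
    axes_rule: str = "and"
    #: Minimum template-response amplitude (g) for a maximum to count as a
    #: gait cycle; suppresses ripple peaks in windows with no locomotion.
    min_cycle_amplitude_g: float = 0.05

    def __post_init__(self) -> None:
        if self.min_cycles >= self.max_cycles:
            raise ValueError("min_cycles must be < max_cycles")
        if not (self.locomotion_band.low_hz <= self.template_freq <= self.locomotion_band.high_hz):
            raise ValueError("template_freq must lie within the locomotion band")
        if self.axes_rule not in ("and", "or"):
            raise ValueError("axes_rule must be 'and' or 'or'")


@dataclass(frozen=True)
class GaitWindowResult:
    window: SignalWindow = field(repr=False)
    cycle_count_v: int
    cycle_count_ap: int
    is_gait: bool


def gait_template(sample_rate: float, freq: float = 2.0) -> np.ndarray:
    """One full sine cycle at the template frequency.

    Length is round(sample_rate / freq) samples, starting at zero, so the
    template has zero mean and unit amplitude.
    """
    if freq >= sample_rate / 2:
        raise ValueError("template frequency must be below Nyquist")
    n = int(round(sample_rate / freq))
    return np.sin(2 * np.pi * np.arange(n) / n)


def find_step_peaks(
    x: np.ndarray, sample_rate: float, min_prominence: float = 0.0
) -> np.ndarray:
    """Indices of local maxima under the shared step-peak rule.

    Peaks must be at least 1/3 s apart (3 Hz is the maximum step rate) and
    have prominence of at least 10% of the sequence maximum, or
    ``min_prominence`` if that is larger. This same rule is used for cycle
    counting on the template response, for the per-channel step counts, and
    for the suspicious-window peak-ratio test, so "peaks" mean the same
    thing in every stage.
    """
    x = np.asarray(x, dtype=float)
    top = x.max(initial=-np.inf)
    if not np.isfinite(top) or top <= 0:
        return np.empty(0, dtype=int)
    distance = max(1, int(round(sample_rate / MAX_STEP_RATE_HZ)))
    prominence = max(PEAK_PROMINENCE_FRACTION * top, min_prominence)
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    return peaks


def count_peaks(
    x: np.ndarray, sample_rate: float, min_prominence: float = 0.0
) -> int:
    """Number of local maxima under the shared step-peak rule."""
    return int(find_step_peaks(x, sample_rate, min_prominence).size)


def find_spaced_peaks(x: np.ndarray, sample_rate: float) -> np.ndarray:
    """Local maxima at least 1/3 s apart, with no prominence requirement.

    Used by the suspicious-window peak-ratio test, where small recovery
    peaks after the impact are exactly what must be found and compared;
    a prominence floor would discard them.
    """
    x = np.asarray(x, dtype=float)
    distance = max(1, int(round(sample_rate / MAX_STEP_RATE_HZ)))
    peaks, _ = sps.find_peaks(x, distance=distance)
    return peaks


def count_cycles(
    window_signal: np.ndarray, sample_rate: float, params: GaitParams | None = None
) -> int:
    """Count gait cycles in a locomotion-band filtered window.

    The signal (already band-passed to the locomotion band) is convolved
    with one template cycle (same-length output, centred on the window) and
    the local maxima of the response are counted; each maximum marks one
    gait cycle. The response is rescaled to signal-amplitude units (g) so
    the absolute ``min_cycle_amplitude_g`` floor applies; windows with no
    locomotion-band energy therefore count zero cycles instead of ripple.
    """
    params = params or GaitParams()
    x = np.asarray(window_signal, dtype=float)
    if x.size == 0:
        return 0
    template = gait_template(sample_rate, params.template_freq)
    response = sps.fftconvolve(x, template, mode="same") / (template.size / 2.0)
    return count_peaks(response, sample_rate, params.min_cycle_amplitude_g)


def is_gait_window(window: SignalWindow, params: GaitParams | None = None) -> GaitWindowResult:
    """Classify a single window as gait or not.

    Counts cycles on the vertical and anterior-posterior acceleration after
    locomotion-band filtering and demeaning; by default both counts must be
    within [min_cycles, max_cycles] (inclusive), which keeps false gait
    detections low.
    """
    params = params or GaitParams()
    fs = window.sample_rate
    counts = {}
    for name in ("acc_v", "acc_ap"):
        filtered = demean(bandpass(window.channel(name), params.locomotion_band, fs))
        counts[name] = count_cycles(filtered, fs, params)
    in_range = {
        name: params.min_cycles <= c <= params.max_cycles for name, c in counts.items()
    }
    if params.axes_rule == "and":
        gait = all(in_range.values())
    else:
        gait = any(in_range.values())
    return GaitWindowResult(
        window=window,
        cycle_count_v=counts["acc_v"],
        cycle_count_ap=counts["acc_ap"],
        is_gait=gait,
    )


def detect_gait(
    recording: SensorRecording, params: GaitParams | None = None
) -> list[GaitWindowResult]:
    """Run the gait gate over a whole recording, one result per window."""
    params = params or GaitParams()
    windows = make_windows(recording, params.window_s, params.stride_s)
    return [is_gait_window(w, params) for w in windows]


def gait_windows_to_hours(n_windows: int, window_s: float = 5.0) -> float:
    """Walking time represented by a count of non-overlapping gait windows."""
    if n_windows < 0:
        raise ValueError("window count must be non-negative")
    return n_windows * window_s / 3600.0
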