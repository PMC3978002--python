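"""The two-part misstep (near fall) classifier.

Part 1 screens gait windows for irregularity. Each demeaned 5-s window is
split into two halves; if the higher half-maximum of the vertical
acceleration exceeds 1.5x the lower one (or likewise for the half-minima of
the anterior-posterior axis) the window is an Abnormal Gait Window (AGW).
An AGW is then re-examined in an environment extended by a quarter window
on each side: on each of the six channels, wide-band (0.5-20 Hz) filtered
and demeaned, the highest peak is compared with the third peak following it
in time. A ratio above 1.8 marks the channel suspicious — the first peak is
the impact, and by the third peak a recovered gait has returned to normal
amplitude — and a majority of more than three channels promotes the window
to a Suspicious Window (SW).

Part 2 confirms an SW by features that separate missteps from ordinary gait
irregularity: step count and maximum amplitude on the vertical,
anterior-posterior and yaw channels, and spectral entropy plus
above-threshold frequency count of the 7-10 Hz band of the vertical axis.
Two or more of the four channel votes label the window a misstep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    IMPACT_BAND,
    WIDE_BAND,
    CHANNELS,
    FilterSpec,
    SensorRecording,
    SignalWindow,
    bandpass,
    demean,
)
from .gait import (
    GaitParams,
    GaitWindowResult,
    count_peaks,
    detect_gait,
    find_spaced_peaks,
)

__all__ = [
    "MisstepParams",
    "ChannelFeatures",
    "MisstepDetection",
    "detect_agw",
    "extend_environment",
    "sw_channel_test",
    "sw_majority",
    "channel_feature_vote",
    "fft_feature_vote",
    "classify_window",
    "detect_missteps",
]

FEATURE_CHANNELS = {"vertical": "acc_v", "anterior-posterior": "acc_ap", "yaw": "gyr_yaw"}


@dataclass(frozen=True)
class MisstepParams:
    """Thresholds of both classifier stages.

    Every comparison follows the printed wording: ratio and entropy
    comparisons are strict (>), "more than 8 steps" is strict, "at least
    three frequencies" and "two or more channels" are >=, "more than three
    channels" means >= 4 of 6.
    """

    half_window_ratio: float = 1.5
    peak_ratio: float = 1.8
    sw_majority_min: int = 4
    env_extension_fraction: float = 0.25
    wide_band: FilterSpec = WIDE_BAND
    min_steps: int = 8
    amp_threshold_v: float = 0.5
    amp_threshold_ap: float = 0.9
    amp_range_yaw: tuple[float, float] = (50.0, 100.0)
    fft_band: FilterSpec = IMPACT_BAND
    entropy_threshold: float = 1.7
    freq_energy_threshold: float = 0.015
    min_freqs_above: int = 3
    final_vote_min: int = 2
    #: "temporal": p3 is the third peak after the highest, in time order;
    #: "rank": p3 is the third-highest peak located after the highest.
    third_peak_rule: str = "temporal"
    #: Part 2 runs on windows that passed part 1 up to this stage.
    part2_applies_to: str = "sw"

    def __post_init__(self) -> None:
        for name in (
            "half_window_ratio",
            "peak_ratio",
            "amp_threshold_v",
            "amp_threshold_ap",
            "entropy_threshold",
            "freq_energy_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1 <= self.sw_majority_min <= 6):
            raise ValueError("sw_majority_min must be in 1..6")
        if not (1 <= self.final_vote_min <= 4):
            raise ValueError("final_vote_min must be in 1..4")
        if self.third_peak_rule not in ("temporal", "rank"):
            raise ValueError("third_peak_rule must be 'temporal' or 'rank'")
        if self.part2_applies_to not in ("sw", "agw"):
            raise ValueError("part2_applies_to must be 'sw' or 'agw'")
        if self.amp_range_yaw[0] >= self.amp_range_yaw[1]:
            raise ValueError("amp_range_yaw must be an increasing interval")


@dataclass(frozen=True)
class ChannelFeatures:
    """Part-2 features of one channel within one window."""

    channel: str
    n_steps: int
    max_amplitude: float
    spectral_entropy: float | None = None
    n_freqs_above: int | None = None


@dataclass(frozen=True)
class MisstepDetection:
    """Full record of the cascade for one window."""

    window: SignalWindow = field(repr=False)
    agw_vertical: bool
    agw_ap: bool
    sw_votes: tuple[bool, bool, bool, bool, bool, bool]
    is_sw: bool
    feature_votes: tuple[bool, bool, bool, bool]
    features: tuple[ChannelFeatures, ...]
    is_misstep: bool

    @property
    def is_agw(self) -> bool:
        return self.agw_vertical or self.agw_ap

    @property
    def detection_time(self) -> float:
        return self.window.start_s


def detect_agw(window: SignalWindow, params: MisstepParams | None = None) -> tuple[bool, bool]:
    """Half-window asymmetry screen (part 1, first gate).

    The demeaned vertical signal is split into two equal halves and the
    maximum of each taken; the window is abnormal when the higher maximum
    strictly exceeds ``half_window_ratio`` times the lower. The
    anterior-posterior axis uses the half-window minima instead, compared by
    absolute magnitude — the downward deflection of a stumble mirrors the
    upward vertical impact. Odd-length windows split with one extra sample
    in the second half.
    """
    params = params or MisstepParams()
    v = demean(window.channel("acc_v"))
    ap = demean(window.channel("acc_ap"))
    mid = v.size // 2

    def ratio_exceeds(high: float, low: float) -> bool:
        if low <= 0:
            # the lower half never rises above the window mean: maximally
            # asymmetric as long as the other half does
            return high > 0
        return high > params.half_window_ratio * low

    m1, m2 = float(v[:mid].max()), float(v[mid:].max())
    agw_v = ratio_exceeds(max(m1, m2), min(m1, m2))
    n1, n2 = abs(float(ap[:mid].min())), abs(float(ap[mid:].min()))
    agw_ap = ratio_exceeds(max(n1, n2), min(n1, n2))
    return agw_v, agw_ap


def extend_environment(window: SignalWindow, fraction: float = 0.25) -> SignalWindow:
    """Widen a window by ``fraction`` of its length on each side.

    The extension is truncated at the recording boundaries; it lets the
    peak-ratio test see whether an irregularity is localized to the window
    or part of a sustained change (obstacle negotiation, gait start/stop).
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    pad = int(round(fraction * window.length_samples))
    start = max(0, window.start_index - pad)
    stop = min(len(window.recording), window.stop_index + pad)
    return SignalWindow(window.recording, start, stop - start)


def sw_channel_test(
    extended_signal: np.ndarray,
    params: MisstepParams | None = None,
    sample_rate: float = 100.0,
) -> bool:
    """Highest-vs-third-following-peak ratio on one wide-band channel.

    Expects the extended environment already 0.5-20 Hz filtered and
    demeaned. Local maxima are spaced at least 1/3 s apart (no prominence
    floor: the small recovery peaks are the point of the comparison); p1 is
    the highest peak and p3 the third peak after it in temporal order (the
    recovery stage), or the third-highest after it under the rank rule. The
    channel votes suspicious iff p1/p3 strictly exceeds ``peak_ratio`` with
    p3 > 0; fewer than three peaks after p1 means the recovery pattern
    cannot be confirmed and the vote is negative.
    """
    params = params or MisstepParams()
    x = np.asarray(extended_signal, dtype=float)
    peaks = find_spaced_peaks(x, sample_rate)
    if peaks.size == 0:
        return False
    heights = x[peaks]
    i1 = int(np.argmax(heights))
    p1 = float(heights[i1])
    after = heights[i1 + 1 :]
    if after.size < 3:
        return False
    if params.third_peak_rule == "temporal":
        p3 = float(after[2])
    else:
        p3 = float(np.sort(after)[::-1][2])
    if p3 <= 0:
        return False
    return p1 / p3 > params.peak_ratio


def sw_majority(
    window: SignalWindow, params: MisstepParams | None = None
) -> tuple[bool, tuple[bool, ...]]:
    """Run the peak-ratio test on all six channels of the extended window.

    Gyroscope channels are demeaned like the accelerometer channels, which
    removes slow turning bias before peak comparison. The window is a
    Suspicious Window when at least ``sw_majority_min`` (default 4, i.e.
    "more than three") channels vote.
    """
    params = params or MisstepParams()
    env = extend_environment(window, params.env_extension_fraction)
    fs = window.sample_rate
    votes = []
    for name in CHANNELS:
        x = demean(bandpass(env.channel(name), params.wide_band, fs))
        votes.append(sw_channel_test(x, params, fs))
    votes = tuple(votes)
    return sum(votes) >= params.sw_majority_min, votes


def channel_feature_vote(
    window_signal: np.ndarray,
    channel: str,
    params: MisstepParams | None = None,
    sample_rate: float = 100.0,
) -> tuple[bool, ChannelFeatures]:
    """Step-count and amplitude vote for one of the three feature channels.

    ``channel`` is one of "vertical", "anterior-posterior", "yaw". Steps are
    local maxima of the demeaned signal under the shared step-peak rule. The
    vote requires strictly more than ``min_steps`` steps AND the amplitude
    criterion: vertical max > 0.5 g, anterior-posterior max > 0.9 g, yaw max
    within [50, 100] deg/s.
    """
    params = params or MisstepParams()
    if channel not in FEATURE_CHANNELS:
        raise ValueError(
            f"unknown feature channel {channel!r}; expected one of "
            f"{sorted(FEATURE_CHANNELS)}"
        )
    x = demean(np.asarray(window_signal, dtype=float))
    n_steps = count_peaks(x, sample_rate)
    max_amp = float(x.max())
    if channel == "vertical":
        amp_ok = max_amp > params.amp_threshold_v
    elif channel == "anterior-posterior":
        amp_ok = max_amp > params.amp_threshold_ap
    else:
        lo, hi = params.amp_range_yaw
        amp_ok = lo <= max_amp <= hi
    vote = n_steps > params.min_steps and amp_ok
    return vote, ChannelFeatures(channel=channel, n_steps=n_steps, max_amplitude=max_amp)


def fft_feature_vote(
    vertical_window: np.ndarray,
    params: MisstepParams | None = None,
    sample_rate: float = 100.0,
) -> tuple[bool, float, int]:
    """Spectral-entropy and frequency-count vote on the vertical 7-10 Hz band.

    The raw vertical window is band-passed to 7-10 Hz and its one-sided FFT
    amplitude spectrum computed (2|X_k|/N, amplitude units of g; FFT length
    equals the window length, no taper). Within the in-band bins,
    ``n_freqs_above`` counts bins whose amplitude exceeds the 0.015 g
    energy threshold, and the entropy is the natural-log Shannon entropy of
    the in-band amplitudes normalized to sum one. The vote requires entropy
    strictly above 1.7 and at least three bins above threshold. A single
    dominant tone concentrates the spectrum in one bin and scores entropy
    near zero; the broadband burst of a misstep impact spreads it.
    """
    params = params or MisstepParams()
    x = np.asarray(vertical_window, dtype=float)
    fs = sample_rate
    filtered = bandpass(x, params.fft_band, fs)
    n = filtered.size
    spectrum = np.abs(np.fft.rfft(filtered)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= params.fft_band.low_hz) & (freqs <= params.fft_band.high_hz)
    band = spectrum[in_band]
    n_above = int(np.count_nonzero(band > params.freq_energy_threshold))
    total = band.sum()
    if total <= 0:
        entropy = 0.0
    else:
        p = band / total
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
    vote = entropy > params.entropy_threshold and n_above >= params.min_freqs_above
    return vote, entropy, n_above


def classify_window(
    window: SignalWindow, params: MisstepParams | None = None
) -> MisstepDetection:
    """Run the full cascade on one gait window.

    AGW gate, then SW majority on the extended environment, then the four
    feature votes (vertical, anterior-posterior, yaw, vertical-FFT); the
    window is a misstep when at least ``final_vote_min`` of the four vote.
    Each stage short-circuits: a window failing a gate is negative and the
    later stages are not evaluated.
    """
    params = params or MisstepParams()
    fs = window.sample_rate
    agw_v, agw_ap = detect_agw(window, params)
    no_votes = (False,) * 6

    if not (agw_v or agw_ap):
        return MisstepDetection(
            window=window, agw_vertical=agw_v, agw_ap=agw_ap, sw_votes=no_votes,
            is_sw=False, feature_votes=(False,) * 4, features=(), is_misstep=False,
        )

    is_sw, sw_votes = sw_majority(window, params)
    if params.part2_applies_to == "sw" and not is_sw:
        return MisstepDetection(
            window=window, agw_vertical=agw_v, agw_ap=agw_ap, sw_votes=sw_votes,
            is_sw=is_sw, feature_votes=(False,) * 4, features=(), is_misstep=False,
        )

    features = []
    votes = []
    for label in ("vertical", "anterior-posterior", "yaw"):
        vote, feats = channel_feature_vote(
            window.channel(FEATURE_CHANNELS[label]), label, params, fs
        )
        votes.append(vote)
        features.append(feats)
    fft_vote, entropy, n_above = fft_feature_vote(window.channel("acc_v"), params, fs)
    votes.append(fft_vote)
    features.append(
        ChannelFeatures(
            channel="fft-vertical",
            n_steps=0,
            max_amplitude=float(np.max(np.abs(demean(window.channel("acc_v"))))),
            spectral_entropy=entropy,
            n_freqs_above=n_above,
        )
    )
    is_misstep = sum(votes) >= params.final_vote_min
    return MisstepDetection(
        window=window, agw_vertical=agw_v, agw_ap=agw_ap, sw_votes=sw_votes,
        is_sw=is_sw, feature_votes=tuple(votes), features=tuple(features),
        is_misstep=is_misstep,
    )


def detect_missteps(
    recording: SensorRecording,
    gait_params: GaitParams | None = None,
    params: MisstepParams | None = None,
    gait_results: list[GaitWindowResult] | None = None,
) -> list[MisstepDetection]:
    """Full pipeline: gait gating then window classification.

    Returns only the positive detections, in temporal order. Precomputed
    gait results may be supplied to avoid re-running the gait gate.
    """
    gait_params = gait_params or GaitParams()
    params = params or MisstepParams()
    if gait_results is None:
        gait_results = detect_gait(recording, gait_params)
    detections = []
    for res in gait_results:
        if not res.is_gait:
            continue
        det = classify_window(res.window, params)
        if det.is_misstep:
            detections.append(det)
    return detections
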