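"""Synthetic 6-channel IMU signals with known ground truth.

No public recordings of lower-back IMU missteps exist, so every stage of
the pipeline is exercised on generated signals calibrated to the published
statistics of laboratory and home gait: vertical peak-to-peak range around
1.32 +/- 0.3 g in the laboratory (1.18 +/- 0.65 g at home), misstep peak
amplitudes drawn from a normal distribution with mean 2.49 g and SD 1.3 g
truncated to [0.4, 6.0] g, event durations between half a second and a few
seconds, and the sensor's 100 Hz sampling with +/- 2 g / 0.001 g
accelerometer and +/- 100 deg/s / 0.0069 deg/s gyroscope range/resolution.

The walking model is deliberately simple — a fundamental at the step
frequency plus one harmonic, phase-shifted copies across axes, Gaussian
noise and a constant tilt offset per accelerometer channel. A misstep is an
impact spike followed by a decaying oscillation (the recovery), a 7-10 Hz
burst, and a yaw deflection into the 50-100 deg/s range; smaller scaled
copies of the transient reach the medio-lateral, pitch and roll channels,
since a loss of balance perturbs the whole trunk. Each component can be
switched off to create hard negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core import ACC_CHANNELS, GYRO_CHANNELS, SensorRecording
from .evaluate import AnnotationEvent, SubjectTrialCounts

__all__ = [
    "WalkConfig",
    "MisstepSpec",
    "SensorSpec",
    "generate_walk",
    "generate_standing",
    "draw_misstep_specs",
    "inject_missteps",
    "apply_sensor",
    "generate_benchmark",
    "generate_cohort",
]

#: Published laboratory vertical peak-to-peak gait range (mean, SD) in g.
LAB_VERTICAL_RANGE = (1.32, 0.3)
#: Published home vertical peak-to-peak gait range (mean, SD) in g.
HOME_VERTICAL_RANGE = (1.18, 0.65)
#: Published misstep peak amplitude distribution in g: mean, SD, bounds.
MISSTEP_AMPLITUDE = (2.49, 1.3, 0.4, 6.0)


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the periodic-gait model.

    ``vertical_range`` is the peak-to-peak vertical range in g; ``None``
    draws one per recording from the laboratory distribution. ``tilt_offset``
    is a constant per-accelerometer-channel offset in g emulating sensor
    tilt; ``None`` draws each channel's offset uniformly from [-0.3, 0.3].
    """

    duration: float = 60.0
    step_freq: float = 2.0
    vertical_range: float | None = None
    range_mean: float = LAB_VERTICAL_RANGE[0]
    range_sd: float = LAB_VERTICAL_RANGE[1]
    ap_fraction: float = 0.6
    ml_fraction: float = 0.4
    gyro_amplitude: float = 15.0
    noise_sd: float = 0.05
    gyro_noise_sd: float = 2.0
    tilt_offset: float | None = None
    sample_rate: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.5 <= self.step_freq <= 3.0):
            raise ValueError("step_freq must lie in the physiologic 0.5-3.0 Hz band")
        if self.noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def home(cls, **kwargs) -> "WalkConfig":
        """Preset with the home-recording vertical-range distribution."""
        return cls(
            range_mean=HOME_VERTICAL_RANGE[0], range_sd=HOME_VERTICAL_RANGE[1], **kwargs
        )


@dataclass(frozen=True)
class MisstepSpec:
    """One misstep transient to inject.

    ``peak_amplitude`` is the height in g of the vertical impact spike above
    the walking baseline; ``recovery_decay`` the time constant of the damped
    recovery oscillation; ``hf_burst_amplitude`` the amplitude of the added
    7-10 Hz content that emulates the impact's high-frequency signature.
    ``gait_suppression`` is the fraction by which the ongoing periodic gait
    is attenuated at the height of the event — a stumble interrupts regular
    stepping, which is what makes the recovery peaks smaller than the
    impact peak.
    """

    start_time: float
    duration: float
    peak_amplitude: float
    recovery_decay: float = 0.6
    hf_burst_amplitude: float = 0.1
    gait_suppression: float = 0.6

    def __post_init__(self) -> None:
        if self.duration < 0.5:
            raise ValueError("misstep duration must be at least 0.5 s")
        lo, hi = MISSTEP_AMPLITUDE[2], MISSTEP_AMPLITUDE[3]
        if not (lo <= self.peak_amplitude <= hi):
            raise ValueError(f"peak_amplitude must lie in [{lo}, {hi}] g")

    @property
    def stop_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class SensorSpec:
    """Range and resolution of the accelerometer and gyroscope."""

    acc_range: float = 2.0
    acc_resolution: float = 0.001
    gyro_range: float = 100.0
    gyro_resolution: float = 0.0069
    clipping_enabled: bool = False

    def __post_init__(self) -> None:
        if min(self.acc_range, self.acc_resolution, self.gyro_range, self.gyro_resolution) <= 0:
            raise ValueError("sensor ranges and resolutions must be positive")


def generate_walk(config: WalkConfig | None = None) -> SensorRecording:
    """Periodic walking signal on all six channels, deterministic per seed."""
    config = config or WalkConfig()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    f = config.step_freq

    if config.vertical_range is None:
        v_range = float(
            np.clip(rng.normal(config.range_mean, config.range_sd), 0.3, None)
        )
    else:
        v_range = config.vertical_range

    def shape(phase: float, harmonic_phase: float) -> np.ndarray:
        s = np.sin(2 * np.pi * f * t + phase) + 0.25 * np.sin(
            4 * np.pi * f * t + harmonic_phase
        )
        ptp = s.max() - s.min()
        return s / ptp if ptp > 0 else s

    phases = rng.uniform(0, 2 * np.pi, size=6)
    if config.tilt_offset is None:
        tilts = rng.uniform(-0.3, 0.3, size=3)
    else:
        tilts = np.full(3, config.tilt_offset)

    acc = {}
    fractions = {"acc_v": 1.0, "acc_ap": config.ap_fraction, "acc_ml": config.ml_fraction}
    for i, name in enumerate(ACC_CHANNELS):
        base = v_range * fractions[name] * shape(phases[i], phases[i] + np.pi / 3)
        acc[name] = tilts[i] + base + rng.normal(0, config.noise_sd, n)

    gyr = {}
    for i, name in enumerate(GYRO_CHANNELS):
        base = config.gyro_amplitude * shape(phases[3 + i], phases[3 + i] + np.pi / 3)
        gyr[name] = base + rng.normal(0, config.gyro_noise_sd, n)

    return SensorRecording(sample_rate=fs, **acc, **gyr)


def generate_standing(
    duration: float,
    sample_rate: float = 100.0,
    noise_sd: float = 0.01,
    gyro_noise_sd: float = 0.5,
    seed: int | None = None,
) -> SensorRecording:
    """Quiet standing: constant tilt plus low-amplitude sensor noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    tilts = rng.uniform(-0.3, 0.3, size=3)
    channels = {
        name: tilts[i] + rng.normal(0, noise_sd, n)
        for i, name in enumerate(ACC_CHANNELS)
    }
    channels.update(
        {name: rng.normal(0, gyro_noise_sd, n) for name in GYRO_CHANNELS}
    )
    return SensorRecording(sample_rate=sample_rate, **channels)


def _amplitude_distribution() -> stats.rv_continuous:
    mean, sd, lo, hi = MISSTEP_AMPLITUDE
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def draw_misstep_specs(
    start_times: np.ndarray | list[float],
    rng: np.random.Generator,
    duration_range: tuple[float, float] = (0.5, 4.0),
    **overrides,
) -> list[MisstepSpec]:
    """Draw misstep parameters from the published distributions.

    Peak amplitudes come from Normal(2.49, 1.3) truncated to [0.4, 6.0] g;
    durations are uniform over ``duration_range`` (half a second to several
    seconds).
    """
    start_times = np.asarray(start_times, dtype=float)
    dist = _amplitude_distribution()
    amps = dist.rvs(size=start_times.size, random_state=rng)
    durs = rng.uniform(*duration_range, size=start_times.size)
    return [
        MisstepSpec(
            start_time=float(s), duration=float(d), peak_amplitude=float(a), **overrides
        )
        for s, d, a in zip(start_times, durs, amps)
    ]


def _transient(
    t_local: np.ndarray,
    spec: MisstepSpec,
    rng: np.random.Generator,
    t_impact: float,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Misstep waveforms over the event span plus the gait-attenuation profile.

    Local time runs from 0 at the event start; ``t_impact`` is the local
    time of the impact spike. Returns the additive wave per channel and the
    attenuation fraction applied to the pre-existing signal (0 at the event
    edges, rising to ``gait_suppression`` mid-event).
    """
    dur = spec.duration
    impact_width = min(0.12, 0.3 * dur)
    in_spike = np.abs(t_local - t_impact) <= impact_width / 2
    spike = np.zeros_like(t_local)
    spike[in_spike] = np.cos(np.pi * (t_local[in_spike] - t_impact) / impact_width) ** 2

    # damped recovery oscillation after the impact
    after = t_local > t_impact
    osc = np.zeros_like(t_local)
    osc[after] = np.exp(-(t_local[after] - t_impact) / spec.recovery_decay) * np.sin(
        2 * np.pi * 4.0 * (t_local[after] - t_impact)
    )

    # smooth envelope for the sustained components, zero at both event edges
    envelope = np.sin(np.pi * np.clip(t_local / dur, 0, 1)) ** 2

    # broadband 7-10 Hz content spanning the event
    burst = np.zeros_like(t_local)
    for freq in (7.4, 8.3, 9.4):
        burst += np.sin(2 * np.pi * freq * t_local + rng.uniform(0, 2 * np.pi))
    burst *= spec.hf_burst_amplitude * envelope

    # quick catch steps at reduced amplitude after the impact: positive
    # bumps at an elevated cadence, the recovery peaks the third-peak
    # comparison is meant to find
    catch = np.zeros_like(t_local)
    catch[after] = (
        np.clip(np.sin(2 * np.pi * 2.5 * (t_local[after] - t_impact)), 0, None) ** 2
    )
    catch *= envelope

    amp = spec.peak_amplitude
    yaw_peak = rng.uniform(55.0, 80.0)
    waves = {
        "acc_v": amp * spike + 0.35 * amp * osc + 0.30 * amp * catch + burst,
        "acc_ap": -amp * spike + 0.4 * amp * osc + 0.25 * amp * catch + 0.6 * burst,
        "acc_ml": -0.35 * amp * spike + 0.25 * amp * osc + 0.15 * amp * catch + 0.3 * burst,
        "gyr_yaw": yaw_peak * spike + 0.35 * yaw_peak * osc + 0.25 * yaw_peak * catch,
        "gyr_pitch": 0.55 * yaw_peak * spike + 0.45 * yaw_peak * osc + 0.2 * yaw_peak * catch,
        "gyr_roll": 0.35 * yaw_peak * spike + 0.3 * yaw_peak * osc + 0.15 * yaw_peak * catch,
    }
    return waves, spec.gait_suppression * envelope


def inject_missteps(
    recording: SensorRecording,
    specs: list[MisstepSpec],
    seed: int | None = None,
) -> tuple[SensorRecording, list[AnnotationEvent]]:
    """Add misstep transients to a recording; returns the annotations.

    Events must be non-overlapping and lie inside the recording; all signal
    modification is confined to each event's [start, start + duration) span.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(specs, key=lambda s: s.start_time)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_time < prev.stop_time:
            raise ValueError(
                f"events overlap: [{prev.start_time}, {prev.stop_time}) and "
                f"[{nxt.start_time}, {nxt.stop_time})"
            )
    duration = recording.duration_s
    channels = {name: recording.channel(name).copy() for name in
                ACC_CHANNELS + GYRO_CHANNELS}
    events = []
    fs = recording.sample_rate
    for spec in ordered:
        if spec.start_time < 0 or spec.stop_time > duration:
            raise ValueError(
                f"event [{spec.start_time}, {spec.stop_time}) outside recording "
                f"of {duration} s"
            )
        i0 = int(round(spec.start_time * fs))
        i1 = int(round(spec.stop_time * fs))
        t_local = (np.arange(i0, i1) - i0) / fs
        # a trip happens at foot strike: align the impact spike with the
        # strongest vertical-acceleration peak early in the event span
        search_end = i0 + max(1, int(round(0.35 * spec.duration * fs)))
        seg_v = channels["acc_v"][i0:search_end]
        t_impact = float(np.argmax(seg_v)) / fs
        waves, attenuation = _transient(t_local, spec, rng, t_impact)
        for name, wave in waves.items():
            seg = channels[name][i0:i1]
            local_mean = seg.mean()
            # interrupted stepping: attenuate the ongoing gait around its
            # local level, then superimpose the transient
            channels[name][i0:i1] = (
                local_mean + (seg - local_mean) * (1.0 - attenuation) + wave
            )
        events.append(AnnotationEvent(start_time=spec.start_time, duration=spec.duration))
    out = recording.replace_channels(**channels)
    return out, events


def apply_sensor(recording: SensorRecording, spec: SensorSpec | None = None) -> SensorRecording:
    """Quantize (and optionally clip) each channel to the sensor grid."""
    spec = spec or SensorSpec()
    channels = {}
    for name in ACC_CHANNELS + GYRO_CHANNELS:
        res = spec.acc_resolution if name in ACC_CHANNELS else spec.gyro_resolution
        rng_limit = spec.acc_range if name in ACC_CHANNELS else spec.gyro_range
        x = recording.channel(name)
        if spec.clipping_enabled:
            x = np.clip(x, -rng_limit, rng_limit)
        channels[name] = np.round(x / res) * res
    return recording.replace_channels(**channels)


def _concatenate(recordings: list[SensorRecording]) -> SensorRecording:
    fs = recordings[0].sample_rate
    channels = {
        name: np.concatenate([r.channel(name) for r in recordings])
        for name in ACC_CHANNELS + GYRO_CHANNELS
    }
    return SensorRecording(sample_rate=fs, **channels)


def generate_benchmark(
    n_recordings: int = 30,
    events_per_recording: int = 1,
    config: WalkConfig | None = None,
    seed: int = 0,
    non_gait_fraction: float = 0.2,
    sensor: SensorSpec | None = SensorSpec(),
) -> list[tuple[SensorRecording, list[AnnotationEvent]]]:
    """Reproducible labeled corpus for hit-ratio / specificity evaluation.

    Each recording is a walking bout with standing filler at both ends
    (``non_gait_fraction`` of total time, exercising the gait gate) and
    ``events_per_recording`` missteps drawn from the published amplitude and
    duration distributions, injected away from the bout edges. One global
    seed drives a per-recording seed sequence, so recordings can be
    regenerated independently.
    """
    if n_recordings < 0 or events_per_recording < 0:
        raise ValueError("counts must be non-negative")
    base = config or WalkConfig()
    corpus = []
    seeds = np.random.SeedSequence(seed).spawn(n_recordings)
    for i in range(n_recordings):
        child = seeds[i].generate_state(4)
        walk_cfg = replace(base, seed=int(child[0] % (2**31)))
        walk = generate_walk(walk_cfg)
        walk_d = walk.duration_s
        filler_total = walk_d * non_gait_fraction / max(1e-9, 1 - non_gait_fraction)
        fs = walk.sample_rate
        window_s = 5.0
        # round filler halves to whole windows so stand/walk boundaries
        # align with the 5-s tiling
        pre_d = max(window_s, round(filler_total / 2 / window_s) * window_s)
        post_d = max(window_s, filler_total - pre_d)
        pre = generate_standing(pre_d, fs, seed=int(child[1] % (2**31)))
        post = generate_standing(post_d, fs, seed=int(child[2] % (2**31)))
        rec = _concatenate([pre, walk, post])

        rng = np.random.default_rng(int(child[3] % (2**31)))
        events: list[AnnotationEvent] = []
        if events_per_recording > 0:
            margin = 8.0
            lo = pre.duration_s + margin
            hi = pre.duration_s + walk_d - margin
            starts = np.sort(rng.uniform(lo, hi, size=events_per_recording))
            specs = draw_misstep_specs(starts, rng)
            # redraw until events are spaced apart (rare with few events)
            for _ in range(100):
                ok = all(
                    b.start_time >= a.stop_time + 1.0
                    for a, b in zip(specs, specs[1:])
                )
                if ok:
                    break
                starts = np.sort(rng.uniform(lo, hi, size=events_per_recording))
                specs = draw_misstep_specs(starts, rng)
            rec, events = inject_missteps(rec, specs, seed=int(child[3] % (2**31)))
        if sensor is not None:
            rec = apply_sensor(rec, sensor)
        corpus.append((rec, events))
    return corpus


def generate_cohort(
    n_per_group: int = 10,
    windows_per_subject: int = 500,
    base_rate: float = 0.05,
    rate_ratio: float = 2.0,
    seed: int = 0,
) -> list[SubjectTrialCounts]:
    """Cohort of faller / non-faller subjects with known event-rate ratio.

    Every subject contributes ``windows_per_subject`` gait windows (trials);
    suspected-misstep windows are binomial draws at ``base_rate`` for
    non-fallers and ``base_rate * rate_ratio`` for fallers.
    """
    if base_rate * rate_ratio >= 1:
        raise ValueError("faller rate must stay below 1")
    rng = np.random.default_rng(seed)
    subjects = []
    for group, faller in (("faller", True), ("control", False)):
        rate = base_rate * (rate_ratio if faller else 1.0)
        for j in range(n_per_group):
            n_sms = int(rng.binomial(windows_per_subject, rate))
            subjects.append(
                SubjectTrialCounts(
                    subject_id=f"{group}-{j:02d}",
                    is_faller=faller,
                    n_sms_windows=n_sms,
                    n_gait_windows=windows_per_subject,
                )
            )
    return subjects
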