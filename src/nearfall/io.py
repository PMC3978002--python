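"""CSV dialects, run configuration, and (de)serialization.

Recordings travel as a seven-column CSV (time plus the six channels, g and
deg/s); annotations as ``start_s,duration_s,label``. The run configuration
is a flat document (JSON or YAML by extension) whose defaults are the
published thresholds of the detection algorithm; unknown keys are rejected
so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FilterSpec, SensorRecording
from .evaluate import AnnotationEvent
from .gait import GaitParams
from .misstep import MisstepDetection, MisstepParams
from .simulate import SensorSpec

__all__ = [
    "RECORDING_COLUMNS",
    "ANNOTATION_COLUMNS",
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "write_detections",
    "read_detections",
]

logger = logging.getLogger("nearfall")

RECORDING_COLUMNS = [
    "time_s",
    "acc_v_g",
    "acc_ml_g",
    "acc_ap_g",
    "gyr_yaw_dps",
    "gyr_pitch_dps",
    "gyr_roll_dps",
]
ANNOTATION_COLUMNS = ["start_s", "duration_s", "label"]

_COLUMN_TO_CHANNEL = {
    "acc_v_g": "acc_v",
    "acc_ml_g": "acc_ml",
    "acc_ap_g": "acc_ap",
    "gyr_yaw_dps": "gyr_yaw",
    "gyr_pitch_dps": "gyr_pitch",
    "gyr_roll_dps": "gyr_roll",
}

#: Tolerance on time-step uniformity, in seconds.
TIME_STEP_TOL = 1e-6


def read_recording(
    path: str | Path, expected_sample_rate: float | None = None
) -> SensorRecording:
    """Read a recording CSV, inferring the sample rate from the time column.

    Rejects missing or extra columns, NaN values and non-uniform sampling
    (tolerance 1e-6 s), naming the offending column or row. Logs a warning
    when the inferred rate differs from the expected one (default 100 Hz
    for the reference sensor).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    extra = [c for c in df.columns if c not in RECORDING_COLUMNS]
    if extra:
        raise ValueError(f"{path.name}: unexpected columns {extra}")
    if len(df) < 2:
        raise ValueError(f"{path.name}: need at least two samples")
    for col in RECORDING_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path.name}: NaN in column {col} at row {bad[0]}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"{path.name}: time not strictly increasing at row {row}")
    if np.any(np.abs(dt - dt[0]) > TIME_STEP_TOL):
        row = int(np.argmax(np.abs(dt - dt[0]) > TIME_STEP_TOL)) + 1
        raise ValueError(
            f"{path.name}: non-uniform time step at row {row} "
            f"(expected {dt[0]:.6f} s within {TIME_STEP_TOL} s)"
        )
    sample_rate = 1.0 / dt[0]
    check_rate = 100.0 if expected_sample_rate is None else expected_sample_rate
    if abs(sample_rate - check_rate) > 0.5:
        logger.warning(
            "%s: inferred sample rate %.2f Hz differs from expected %.0f Hz",
            path.name,
            sample_rate,
            check_rate,
        )
    channels = {
        _COLUMN_TO_CHANNEL[col]: df[col].to_numpy(dtype=float)
        for col in RECORDING_COLUMNS[1:]
    }
    return SensorRecording(sample_rate=sample_rate, start_time=float(t[0]), **channels)


def write_recording(path: str | Path, recording: SensorRecording) -> None:
    """Write a recording CSV with six-decimal values."""
    df = pd.DataFrame({"time_s": recording.time_s})
    for col, name in _COLUMN_TO_CHANNEL.items():
        df[col] = recording.channel(name)
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> list[AnnotationEvent]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    return [
        AnnotationEvent(
            start_time=float(r.start_s), duration=float(r.duration_s), label=str(r.label)
        )
        for r in df.itertuples()
    ]


def write_annotations(path: str | Path, events: list[AnnotationEvent]) -> None:
    df = pd.DataFrame(
        {
            "start_s": [e.start_time for e in events],
            "duration_s": [e.duration for e in events],
            "label": [e.label for e in events],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_detections(path: str | Path, detections: list[MisstepDetection]) -> None:
    """One CSV row per detection: window span, votes, key features."""
    rows = []
    for d in detections:
        row = {
            "window_start_s": d.window.start_s,
            "window_s": d.window.duration_s,
            "agw_vertical": d.agw_vertical,
            "agw_ap": d.agw_ap,
            "n_sw_votes": sum(d.sw_votes),
            "n_feature_votes": sum(d.feature_votes),
        }
        for f in d.features:
            key = f.channel.replace("-", "_")
            row[f"steps_{key}"] = f.n_steps
            row[f"max_amp_{key}"] = round(f.max_amplitude, 4)
            if f.spectral_entropy is not None:
                row["entropy"] = round(f.spectral_entropy, 4)
                row["n_freqs_above"] = f.n_freqs_above
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[tuple[float, float]]:
    """Detection window spans (start_s, stop_s) from a detections CSV."""
    df = pd.read_csv(path)
    if len(df) == 0:
        return []
    return [
        (float(r.window_start_s), float(r.window_start_s) + float(r.window_s))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; defaults are the published thresholds."""

    window_s: float = 5.0
    stride_s: float = 5.0
    seed: int = 0
    filter_order: int = 4
    # gait gate
    template_freq: float = 2.0            # one 2 Hz sine cycle = one gait cycle
    min_cycles: int = 2                   # 2-15 cycles per 5-s window is gait
    max_cycles: int = 15
    locomotion_low_hz: float = 0.5        # locomotion band 0.5-3.0 Hz
    locomotion_high_hz: float = 3.0
    axes_rule: str = "and"
    min_cycle_amplitude_g: float = 0.05
    # misstep part 1
    half_window_ratio: float = 1.5        # higher half-max > 1.5x lower
    peak_ratio: float = 1.8               # highest peak > 1.8x third following
    sw_majority_min: int = 4              # more than 3 of 6 channels
    env_extension_fraction: float = 0.25  # quarter-window extension per side
    wide_low_hz: float = 0.5              # 0.5-20 Hz noise-reduction band
    wide_high_hz: float = 20.0
    # misstep part 2
    min_steps: int = 8                    # more than 8 steps per window
    amp_threshold_v: float = 0.5          # vertical max > 0.5 g
    amp_threshold_ap: float = 0.9         # anterior-posterior max > 0.9 g
    amp_yaw_low: float = 50.0             # yaw max within 50-100 deg/s
    amp_yaw_high: float = 100.0
    fft_low_hz: float = 7.0               # 7-10 Hz band of the vertical axis
    fft_high_hz: float = 10.0
    entropy_threshold: float = 1.7        # spectral entropy > 1.7
    freq_energy_threshold: float = 0.015  # bins with amplitude > 0.015 g
    min_freqs_above: int = 3              # at least 3 such bins
    final_vote_min: int = 2               # 2 or more of the 4 channel votes
    third_peak_rule: str = "temporal"
    part2_applies_to: str = "sw"
    # sensor
    acc_range: float = 2.0
    acc_resolution: float = 0.001
    gyro_range: float = 100.0
    gyro_resolution: float = 0.0069
    clipping_enabled: bool = False

    def gait_params(self) -> GaitParams:
        return GaitParams(
            template_freq=self.template_freq,
            min_cycles=self.min_cycles,
            max_cycles=self.max_cycles,
            locomotion_band=FilterSpec(
                self.locomotion_low_hz, self.locomotion_high_hz, self.filter_order
            ),
            window_s=self.window_s,
            stride_s=self.stride_s,
            axes_rule=self.axes_rule,
            min_cycle_amplitude_g=self.min_cycle_amplitude_g,
        )

    def misstep_params(self) -> MisstepParams:
        return MisstepParams(
            half_window_ratio=self.half_window_ratio,
            peak_ratio=self.peak_ratio,
            sw_majority_min=self.sw_majority_min,
            env_extension_fraction=self.env_extension_fraction,
            wide_band=FilterSpec(self.wide_low_hz, self.wide_high_hz, self.filter_order),
            min_steps=self.min_steps,
            amp_threshold_v=self.amp_threshold_v,
            amp_threshold_ap=self.amp_threshold_ap,
            amp_range_yaw=(self.amp_yaw_low, self.amp_yaw_high),
            fft_band=FilterSpec(self.fft_low_hz, self.fft_high_hz, self.filter_order),
            entropy_threshold=self.entropy_threshold,
            freq_energy_threshold=self.freq_energy_threshold,
            min_freqs_above=self.min_freqs_above,
            final_vote_min=self.final_vote_min,
            third_peak_rule=self.third_peak_rule,
            part2_applies_to=self.part2_applies_to,
        )

    def sensor_spec(self) -> SensorSpec:
        return SensorSpec(
            acc_range=self.acc_range,
            acc_resolution=self.acc_resolution,
            gyro_range=self.gyro_range,
            gyro_resolution=self.gyro_resolution,
            clipping_enabled=self.clipping_enabled,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path.name}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
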