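from __future__ import annotations

import numpy as np
import pytest

from nearfall.core import CHANNELS, SensorRecording, SignalWindow

FS = 100.0


def bump_train(
    n: int,
    centers,
    heights,
    width: float = 0.3,
    sample_rate: float = FS,
) -> np.ndarray:
    """Train of raised-cosine bumps; a controllable stand-in for step peaks."""
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for c, h in zip(centers, heights):
        mask = np.abs(t - c) <= width / 2
        x[mask] += h * np.cos(np.pi * (t[mask] - c) / width) ** 2
    return x


def recording_from(channels: dict[str, np.ndarray], sample_rate: float = FS) -> SensorRecording:
    """Recording with the given channels; missing ones default to zeros."""
    n = len(next(iter(channels.values())))
    data = {name: np.zeros(n) for name in CHANNELS}
    data.update(channels)
    return SensorRecording(sample_rate=sample_rate, **data)


def window_of(signal_or_channels, sample_rate: float = FS) -> SignalWindow:
    """Whole-length window over a single-channel or dict-of-channels input."""
    if isinstance(signal_or_channels, dict):
        rec = recording_from(signal_or_channels, sample_rate)
    else:
        x = np.asarray(signal_or_channels, dtype=float)
        rec = recording_from({"acc_v": x}, sample_rate)
    return SignalWindow(rec, 0, len(rec))


@pytest.fixture
def rng():
    return np.random.default_rng(20140403)


@pytest.fixture
def walk_recording():
    from nearfall.simulate import WalkConfig, generate_walk

    return generate_walk(WalkConfig(duration=60.0, seed=5))
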