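import dataclasses

import numpy as np
import pytest

from nearfall.core import SignalWindow, WIDE_BAND, bandpass, demean
from nearfall.gait import detect_gait
from nearfall.misstep import (
    MisstepParams,
    channel_feature_vote,
    classify_window,
    detect_agw,
    detect_missteps,
    extend_environment,
    fft_feature_vote,
    sw_channel_test,
    sw_majority,
)
from nearfall.simulate import MisstepSpec, WalkConfig, generate_walk, inject_missteps

from .conftest import FS, bump_train, recording_from, window_of
from .oracles import reference_agw, reference_sw_channel


def two_half_window(max1, max2, min1=-0.1, min2=-0.1):
    """5-s vertical/AP window with prescribed half-window extrema.

    Built from narrow bumps so the window mean is negligible and the
    demeaned extrema stay within 2% of the prescribed values.
    """
    v = bump_train(500, [1.0, 3.7], [max1, max2], width=0.2)
    ap = bump_train(500, [1.3, 4.0], [-min1, -min2], width=0.2) * -1.0
    return window_of({"acc_v": v, "acc_ap": ap})


class TestDetectAgw:
    def test_asymmetric_half_maxima_flagged(self):
        # 0.9 vs 0.5: 0.9 > 1.5 x 0.5
        agw_v, _ = detect_agw(two_half_window(0.9, 0.5))
        assert agw_v

    def test_mild_asymmetry_not_flagged(self):
        # 0.6 vs 0.5: below the 1.5 ratio
        agw_v, _ = detect_agw(two_half_window(0.6, 0.5))
        assert not agw_v

    def test_equal_halves_not_flagged(self):
        agw_v, _ = detect_agw(two_half_window(0.5, 0.5))
        assert not agw_v

    def test_ap_uses_minima_magnitudes(self):
        _, agw_ap = detect_agw(two_half_window(0.5, 0.5, min1=-0.9, min2=-0.5))
        assert agw_ap
        _, agw_ap = detect_agw(two_half_window(0.5, 0.5, min1=-0.6, min2=-0.5))
        assert not agw_ap

    def test_offset_invariance(self, rng):
        """A constant added to every sample changes no decision."""
        for _ in range(20):
            v = rng.normal(0, 0.3, 500)
            ap = rng.normal(0, 0.3, 500)
            base = detect_agw(window_of({"acc_v": v, "acc_ap": ap}))
            shifted = detect_agw(window_of({"acc_v": v + 0.8, "acc_ap": ap - 0.4}))
            assert base == shifted

    def test_matches_loop_reference(self, rng):
        for _ in range(200):
            v = rng.normal(0, rng.uniform(0.05, 0.5), 500)
            ap = rng.normal(0, rng.uniform(0.05, 0.5), 500)
            if rng.random() < 0.5:
                v[rng.integers(0, 500)] += rng.uniform(0.5, 3)
                ap[rng.integers(0, 500)] -= rng.uniform(0.5, 3)
            w = window_of({"acc_v": v, "acc_ap": ap})
            assert detect_agw(w) == reference_agw(list(v), list(ap))


class TestExtendEnvironment:
    def test_quarter_extension_mid_recording(self):
        rec = recording_from({"acc_v": np.zeros(2000)})
        w = SignalWindow(rec, 750, 500)
        env = extend_environment(w, 0.25)
        assert env.start_index == 625
        assert env.length_samples == 750
        # same centre
        assert env.start_index + env.length_samples / 2 == w.start_index + w.length_samples / 2

    def test_truncated_at_recording_start(self):
        rec = recording_from({"acc_v": np.zeros(1000)})
        env = extend_environment(SignalWindow(rec, 0, 500), 0.25)
        assert env.start_index == 0
        assert env.stop_index == 625

    def test_zero_fraction_is_identity(self):
        rec = recording_from({"acc_v": np.zeros(1000)})
        w = SignalWindow(rec, 200, 500)
        env = extend_environment(w, 0.0)
        assert (env.start_index, env.stop_index) == (w.start_index, w.stop_index)


def spaced_peak_signal(heights, spacing=0.5, n=1000):
    centers = [0.5 + spacing * i for i in range(len(heights))]
    return bump_train(n, centers, heights, width=0.2)


class TestSwChannelTest:
    def test_impact_with_small_recovery_votes(self):
        # p1 = 2.0, following peaks 1.0: ratio 2.0 > 1.8
        x = spaced_peak_signal([2.0, 1.0, 1.0, 1.0, 1.0])
        assert sw_channel_test(x, sample_rate=FS)

    def test_ratio_at_threshold_is_rejected(self):
        x = spaced_peak_signal([1.8, 1.0, 1.0, 1.0, 1.0])
        assert not sw_channel_test(x, sample_rate=FS)

    def test_single_peak_cannot_confirm_recovery(self):
        x = bump_train(1000, [5.0], [2.0])
        assert not sw_channel_test(x, sample_rate=FS)

    def test_rank_rule_uses_third_highest_after(self):
        # after p1=2.0 the peaks are 1.9, 1.5, 0.4, 1.2:
        # temporal p3 = 0.4 (ratio 5.0), rank p3 = 1.2 (ratio 1.67)
        x = spaced_peak_signal([2.0, 1.9, 1.5, 0.4, 1.2])
        assert sw_channel_test(x, MisstepParams(third_peak_rule="temporal"), FS)
        assert not sw_channel_test(x, MisstepParams(third_peak_rule="rank"), FS)

    def test_matches_loop_reference(self, rng):
        t = np.arange(500) / FS
        for _ in range(200):
            x = rng.normal(0, 0.2, 500) + 0.5 * np.sin(2 * np.pi * 2 * t)
            if rng.random() < 0.5:
                x[rng.integers(20, 480)] += rng.uniform(0.5, 3)
            x = x - x.mean()
            assert sw_channel_test(x, sample_rate=FS) == reference_sw_channel(list(x), FS)


def k_pattern_recording(k):
    """Ten-second recording where the first k channels carry the misstep
    peak pattern (one double-height peak then normal peaks) and the rest a
    uniform peak train."""
    centers = np.arange(0.5, 9.6, 0.5)
    pattern = bump_train(1000, centers, [2.0 if abs(c - 5.0) < 0.01 else 1.0 for c in centers])
    flat = bump_train(1000, centers, [1.0] * len(centers))
    names = ["acc_v", "acc_ml", "acc_ap", "gyr_yaw", "gyr_pitch", "gyr_roll"]
    rec = recording_from(
        {nm: (pattern.copy() if i < k else flat.copy()) for i, nm in enumerate(names)}
    )
    return SignalWindow(rec, 250, 500)


class TestSwMajority:
    @pytest.mark.parametrize("k,expected", [(0, False), (3, False), (4, True), (6, True)])
    def test_more_than_three_channels_required(self, k, expected):
        is_sw, votes = sw_majority(k_pattern_recording(k))
        assert sum(votes) == k
        assert is_sw is expected


class TestChannelFeatureVote:
    def test_vertical_nine_steps_and_amplitude(self):
        x = bump_train(500, np.arange(0.25, 4.8, 0.5), [0.7] * 9, width=0.2)
        vote, feats = channel_feature_vote(x, "vertical")
        assert feats.n_steps == 9
        assert feats.max_amplitude > 0.5
        assert vote

    def test_eight_steps_is_not_enough(self):
        x = bump_train(500, np.arange(0.25, 4.3, 0.5)[:8], [2.5] * 8, width=0.2)
        vote, feats = channel_feature_vote(x, "vertical")
        assert feats.n_steps == 8
        assert not vote  # strictly more than 8 required

    def test_yaw_amplitude_interval(self):
        centers = np.arange(0.25, 4.8, 0.5)
        too_fast = bump_train(500, centers, [130] * 10, width=0.2)
        vote, feats = channel_feature_vote(too_fast, "yaw")
        assert feats.max_amplitude > 100
        assert not vote
        in_range = bump_train(500, centers, [75] * 10, width=0.2)
        vote, feats = channel_feature_vote(in_range, "yaw")
        assert 50 <= feats.max_amplitude <= 100
        assert vote

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown feature channel"):
            channel_feature_vote(np.zeros(500), "pitch")


class TestFftFeatureVote:
    def test_broadband_impact_content_votes(self):
        """Wideband noise spreads 7-10 Hz energy over many bins: entropy
        above 1.7 with several bins over the 0.015 g threshold."""
        rng = np.random.default_rng(3)
        vote, entropy, n_above = fft_feature_vote(rng.normal(0, 0.3, 500))
        assert entropy > 1.7
        assert n_above >= 3
        assert vote

    def test_single_tone_concentrates_spectrum(self):
        """A pure 8 Hz tone is one dominant bin; a one-hot normalized
        spectrum has entropy 0, so the vote must fail however strong it is."""
        tone = np.sin(2 * np.pi * 8.0 * np.arange(500) / FS)
        vote, entropy, n_above = fft_feature_vote(tone)
        assert entropy < 1.7
        assert not vote

    def test_quiet_window_has_too_few_bins_above(self):
        rng = np.random.default_rng(4)
        vote, _, n_above = fft_feature_vote(rng.normal(0, 0.005, 500))
        assert n_above < 3
        assert not vote


class TestClassifyWindow:
    def test_normal_gait_window_short_circuits_at_agw(self):
        t = np.arange(500) / FS
        w = window_of(
            {
                "acc_v": 0.6 * np.sin(2 * np.pi * 2 * t),
                "acc_ap": 0.4 * np.sin(2 * np.pi * 2 * t + 1.0),
            }
        )
        det = classify_window(w)
        assert not det.is_agw
        assert not det.is_sw
        assert not det.is_misstep
        assert det.features == ()

    def test_cascade_flags_recorded_for_detected_event(self):
        rec = generate_walk(WalkConfig(duration=30.0, seed=6))
        rec, events = inject_missteps(
            rec, [MisstepSpec(start_time=12.0, duration=2.0, peak_amplitude=3.0)], seed=1
        )
        w = SignalWindow(rec, 1000, 500)  # 10-15 s window holds the event
        det = classify_window(w)
        assert det.is_misstep
        assert det.is_agw and det.is_sw
        assert sum(det.sw_votes) >= 4
        assert sum(det.feature_votes) >= 2
        assert len(det.features) == 4

    def test_final_vote_minimum(self):
        rec = generate_walk(WalkConfig(duration=30.0, seed=6))
        rec, _ = inject_missteps(
            rec, [MisstepSpec(start_time=12.0, duration=2.0, peak_amplitude=3.0)], seed=1
        )
        w = SignalWindow(rec, 1000, 500)
        strict = classify_window(w, MisstepParams(final_vote_min=4))
        default = classify_window(w)
        assert sum(default.feature_votes) >= 2
        if sum(strict.feature_votes) < 4:
            assert not strict.is_misstep


class TestDetectMissteps:
    def test_injected_event_is_the_only_detection(self):
        rec = generate_walk(WalkConfig(duration=60.0, seed=10))
        rec, events = inject_missteps(
            rec, [MisstepSpec(start_time=31.0, duration=2.0, peak_amplitude=2.5)], seed=2
        )
        detections = detect_missteps(rec)
        assert len(detections) >= 1
        ev = events[0]
        for det in detections:
            assert det.window.start_s < ev.stop_time
            assert det.window.stop_s > ev.start_time

    def test_clean_walk_yields_no_detections(self):
        rec = generate_walk(WalkConfig(duration=120.0, seed=12))
        assert detect_missteps(rec) == []

    def test_recording_shorter_than_window(self):
        rec = generate_walk(WalkConfig(duration=3.0, seed=1))
        assert detect_missteps(rec) == []

    def test_cascade_monotone_in_stages(self):
        """Every positive is also SW, AGW and gait — checked on a recording
        with events to exercise all branches."""
        rec = generate_walk(WalkConfig(duration=60.0, seed=13))
        rec, _ = inject_missteps(
            rec,
            [
                MisstepSpec(start_time=20.5, duration=1.5, peak_amplitude=2.0),
                MisstepSpec(start_time=40.0, duration=3.0, peak_amplitude=4.0),
            ],
            seed=3,
        )
        gait = detect_gait(rec)
        for r in gait:
            det = classify_window(r.window)
            if det.is_misstep:
                assert det.is_sw and det.is_agw
            if det.is_sw:
                assert det.is_agw


@pytest.fixture(scope="module")
def fixed_scene():
    rec = generate_walk(WalkConfig(duration=120.0, seed=21))
    specs = [
        MisstepSpec(start_time=s, duration=2.0, peak_amplitude=a)
        for s, a in [(15.0, 1.2), (35.0, 2.5), (55.0, 0.8), (75.0, 4.0), (95.0, 1.8)]
    ]
    rec, _ = inject_missteps(rec, specs, seed=5)
    gait = detect_gait(rec)
    return rec, gait


class TestThresholdMonotonicity:
    @pytest.mark.parametrize(
        "field,values",
        [
            ("peak_ratio", [1.8, 2.6, 4.0]),
            ("half_window_ratio", [1.5, 2.2, 3.5]),
            ("entropy_threshold", [1.7, 2.3, 3.0]),
            ("min_steps", [8, 10, 13]),
            ("amp_threshold_v", [0.5, 1.5, 3.0]),
        ],
    )
    def test_raising_threshold_never_adds_detections(self, fixed_scene, field, values):
        rec, gait = fixed_scene
        counts = []
        for value in values:
            params = dataclasses.replace(MisstepParams(), **{field: value})
            counts.append(len(detect_missteps(rec, params=params, gait_results=gait)))
        assert counts[0] >= 1  # defaults detect the injected events
        assert all(a >= b for a, b in zip(counts, counts[1:]))
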