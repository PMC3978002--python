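"""Run the full two-part misstep classifier on a recording.

A 2-minute walk gets two injected missteps. The detector should flag the
windows overlapping them and report the cascade evidence: which channels
voted at the suspicious-window stage and which features confirmed.
"""

import numpy as np

from nearfall import (
    MisstepSpec,
    WalkConfig,
    detect_missteps,
    generate_walk,
    inject_missteps,
)

walk = generate_walk(WalkConfig(duration=120.0, seed=11))
specs = [
    MisstepSpec(start_time=33.0, duration=1.5, peak_amplitude=3.2),
    MisstepSpec(start_time=81.0, duration=2.5, peak_amplitude=1.4),
]
recording, events = inject_missteps(walk, specs, seed=11)

detections = detect_missteps(recording)
print(f"injected events : {[f'{e.start_time:.0f}-{e.stop_time:.1f} s' for e in events]}")
print(f"detections      : {len(detections)}")
for det in detections:
    feats = {f.channel: f for f in det.features}
    v = feats["vertical"]
    fft = feats["fft-vertical"]
    print(
        f"  window {det.window.start_s:5.1f}-{det.window.stop_s:5.1f} s | "
        f"SW votes {sum(det.sw_votes)}/6 | feature votes {sum(det.feature_votes)}/4 | "
        f"vertical: {v.n_steps} steps, max {v.max_amplitude:.2f} g | "
        f"entropy {fft.spectral_entropy:.2f}, bins>0.015 g: {fft.n_freqs_above}"
    )
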