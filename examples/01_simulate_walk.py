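"""Generate a synthetic walking bout and inject a misstep.

Prints the calibration statistics of the generated signal: the vertical
peak-to-peak range should sit near the laboratory figure of 1.32 g, and the
injected event's vertical peak reaches its drawn amplitude on top of the
walking baseline.
"""

import numpy as np

from nearfall import MisstepSpec, WalkConfig, generate_walk, inject_missteps

config = WalkConfig(duration=60.0, step_freq=2.0, seed=7)
walk = generate_walk(config)

spec = MisstepSpec(start_time=30.0, duration=2.0, peak_amplitude=2.5)
recording, events = inject_missteps(walk, [spec], seed=7)

i0, i1 = int(30.0 * 100), int(32.0 * 100)
print(f"duration            : {recording.duration_s:.0f} s at {recording.sample_rate:.0f} Hz")
print(f"vertical p2p range  : {np.ptp(walk.acc_v):.2f} g (lab calibration target 1.32 +/- 0.3 g)")
print(f"event               : {events[0].start_time:.1f}-{events[0].stop_time:.1f} s")
print(f"vertical peak in event : {recording.acc_v[i0:i1].max():.2f} g "
      f"(impact of {spec.peak_amplitude} g riding on the gait baseline)")
print(f"yaw peak in event   : {recording.gyr_yaw[i0:i1].max():.1f} deg/s "
      "(inside the 50-100 deg/s misstep range)")
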