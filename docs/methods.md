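# Methods

## Signal model and conventions

A recording is six synchronously sampled channels from a single lower-back
sensor: vertical (V), medio-lateral (ML) and anterior-posterior (AP)
acceleration in g, and yaw/pitch/roll angular velocity in deg/s. The
reference sensor samples at 100 Hz with ±2 g range and 0.001 g resolution
for the accelerometer and ±100 deg/s range and 0.0069 deg/s resolution for
the gyroscope; other rates are accepted and every sample-count parameter is
derived as seconds × sample rate. Channels must be gap-free — recordings
with gaps are split upstream. Units are fixed at the API boundary (g,
deg/s); conversion happens only in I/O.

All classification operates on non-overlapping 5-s windows. The window
stride is configurable, but the default tiling is what makes the
normalized suspected-misstep rate (detections per 100 gait windows) a
well-defined fraction of walking time.

## Filtering

All band-pass filters are Butterworth designs of order 4 applied
forward-backward (`sosfiltfilt`), i.e. zero phase. The choice matters: the
classifier compares peak *positions* (the half-window split, the
third-peak-after rule), so group delay from a causal filter would shift
events relative to window boundaries between stages. The cost is a squared
magnitude response, which only sharpens the band edges. Three passbands are
used: 0.5–3.0 Hz (locomotion), 0.5–20.0 Hz (noise reduction before peak
comparison), 7–10 Hz (impact signature of the vertical axis). Signals
shorter than the filter's padding requirement are rejected with an explicit
minimum length.

## Peak rules

Two peak definitions are used, both with a minimum separation of 1/3 s
(3 Hz is the fastest physiologic step rate):

- **Step peaks** (gait-cycle counting, per-channel step counts) must also
  have topographic prominence of at least 10% of the sequence maximum.
  For cycle counting the template response is additionally rescaled to
  signal-amplitude units and maxima below 0.05 g are ignored, so windows
  with no locomotion-band energy (standing, instrument noise) count zero
  cycles rather than counting ripple.
- **Spaced peaks** (the suspicious-window p₁/p₃ test) have no prominence
  floor: the small recovery peaks after an impact are exactly what the test
  must find and compare, and a prominence filter would discard them.

## Gait gate

Each window of V and AP is locomotion-band filtered, demeaned, and
convolved (same-length, centred) with one cycle of a 2 Hz sine — the
template of one gait cycle. Counted response maxima are gait cycles; a
window is gait when both axes count within [2, 15] inclusive (2 ≈ a stride
every two seconds, 15 = 3 steps/s for 5 s). Requiring both axes (an AND
rule, configurable to OR) favours specificity: false gait costs false
misstep alarms downstream. On clean generated walking at step frequency f,
the per-window count is round(5f) ± 1; the ±1 comes from edge maxima of the
convolution whose prominence depends on the window phase.

## Misstep classifier

Part 1 screens and localizes. The half-window comparison uses strict
inequalities throughout ("greater than one and a half times" → `>`); when
the lower half-extremum does not rise above the window mean at all, the
window is treated as maximally asymmetric (abnormal if the other half
does). The AP rule mirrors the vertical one on minima, compared by absolute
magnitude — the downward lurch of a stumble is the AP analogue of the
vertical impact. The environment extension (quarter-window each side,
truncated at recording edges) distinguishes a localized irregularity from
sustained changes such as obstacle negotiation or gait initiation. In the
p₁/p₃ test, p₃ is the third spaced peak *in temporal order* after the
highest (configurable to third-by-rank); fewer than three following peaks,
or a non-positive p₃, vote negative — the recovery pattern cannot be
confirmed. Votes from all six channels (gyroscope channels demeaned exactly
like accelerometer channels, removing slow turning bias) enter the majority
rule: at least 4 of 6.

Part 2 runs on windows that survived part 1 (configurable to run on all
AGWs). Step counts use the step-peak rule on the demeaned window; amplitude
criteria are V max > 0.5 g, AP max > 0.9 g, yaw max within [50, 100] deg/s
(inclusive interval). The spectral features come from the rfft of the
7–10 Hz filtered vertical window at the window's own length (no
zero-padding, no taper): bins are scaled to one-sided amplitude in g
(2|Xₖ|/N) because the 0.015 g threshold is printed in g, and the entropy is
the natural-log Shannon entropy of the in-band amplitude spectrum
normalized to sum one. With a 5-s window the band holds 16 bins
(ln 16 ≈ 2.77 maximum entropy), which places the 1.7 threshold and the
observed misstep operating range (≈ 2.4–2.7) consistently: a single
dominant tone scores near zero, a broadband impact scores high. The final
rule is ≥ 2 of the 4 votes.

## Evaluation metrics

Hit ratio is event-wise: an annotated event is detected if at least one
flagged window overlaps it (half-open intervals), however many windows it
spans. Specificity's denominator is gait windows with zero event overlap;
a flagged window that partially overlaps an event is a hit, never a false
positive. Both are invariant to detection order and duplicates. The
faller/non-faller comparison pools sMS windows (events) and gait windows
(trials) by group into one 2×2 table; the odds ratio uses Woolf's log-based
95% CI with the Haldane–Anscombe 0.5 correction when a cell is zero. This
pooled approximation deliberately ignores within-subject correlation — a
repeated-measures regression is out of scope — so its CI is anti-
conservative relative to a subject-level model.

## Synthetic-data generator

The generator exists to make every stage testable with known ground truth;
it is an engineering construction, documented as such, not a biomechanical
simulation.

**Walking** is a fundamental at the step frequency plus a first harmonic at
quarter amplitude, rescaled so the noiseless vertical peak-to-peak range
equals a draw from N(1.32, 0.3²) g (laboratory preset; home preset
N(1.18, 0.65²) g), with AP and ML as phase-shifted copies at 0.6 and 0.4 of
the vertical amplitude, gyroscope channels at 15 deg/s, white Gaussian
noise (0.05 g accelerometer, 2 deg/s gyroscope), and a constant tilt offset
per accelerometer channel drawn U(−0.3, 0.3) g. Standing filler is tilt
plus low noise (0.01 g).

**A misstep** over a span [start, start+duration), duration U(0.5, 4.0) s:

- an impact spike (raised-cosine, ≈ 0.12 s) whose height is the event's
  peak amplitude, drawn from N(2.49, 1.3²) g truncated to [0.4, 6.0] g
  (truncation lifts the theoretical mean to ≈ 2.63 g). The spike is aligned
  with the strongest vertical gait peak early in the span — a trip happens
  at foot strike — so the impact rides on, not beside, the stepping
  pattern. AP receives the inverted spike (the forward lurch), ML a 0.35×
  copy;
- suppression of the ongoing gait by up to 60% around its local mean under
  a smooth envelope — a stumble interrupts regular stepping, which is what
  makes the recovery peaks genuinely smaller than the impact;
- a damped 4 Hz recovery oscillation (time constant 0.6 s) and a train of
  reduced-amplitude catch steps at 2.5 Hz after the impact — these provide
  the positive "third peak following" that the p₁/p₃ test compares, and
  the elevated step counts seen in misstep windows;
- a 7–10 Hz three-tone burst (0.1 g) spanning the event, the spectral
  signature the FFT vote keys on;
- gyroscope deflections: a yaw spike drawn U(55, 80) deg/s (so the window
  maximum stays inside the 50–100 deg/s criterion after noise), with pitch
  and roll at 0.55× and 0.35× — a loss of balance rotates the whole trunk,
  which is what lets four or more channels clear the suspicious-window
  majority.

All signal modification is confined to the event span, and the returned
annotations are exactly those spans. Each transient component can be
switched off (e.g. `hf_burst_amplitude=0`, `gait_suppression=0`) to create
hard negatives. Sensor quantization (round to resolution grid) is applied
by default in the benchmark; clipping to ±2 g is off by default because
misstep amplitudes up to 6 g must survive injection — the reference
device's printed amplitude statistics exceed its nominal range, and the
generator favours the printed amplitudes.

**What the generator does not emulate:** PD tremor spectra, freezing of
gait, turning, multi-activity daily-living noise (sit-to-stand, stairs),
sensor re-positioning drift, or actual falls. Passing the benchmark
therefore demonstrates that the implementation realizes the intended
decision rules and that those rules separate the modelled misstep
morphology from clean gait — not that the same operating point would hold
on real free-living recordings.

## Benchmark and cohort conditions

The default benchmark is 30 recordings, each ≈ 60 s of walking with
standing filler making up 20% of the time (aligned to the 5-s tiling so the
gait gate is exercised), one injected misstep per recording drawn from the
distributions above, events kept ≥ 8 s from bout edges and ≥ 1 s apart. A
global seed spawns independent per-recording seed sequences. Expected
operating point: hit ratio ≥ 90% with specificity ≥ 95%; residual misses
are low-amplitude events (≲ 0.5 g, which the screen cannot distinguish
from gait variability) and events whose impact lands in the last fraction
of a second of a window.

The simulated cohort gives every subject 500 gait windows ("trials") and
draws sMS windows binomially at 5% for non-fallers and 10% for fallers
(rate ratio 2), 10 subjects per group. At these event counts the pooled
odds-ratio estimate (true OR ≈ 2.1 at these rates) falls within [1.5, 2.7]
in well over 95% of replicates. The per-subject window count is kept at a
realistic free-living magnitude (the printed per-subject range spans
roughly 95–4148 windows over three days).

## Numerical and degenerate-input choices

- Trailing samples shorter than one window are dropped, never padded:
  padding would fabricate signal next to potential events.
- Odd-length windows split with the extra sample in the second half.
- A recording shorter than one window yields zero windows (not an error);
  an empty event list makes the hit ratio an explicit error, as does a
  specificity denominator of zero.
- Demeaning is exact to float precision; all amplitude decisions are
  therefore invariant to constant offsets (sensor tilt).
- Filter edge transients at the 0.5 Hz band edge persist for seconds;
  amplitude assertions in the tests use long signals and interior sections
  where steady state applies.
- CSV round-trips keep six decimals (beyond both sensor resolutions);
  config round-trips are lossless and unknown keys are rejected.

## Known limitations

- Thresholds are taken as published constants; no re-tuning or learning is
  attempted, and threshold sensitivity beyond monotonicity is not
  characterized.
- The specificity denominator uses gait windows only; on data where the
  gait gate leaks non-walking activity, window-wise specificity would be
  optimistic.
- The pooled odds ratio understates uncertainty relative to a
  repeated-measures model when subjects differ strongly in exposure.
- Real misstep morphology is more heterogeneous than the single transient
  family generated here; the benchmark's operating point is an internal
  consistency check, not a clinical validation.
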