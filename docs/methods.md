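# Methods

This note documents the models, detectors, and default parameters of
`motorcap`, the reasoning behind the genuinely open design choices, and what
the synthetic data can and cannot establish.

## Signal conventions

Acceleration is in g, angular velocity in deg/s, sampling at 100 Hz unless
configured otherwise. Sample intervals are half-open `[start, end)`,
0-based. Every stage operates on the Euclidean magnitude of the 3-axis
signals; the magnitude is invariant to any fixed rotation of the sensor
axes, which is what makes the features robust to sensor (re)placement
between and within sessions. Linear filtering per axis commutes with fixed
rotations, so filtering before taking magnitudes preserves that invariance
(a property the test suite checks end to end).

Low-pass filtering uses a 4th-order zero-phase Butterworth
(forward–backward), default cutoff 45 Hz. At 100 Hz sampling this sits just
below Nyquist and is nearly a pass-through for movement-band signals; the
zero-phase choice keeps detected event times from shifting. The cutoff is
validated against Nyquist because the default leaves little headroom.

## Task labeling

The labeling sensor carries one sharp rotation burst about its x-axis at
each task start and a double burst at each end. Detection thresholds
`|gyro_x|` at `median + 6 * MAD`, floored at 50 deg/s; peaks closer than
0.25 s are one burst, bursts closer than 1.0 s are one event, and event
multiplicity (1 vs 2) decides start vs end. Unpairable events are a hard
error listing the orphan times rather than a silent re-pairing. These
thresholds are config-exposed; nothing in the protocol pins them, so they
were chosen to separate cleanly at the burst amplitudes a deliberate fast
wrist rotation produces (hundreds of deg/s against a quiescent floor of a
few deg/s).

The synchronization clap of the calibration pose is detected as the largest
acceleration-magnitude sample above 2.5 g; absence of any supra-threshold
sample is reported explicitly ("no clap found"), not as index 0.

## Task completion time (TIME)

The activity statistic is the standard deviation of the acceleration
magnitude over a 0.5 s window sliding in steps of 10 ms (0.49 s overlap).
With an explicit absolute threshold, a window is active when its std exceeds
the threshold, and the interval runs from the midpoint of the first active
window to the midpoint of the last.

The self-calibrating default is two-stage, because a windowed statistic
localizes an edge only to a fraction of the window, and because a 0.5 s
window holds less than one cycle of a ~1 Hz movement so its raw std
oscillates with cycle phase:

1. **Coarse.** The windowed variance is smoothed with a centered 0.7 s
   moving average and thresholded at the midpoint between the quiet floor
   (1st percentile) and the active plateau (90th percentile, refined
   iteratively against the plateau local to each edge). A variance step
   smeared by symmetric kernels crosses its midpoint where half a window
   overlaps the movement — i.e. at the movement edge.
2. **Fine.** Each coarse edge snaps to the first/last sample within ±0.6 s
   whose deviation from the quiet-baseline median exceeds 4 robust standard
   deviations (MAD-based), confirmed by a neighbor sample.

On constructed bursts of 2–8 s in sensor-level noise this recovers the
programmed duration to within ±0.05 s. A series whose smoothed variance
shows no quiet/active contrast (ratio under 4) is reported as "no movement",
deliberately distinct from a zero-length interval.

## Spectral features (DF, SM)

Spectra are computed by FFT on the raw segment after mean (DC) removal;
without DC removal gravity would pin every dominant frequency at 0. Energy
is the squared bin amplitude. DF is the positive-frequency bin of maximal
energy; numerical ties (within a relative 1e-9) resolve to the lowest
frequency. SM is the energy within DF ± 0.1 Hz, boundary bins inclusive,
over the total positive-frequency energy; the fixed absolute band makes SM
comparable across tasks whose differing durations give differing spectral
resolutions. No zero-padding is applied: padding redistributes a
bin-centered tone's energy into sidelobe samples and breaks the pure-tone
limit SM → 1. For segments shorter than 5 s the band degenerates to the DF
bin itself and the feature vector carries an `sm_lowres` flag in its
metadata.

For white noise, SM does not equal band-width/bandwidth (0.2/50 = 0.004):
the band is centered on the *argmax* bin, whose expected energy is
`ln(N) + gamma` times the mean bin energy over N bins. The expected SM is
therefore `(ln N + gamma + 2)/N` ≈ 0.018 at N = 500, which simulation
reproduces; the tests assert this corrected expectation.

## Rotation features (ARE, RANG)

"Rotation energy" is read as the squared angular-velocity magnitude,
`gx² + gy² + gz²`, averaged over the task — units (deg/s)². This is the
natural kinetic-energy-like reading; nothing in the protocol writes the
formula out. RANG is max − min of the angular-velocity magnitude.

## Gait events

Heel strikes are supra-threshold peaks of the foot acceleration magnitude
(default 1.8 g, refractory 0.4 s). After the impact transient the foot rests
on the ground at ~1 g; once the magnitude has stayed within 0.15 g of 1 g
for 50 ms, the first departure beyond 0.15 g is the lift-off. Step duration
is the time between consecutive same-foot strikes; stance runs from strike
to following lift-off; averages pool both feet and ratios divide the right
foot's mean by the left's. An event-free trace yields empty events (a valid
observation), while computing durations from fewer than two strikes is an
error naming the foot. Stair climbing reuses the same machinery on the
upper-leg sensors.

## Wheelchair propulsion

The propulsion trace is segmented into straight-driving and turning with
SWAB (sliding window and bottom-up) piecewise-linear segmentation applied to
an activity envelope (sliding std, 1 s window, sampled at 10 Hz). The
per-segment SSE cap defaults to four times the envelope's lag-1 difference
variance accumulated over a nominal segment; segments are labeled straight
(high envelope) or turn (low) against the midpoint of the envelope's decile
range, and adjacent same-label segments merge. With the buffer spanning the
whole series SWAB reduces exactly to bottom-up segmentation, which the tests
use as the oracle.

Arm synchrony is measured on straight segments only: push peaks are detected
per wrist (prominence 0.6 × the 98th amplitude percentile, guarded against
noise-only segments by requiring that percentile to exceed 5 robust sigma),
the cycle duration is the median inter-peak interval — the spectral peak of
a pulse train can sit on a harmonic, so DF is not used here — and the
per-cycle lag |t_left − t_right| is normalized by the cycle duration. The
reported feature is the mean push-phase lag in [0, 0.5]; the release-phase
lag, measured from the secondary peak between pushes, is emitted as
diagnostic metadata only, since the feature table carries a single synchrony
number.

## Rating model and evaluation

Features and targets are min-max standardized to [0, 1] on the training
data; test data reuse training bounds and may fall outside [0, 1].
A constant training column is an error naming the feature. The model is OLS;
per-coefficient p-values come from the standard coefficient t-test
(coefficient / SE against Student-t with n − k − 1 df). Gating drops
features with p ≥ 0.05 and refits once; a `selection="backward"` variant
eliminates the least significant feature one at a time until all retained
coefficients are significant. Backward elimination is the pipeline default
because with few sessions and strongly correlated features the one-shot test
can judge every feature individually redundant and discard all of them, in
which case the model collapses to the fold mean (whose leave-one-out
predictions are *anti*-correlated with the truth — an r near −1 in a report
is the signature of this collapse, not a sign error).

Evaluation is leave-one-session-out: folds are (subject, week) keys, so the
left- and right-hand executions of a single-handed task share a fold and a
model. Scaling and selection are computed within each training fold —
leak-free — by default; `gate_scope="dataset"` instead selects once on the
full dataset before cross-validating, reproducing protocols that report a
single p-value per task and feature. The pipeline falls back to
dataset-scope selection automatically when a training fold would retain
fewer than 8 residual degrees of freedom under the full feature set (e.g.
14 bimanual features against 15 training rows). Zero-variance predictions
or truths make Pearson r undefined; this is flagged explicitly rather than
returned as a bare NaN.

## Synthetic sessions

The generator emulates the statistical structure the analysis is sensitive
to, not biomechanics:

- **Manual tasks** are a quiescent lead-in/out (gravity plus 0.008 g sensor
  noise) around an active window of a cycle-frequency tone (task-specific
  nominal rates, 0.5–1.2 Hz) plus movement-band broadband noise, projected
  onto directions with a substantial vertical component — a near-horizontal
  dynamic would be invisible to the magnitude pipeline, which is not how
  reaching movements behave. Rising impairment lengthens the active window
  (up to 2×), narrows the acceleration spread, moves spectral energy from
  the tone into the broadband component, and shrinks the angular-velocity
  amplitude. Impairment acts through partly independent facets (speed,
  amplitude, spectral dispersion, rotation) with ±0.15 trial-to-trial
  spread, plus ~10 % execution-speed variability; without this decorrelation
  every feature would be a perfect proxy of every other, which no real
  trial-to-trial data shows and which makes per-coefficient inference
  degenerate.
- **Gait** places a 2 g impact pulse at each programmed heel strike, a ~1 g
  plateau during stance, a sharp 0.6 g toe-off transient at lift-off, and an
  elevated swing profile; pulse peaks sit on exact sample indices so that
  event recovery can be asserted at ±2 samples and durations at ±2 %.
- **Wheelchair propulsion** lays out straight (n push cycles) → turn →
  straight, one push peak and a smaller release peak per cycle per wrist,
  the right wrist delayed by the programmed lag fraction.
- **The labeling trace** carries 0.16 s half-sine rotation bursts (500
  deg/s): one at each task start, two at each end.
- **Ratings** are `clip(w0 + wᵀx + ε, 0, 1)` where `x` is the feature
  vector *extracted from the generated traces* and ε is Gaussian. Using
  extracted rather than latent quantities makes the noiseless case exactly
  linear in what the model sees, so LOSO must recover the generating
  weights to machine precision — a sharp correctness test of the whole
  scaling/fitting/selection chain. Default weights follow the expected
  clinical directions (longer TIME → worse; higher SM, ARE, RANG → better)
  with magnitudes chosen to keep ratings inside (0, 1) across the impairment
  range, so the clip is inactive and linearity exact.

Everything is deterministic given the seed; there is no global random
state. Sub-seeds derive from (seed, subject, week, task index), so any
session can be regenerated independently.

What the synthetic data does **not** emulate: real limb kinematics, sensor
drift or slippage beyond additive noise, magnetometer output, rater
disagreement structure (noise is i.i.d. Gaussian), or nonlinear
feature–rating relationships. Passing tests therefore demonstrate that the
pipeline recovers what it measures and that the estimation machinery is
correct and calibrated — not that these features predict clinical ratings
in real populations.

## Problem sizes and defaults

The test suite and acceptance script run, per quantity: 200 random traces
for the feature oracles; 20 seeds of 10-step gait at 0.02 g noise; lags
{0, 0.1, 0.25} × 5 seeds of 8-cycle propulsion; 20 seeds × four burst
durations for task-time recovery; 15 sessions (5 subjects × 3 weeks, both
hands) for regression recovery, with 10 replicate datasets at rating noise
0.05; 1000 fits at n = 30 for gate calibration; and a 4-subject × 4-week
demo pipeline executed twice for bit-level determinism. These sizes give
stable Monte-Carlo estimates (binomial SE ≈ 0.7 % at 1000 replicates for
the gate rate) while keeping a full run in the low minutes on one CPU.

## Known limitations

- TIME from the activity detector measures when the hand moves, not when
  objects are touched and released, so it can differ from stopwatch-based
  completion times by design.
- The stance-duration ratio's direction depends on which side is affected;
  a linear model with a fixed sign cannot use it symmetrically, which is why
  the synthetic gait rating leans on cadence instead.
- With ~15 sessions and 11–14 features, per-coefficient inference is at the
  edge of identifiability regardless of protocol; the dataset-scope /
  backward-elimination fallbacks make the small-sample behavior graceful,
  not powerful.
- SM's fixed 0.2 Hz band quantizes harshly for tasks shorter than ~5 s
  (band = one bin); the low-resolution flag marks affected vectors.
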