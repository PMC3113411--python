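# Methods

## The system in one paragraph

`cortexloop` is a headless, deterministic re-creation of a classic real-time
brain-machine-interface (BMI) architecture: three engines — acquisition,
signal processing, application — pass one bundle of variables per frame
around a closed ring. The acquisition engine owns the clock (33.3 ms frames,
40 samples per frame at 1200 Hz by default); each frame is fully processed
and a system output produced before the next frame is emitted. Every value
that crosses an engine boundary or reaches disk carries the packet index of
its frame, which makes runs exactly replayable. On top of the ring sit a
directionally tuned ECoG simulator, autoregressive band-power features with
pseudo-Z normalization, population-vector decoding with permutation-based
feature selection, a center-out cursor task, an HDF5 recorder with MAT
export, and timing benches.

## Synthetic ECoG model

Each channel emits

    S = S1 + d · cos(θ − PD) · S2

where `S1` is pink noise (power spectral density ∝ 1/f), `S2` is the
high-gamma (70–120 Hz) band component of the same noise process, `d ∈ [0, 1]`
is the modulation depth, `θ` the drive direction (target direction during
training and closed-loop control; the drive is inactive during baseline) and
`PD` the channel's preferred direction. Preferred directions of the
`n_channels` (default 32) channels are uniform over the plane, `2πk/n`.

Two design points matter here:

* **Pink noise is generated by a streaming filter cascade**, not FFT
  shaping: white Gaussian noise runs through ~10 log-spaced first-order
  pole/zero sections (bilinear-transformed, paired into biquads). Filter
  state persists across blocks, so generation is exactly block-size
  invariant — two consecutive 40-sample frames equal one 80-sample call.
  The realized log–log PSD slope over 2–300 Hz is −1.00 ± 0.05 (the slope
  check in the test suite allows ±0.2).

* **S2 must be phase-aligned with S1.** The band component is extracted with
  a linear-phase FIR band-pass (401 taps at 1200 Hz, ≈10 Hz transition) and
  S1 is delayed by the filter's exact integer group delay. In-band the
  output transfer is then `(1 + d·cos)·S1band`, so band *power* scales as
  `(1 + d·cos)²` — monotone in the cosine, i.e. a genuine directional tuning
  curve with a single maximum, recoverable by linear regression. A causal
  IIR band-pass instead rotates S2's phase against S1; the cross term then
  averages out and only the even `d²cos²` component survives, which has two
  maxima per cycle and *no* preferred direction. We verified this
  numerically (band-power ratio 1.12× instead of the expected 2.25× at
  d = 0.5) before settling on the FIR design.

Amplitude is scaled to 50 µV RMS per channel — a typical subdural ECoG
amplitude; the scale cancels in every downstream statistic. Default depth is
0.3 for parameter-recovery runs and 0.5 for closed-loop runs.

## Features

Per frame, the trailing 500 ms window of each channel is fit with an AR(15)
model by Burg's method; the model PSD is evaluated on a 1 Hz grid and
trapezoid-integrated over 10 Hz bins from 0 to 200 Hz (20 bands — everything
the decoders use lies at or below 120 Hz). The window hops one frame
(33.3 ms) per frame, ~93 % overlap. The Burg recursion is vectorized over
channels (one pass fits all 32 channels), which is what keeps feature
extraction comfortably inside the frame budget; it is checked coefficient-
for-coefficient against the per-series Burg implementation in statsmodels.

Band powers are standardized to pseudo-Z-scores,
`z = (f − mean) / sd`, with mean and sample standard deviation (n−1)
accumulated by a numerically stable streaming (Welford) update over a
baseline period (~3 minutes, ≈5400 frames) in which the drive is inactive.
Normalizing the baseline frames by their own statistics yields per-feature
mean 0 and sd 1 up to floating-point error by construction; the calibration
test bounds |mean| < 0.05 and sd ∈ [0.9, 1.1].

## Decoding

Directional tuning of each feature is modelled by ordinary least squares of
its activity on the desired movement direction,

    f_i = b0_i + bx_i·m_x + by_i·m_y,

with `(m_x, m_y)` the unit vector toward the current target for every
buffered training frame. The preferred direction is
`C_i = (bx_i, by_i)/‖(bx_i, by_i)‖` and the 2-D control signal is the
population vector

    P = Σ_{i ∈ selected} (d_i − b0_i) · C_i,

scaled by a live gain. Feature selection thresholds the plain (unadjusted)
R² at the 95th percentile of a permutation null: tuning is refit on 1000
target-shuffled copies of the buffer (whole kinematics rows permuted, which
preserves the marginal target distribution while breaking the
feature–target pairing) and R² values are pooled across features. The null
may be computed on an evenly spaced feature subset (default 64 of 640) —
the pooled percentiles are unchanged in expectation and the cost drops
tenfold.

Caveat recorded deliberately: with 93 %-overlapping windows both features
and kinematics are autocorrelated, while row permutation produces an
exchangeable null. On simulator data this inflates the selection rate of
weakly correlated out-of-band features; they carry near-zero excess and
random directions, so they add variance but no bias to the population
vector, and the in-band features (R² ≈ 0.4–0.7 at d = 0.3) clear the
threshold by two orders of magnitude. The 5 % false-positive calibration of
the null is therefore asserted on exchangeable (i.i.d.) features.

The 1-D push-pull decoder `c_y = a·(s1 − s2) − b` maps the high-gamma power
difference of two electrodes to vertical velocity; `a = 1/sd`, `b = a·mean`
over a baseline of the difference, standardizing the baseline control signal
to zero mean, unit variance (sample sd). The population vector is also
expressible as a generic linear readout (`TuningModel.as_linear`), and the
equivalence is tested.

## Task

Center-out: unit-square workspace `[−1, 1]²`, targets on a circle of radius
0.8, target and cursor radius 0.1, trial timeout 10 s, inter-trial interval
2 s with cursor and target hidden and control input ignored. A trial
succeeds when the center distance falls within the sum of the radii; there
is no hold requirement by default. Targets come in balanced shuffled blocks.
With two targets the layout is vertical and a length-1 control signal moves
the cursor vertically, positive up. The control signal is integrated as
velocity in screen-units/s; the decoder gain is calibrated once after
training so the median population-vector magnitude maps to 0.4 units/s
(crossing the target distance in ~2 s) — the knob a human operator would
otherwise trim by hand mid-run.

## Workflow and determinism

The four-step session (baseline → training-data collection → decoder
training → closed-loop control) runs as one continuous system: every
transition is a live parameter update, applied atomically at the start of
the next frame, stamped with that frame's packet index and change-logged by
the recorder — including the published decoder weights, so mid-session
refits are visible in the controls log. The training cursor is
computer-driven straight toward each target (standing in for the
experimenter's mouse); during closed-loop trials the simulator's drive
follows the current target (the "subject" intends toward the target).

In simulated-clock mode the system is bit-deterministic: repeated runs with
the same seeds and configuration produce byte-identical sampled-variable
streams, and re-executing the task from the recorded control signals
reproduces the recorded cursor trajectory exactly. Default study sizes —
180 s baseline, 24 training trials (3 per direction), 40 control trials —
run in a few minutes of wall time; the repository's smaller test sessions
(20–60 s baselines) exercise identical code paths.

## Timing benches

*Processing* is the wall time from block arrival to ring completion
(virtual, when an injected `virtual_cost_s` is set); *refresh* is the
interval between application-engine display updates, exactly one frame
period under the simulated clock; *latency* is the time from a zero
crossing of a sine test tone to the response flag flipped at the display
update of the frame that contains the crossing. With crossing phases
uniform over the frame, mean latency = frame/2 + processing delay and
sd = frame/√12. Two numerical details: the tone is detuned to 9.7 Hz
(an exact 10 Hz tone against the 33.3 ms frame locks the crossing phase to
a two-point pattern; the detuned tone sweeps a 97-point uniform grid, which
is the uniform-phase condition under which the closed form holds), and a
crossing is only observable at the next sample, which biases the mean by
+1/sample_rate — the bench samples the tone at 4800 Hz so this term stays
well inside the closed form's 2 % check. Both edges are detected, with
linear interpolation for sub-sample crossing times.

## Recording

One HDF5 file per run; suspend/stop closes it, resume opens a new one with
all in-memory engine state (baseline statistics, decoder weights) intact.
Per engine, *sampled variables* are per-frame streams and *controls* are
change logs with the initial value at index 0; everything is keyed by packet
index, arrays may change size per packet (stored ragged, exported to MAT as
cell arrays), and streams are index-sorted at close so out-of-order network
arrival cannot corrupt a file. The save path is a bounded FIFO
(capacity 1024) that never blocks the real-time path; overflow drops the
newest record and counts it. Dataset timestamps are disabled so identical
runs produce identical files.

## What the simulator does and does not show

The generator reproduces the *structure* real decoders rely on — 1/f
background, band-limited directional modulation, per-window estimation
noise — but not artifacts, nonstationarity, channel correlations, volume
conduction, or a learning subject. Passing tests therefore demonstrate that
the pipeline is correct and deterministic and that the decoder recovers the
tuning the generator embeds; they say nothing about decoding performance on
real ECoG. Closed-loop success rates here reflect a noiseless "intent"
(drive = target direction) and should be read as an upper bound of the
architecture, not a behavioral claim.

## Known limitations

* The shuffle null is exchangeable while session data are autocorrelated
  (discussed above); a block-permutation null would be the conservative
  alternative and is left as an extension.
* Suspend/resume and hot-swap are features of the in-process transport; the
  TCP transport runs fixed-length sessions (links self-repair, and the
  distributed run is verified byte-identical to the local one).
* The UDP acquisition dialect is this package's own (documented in
  `simulate.py`); no vendor format is parsed.
* AR band power is bin-integrated model PSD; density-at-bin-center is the
  other convention and differs by a near-constant factor at these
  bandwidths.
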