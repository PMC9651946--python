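# Methods

This note documents the models, numerical choices and limitations behind
`flygaze`. Angles are degrees, time seconds, frequencies Hz everywhere.

## Control model

The gaze-stabilization loop is modeled as linear and time-invariant about
the yaw axis. The visual perturbation R generates retinal slip
E = R − H − B; four sensorimotor branches close the loop:

- **G_head,V** (E → H): visual head drive, pure delay 30 ms (visuomotor
  latency);
- **G_head,M** (B → H): mechanosensory head drive from body rotation,
  pure delay 5 ms (haltere latency);
- **G_body,V** (E → B) and **G_body,M** (B → B): the body analogues.

Each branch is a rational transfer function times a pure delay. Visual
feedback carries an implicit gain of −1 (self-motion produces equal and
opposite retinal slip), which is what makes the loop negative feedback.
Solving the loop for the body-free head response gives the three-term
decomposition implemented in `decompose.closed_loop_head_free`; body
fixation removes the two body terms; motor replay (display co-rotating with
the body) removes body visual feedback while leaving the mechanosensory
route intact. Neck proprioception is outside the model: it is present in
every condition the model contrasts, so it cancels out of the comparisons
but is genuinely not represented.

### Sign conventions

The canonical decomposition adds the mechanosensory term
(+ G_head,M/(1+G_head,V) · B/R); destructive interference with the visual
drive is carried by the *phase* of G_head,M, not by an explicit minus sign.
A subtractive variant is available via `mech_feedback_sign=-1`. For the
motor-replay inversion, two conventions are implemented and labeled:
`"as_printed"` computes (1 − G_head,V)·(H/B) and `"rederived"` computes
(1 + G_head,V)·(H/B). The rederived form is the exact inverse of the replay
loop H = G_head,V·(−H) + g·G_head,M·B, and is what the pipeline's gating
contrast uses; the alternative is retained so both conventions found in the
literature can be reproduced.

## Default synthetic animal

`flysim.default_fly()` is a documented, stable parameterization with
fly-like *qualitative* behavior; its constants are design choices, not
measurements:

| branch | form | gain/pole | delay |
|---|---|---|---|
| G_head,V | low-pass | 0.3, pole 3 Hz | 30 ms |
| G_head,M | differentiator, negative sign | 0.04 s, pole 8 Hz | 5 ms |
| G_body,V | low-pass | 3.0, pole 0.8 Hz | 30 ms |
| G_body,M | differentiator, negative sign | 0.1 s, pole 1.5 Hz | 5 ms |

Rationale: the body visual gain of 3 makes the closed-loop body response
near unity at low frequency and low-pass overall; the negative
differentiator branches implement velocity damping; the mechanosensory head
branch yields |G_head,M| rising with frequency (high-pass, phase −96° to
−162° across 0.7–10.6 Hz — destructive against the visual drive); the head
visual gain of 0.3 keeps the body-fixed head response just inside the ±15°
neck limit for the 250 deg/s battery so the linear analysis applies without
saturation rescue. Gains of delayed feedback branches are kept below unity
at the frequencies where their delay contributes ~180° of phase; the loop
is verified numerically before every simulation (component poles checked
analytically, plus an impulse-response decay test of the full delayed loop).
The mechanosensory weighting |G_head,V+M / G_head,V| of this animal is
0.54–0.94 below ~5 Hz and exceeds 1 at 10.6 Hz, where its body barely moves
— the damping band, not its exact width, is the modeled phenomenon.

## Simulation

Transfer functions are discretized by bilinear transform at an internal
rate of 10× the recording rate (1 kHz for 100 Hz recordings) so the 5 ms
haltere delay is an exact integer number of samples; delays round to the
nearest internal sample (minimum one, to keep the loop causal). The loop is
stepped sample by sample; the head output is clipped at ±head_limit with
state clamping (branch states rescaled onto the limit — the simplest
anti-windup consistent with saturated trajectories). The result is
decimated back to the recording rate and white Gaussian tracking noise is
added to the *measured* head and body angles only (the noise source being
emulated is video tracking, not motor noise); the stored retinal slip E is
the pre-noise loop error. Stimuli supplied as `PerturbationSpec` are
synthesized exactly at the internal rate; stimuli supplied as sampled
series are band-limited (FFT) resampled, which is exact for the periodic
battery signals.

Synthetic saccades are smooth single-peaked velocity pulses (displacement
A·(x − sin 2πx/2π), peak velocity 2A/d) followed by an exponential return
to neutral with time constant τ. Generator defaults — amplitude
10 ± 2.5° (floor 5°, clip at the 15° limit), duration 40–90 ms,
τ = 0.2 s body-free and 8× that body-fixed, ~9 saccades per 20 s trial,
0.1° noise — keep saccadic peak velocities well above 100 deg/s while
return movements stay below it, so the two movement classes are
kinematically separable, and injected events are logged as ground truth.

## System identification

- **Preprocessing**: linear detrend plus zero-phase (forward–backward)
  2nd-order Butterworth low-pass at 40 Hz. The effective 4th-order
  zero-phase response attenuates 45 Hz by ~19× at 100 Hz sampling while
  leaving passband timing untouched. Rejected below 80 Hz sampling (cutoff
  at/above Nyquist).
- **Spectra**: chirp-z transform on 0–50 Hz in 0.05 Hz steps, normalized so
  a sine A·sin(2πft+φ) over whole cycles returns A·e^{jφ} at its bin. FRFs
  divide output by input spectra; input magnitudes below 1e-8 flag the
  frequency invalid instead of dividing.
- **Trial windows**: 12 s trials, first 2 s discarded (transients), the
  10 s analysis window holds an integer number of cycles at every battery
  frequency (all are multiples of 0.1 Hz), eliminating leakage at the
  stimulus bins.
- **Coherence**: magnitude-squared coherence from trial-averaged cross- and
  auto-spectra; at least two trials (one trial is degenerately 1).
- **Saturation rescue**: samples at >95% of the limit with speed below 10%
  of the sine's limiting peak speed are masked; a three-parameter sinusoid
  (LSSA) fit on the remainder rescales the gain at that frequency; phase is
  never touched. Rejected when >90% of samples are masked.
- **Across-animal statistics**: arithmetic mean/SD of gain and compensation
  error, circular mean and circular SD (√(−2 ln R̄)) of phase. Derived
  transforms that mix animal groups get uncertainties by seeded Monte Carlo
  (gain normal, phase wrapped-normal, ≥100 draws), since the groups are
  independent by design.

## Saccade analysis

Detection: |velocity| threshold (default 100 deg/s, logged with results)
with hysteresis — events extend outward while speed exceeds 25% of the
threshold *and* velocity keeps the saccade's sign, so the event ends at the
movement turn-around and the post-saccade return is excluded; events closer
than 100 ms merge. The damping constant τ comes from a nonlinear
least-squares fit of θ₀e^{−t/τ}+θ∞ over 1 s after the event (log-linear
initialization; fits with R² < 0.5, or windows contaminated by the next
event, yield no τ). Group contrasts use the two-sided Wilcoxon rank-sum and
Welch t-test plus the ratio of group medians; displacement-spread contrasts
use a two-sided F-test.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis assumes: nested LTI
feedback with realistic delays, head saturation, measurement noise, and
gated mechanosensory transmission (a scalar gate on the haltere pathway,
1 for self-generated motion, 0.1 for imposed motion — the biological gating
mechanism is not modeled). Passing tests therefore demonstrate that the
estimators are correct and well-conditioned under those assumptions at
realistic noise levels, including exact recovery of a transform that is
never directly measurable. They do not validate the LTI assumption itself,
head–body coupling nonlinearities beyond saturation, trial-to-trial
behavioral variability, or tracking-noise spectra of real video, and the
default animal's gain curves are plausible rather than fitted to any
recorded fly.

## Problem sizes

Default study sizes: 5 animals × 7 frequencies × 12 s for population
recovery; 3 animals × 3 mid-band frequencies for the gating contrast
(mid-band because both the self- and externally generated estimates are
well-conditioned there); 40 trials per condition (≈360 events per group)
for the saccade study. These sizes give sampling error comfortably inside
the documented recovery tolerances while keeping a full run in tens of
seconds on one core.
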