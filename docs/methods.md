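# Methods

This note documents the generative model behind the synthetic recordings,
the signal-processing and statistical choices of the pipeline, and what the
passing tests do and do not establish about real data.

## The synthetic tethered-flight model

Every recording is built stroke by stroke at 10 kHz.

**Wingbeat kinematics.**  Per-stroke wingbeat frequency is a stationary AR(1)
process around the condition mean (default SD 0.5 Hz, stroke-to-stroke
correlation 0.99, clipped to the admissible band).  Tethered moths modulate
wingbeat frequency over seconds, not cycle to cycle; modelling the jitter as
a slow drift also keeps F_z locally narrowband, which matters because the
type-II Chebyshev band-pass visibly distorts the Hilbert phase of a signal
whose frequency steps discontinuously at each cycle.  The continuous stroke
coordinate u(t) is a monotone cubic (PCHIP) interpolant through the stroke
boundaries, so instantaneous frequency is continuous; with zero jitter it
degenerates to a linear ramp and the bout is exactly periodic.

**Vertical force.**  F_z = A·cos(2π·u(t)) + noise (A = 15 mN).  The cosine
convention puts the ascending zero crossing of the *Hilbert phase* — the
segmentation criterion — exactly at each true stroke boundary, making the
boundary-recovery oracle well posed.  (The phase of a narrowband signal
crosses zero at the oscillation peak, not at the signal's zero crossing.)

**Spike timing.**  Each stroke carries one DLM spike per side at phase
~N(0.327, 0.05) (the natural DLM range is roughly 20–55% of the stroke) and
one first DVM spike per side following the same-side DLM by
~N(interval_mean, 2.0 ms); left/right timing receives 0.3 ms of independent
jitter.  Condition presets: pitch-up 18.6 Hz / 24.5 ms, pitch-down
22.9 Hz / 17.6 ms, stimulation sessions 20 Hz / 20 ms.

**EMG.**  Each muscle channel is Gaussian noise (SD 0.05 V) plus a fixed
biphasic kernel — one sine cycle over 2 ms, amplitude 1 V — placed at each
spike time (kernel onset = spike time), giving a 20:1 SNR.  Real muscle
action potential shapes, baseline wander and motion artifacts are *not*
emulated; threshold-crossing detection on this data is therefore an easier
problem than interactive spike sorting on real EMG.

**Pitch torque.**  Within a stroke,

    τ_x(φ) = A_τ·sin(2πKφ − g·δ) + G·δ·w(φ) + uncoupled(φ) + offset + noise

with φ the within-stroke fraction, K = 4 oscillation cycles (3 is
configurable), A_τ = 1 mN m, and δ the deviation of the stroke's *first* DLM
spike phase from the natural mean — natural jitter and stimulation-evoked
shifts enter through the same mechanistic variable.  Two coupled mechanisms:

* a linear *phase advance* of the oscillation for earlier DLM spikes
  (g = 1.5 rad per unit phase deviation), and
* an additive transient w(φ) scaled by δ (G = 15 mN m per unit deviation):
  a negative lobe over φ < 0.25 followed by a broader positive lobe, so an
  early evoked spike (δ < 0) pushes torque positive (nose-down) immediately
  after stimulation while the net signed area makes angular impulse increase
  linearly with evoked phase (positive slope; more negative angular momentum
  for a longer DLM→DVM interval).

G was fixed once so that the peak torque deviation at the largest evoked
shifts (|δ| ≈ 0.33) reaches at least 4 mN m.  Uncoupled stroke-to-stroke
variability is a random 4-harmonic Fourier series per stroke (SD 0.3/h mN m
per harmonic).  For stimulation sessions the uncoupled amplitude is rescaled
once, by a bisection solve at generation time, so that the noiseless coupled
component accounts for a target fraction (default 0.355) of the per-column
variance of the stimulated-stroke torque matrix — the calibration the
variance-accounting recovery checks rely on.  The torque model is
phenomenological: there is no aerodynamic or musculoskeletal forward model.

**Stimulation protocol.**  Stimuli follow the first detected trigger-DVM
spike after the previous stimulus by a uniform 4–40 ms delay, separated by
at least 4 s; both DLMs receive an evoked spike exactly 4 ms after each
stimulus, and natural DLM spikes scheduled within the 20 ms motor-unit
refractory period after an evoked spike are suppressed ("motor overwrite").
The generator's stimulated-stroke set is defined *operationally*: strokes
whose first DLM spike on both sides falls within the 5 ms evoked window — a
natural spike landing in that window is indistinguishable from an evoked one
to any detector, and the inclusion rule treats it as evoked.

**Quiescent segments.**  Constant weight vector (−19.6 mN on z, ≈ 2 g moth)
plus noise; sensor torques are r × F for the configured true COM offset.
With a purely vertical load the z-component of r is only weakly
identifiable — and correspondingly irrelevant for the in-flight torque
correction, which is dominated by the vertical force.

## Pipeline choices

* **Zero-phase filtering everywhere** (forward–backward), because any phase
  lag would bias spike-phase assignment; the magnitude response is squared
  and the effective order doubles.  The 1 kHz force/torque low-pass is an
  8th-order Butterworth.
* **Band-pass for segmentation**: Chebyshev type II, 40 dB stop-band, with
  scipy's convention that the band gives the stop-band edges.  The
  stimulation variant is the 4th-order 10–40 Hz design.  For the 5–35 Hz
  variant the order is a free choice; order 6 keeps the squared response
  above 0.99 across 15–23 Hz while remaining numerically well conditioned at
  these very low normalized frequencies (order 8 measurably degrades
  boundary precision through coefficient round-off).  The channel mean is
  removed before filtering, so DC is nulled exactly.
* **Stroke conventions**: half-open [t0, t1); a spike exactly at a crossing
  belongs to the starting stroke; in-stroke times quantized to 0.1 ms,
  rounding half away from zero; strokes whose implied frequency falls
  outside the filter band are flagged invalid; edge strokes truncated by the
  record are discarded.  Strokes lacking a DLM or DVM spike on a side are
  excluded listwise for that side and counted.
* **Spike detection**: per-channel threshold at 5× the robust noise SD
  (1.4826·MAD) on the rectified voltage, 2 ms dead time, spike time = first
  suprathreshold sample.  This replaces the interactive commercial sorter
  used on real data; detection onset sits ~0.08 ms after the true spike
  time, far below the 0.1 ms quantization.
* **COM estimation**: bounded linear least squares (default ±10 mm box) on
  the quiescent model τ = r × F, reported with the residual RMS.
* **CCA (k = 1)**: for univariate Ŷ the canonical torque direction is the
  regression direction (T̂ᵀT̂ + εnI)⁻¹T̂ᵀŶ, normalized; ridge ε = 10⁻⁶
  (relative to the mean covariance diagonal) stabilizes the rank-deficient
  n < m = 300 case.  Loadings are the least-squares map from scores back to
  T̂, so reconstructions are the projection of the data onto the score
  direction; the sign is oriented so scores correlate positively with Ŷ.
  Variance explained is computed on the z-scored matrix (each of the 300
  phase samples weighted equally); a raw-unit variant is available via
  `variance_explained(..., scale="raw")`.  Y is z-scored with the sample SD.
  scikit-learn's `CCA` serves as an independent cross-check in the tests,
  never as the implementation.
* **Mechanics**: reconstructions are resampled from m = 300 back to each
  stroke's original sample count before trapezoidal integration;
  Δω = J / I_yy with I_yy = 266.7 g mm² read as 2.667·10⁻⁷ kg m² (the
  printed unit "g mm⁻²" is not dimensionally usable in Δω = J/I).
* **Statistics**: two-sided paired t-tests at α = 0.05 without multiplicity
  correction (pairs = individual × side for timing, individual for
  frequency and torques); the stimulation slope test is a linear
  mixed-effects model with a random intercept per individual, falling back
  to per-individual OLS slopes plus a one-sample t-test (flagged) if the
  mixed fit is singular.
* **Decile summaries** use equal-count bins of evoked/stimulation phase.

## What the tests show — and what they cannot

Recovery tests run the full chain on generator output: 9 virtual individuals
× ~500 strokes per optomotor condition recover the condition means
(intervals to ±0.8/±0.7 ms, frequencies to ±0.4/±0.5 Hz, DVM phases and the
natural DLM phase to ±1 percentage point); 5 virtual individuals × 480
stimulation trials (≥ 200 valid strokes each) recover the calibrated
unexplained-variance fraction to within ±6.7 percentage points and give
every individual a reconstruction-Δω decile span well above 400 deg/s.
Type-I-error suites (200 replicates) simulate the statistical inputs of the
paired and slope tests directly rather than re-running the signal pipeline,
which tests the inferential step at meaningful replication counts within a
practical compute budget.

Because the generator produces what the pipeline assumes — Gaussian jitter,
a stereotyped EMG kernel, an exactly linear DLM–torque coupling, no
electrode drift, no stimulus artifacts, no missing channels — passing these
tests demonstrates correctness of the implementation and identifiability of
the analysis, not robustness to the full messiness of real tethered-flight
recordings.  One subtlety the synthetic model did expose: evoked phase and
the time-normalized torque rows both depend on the wingbeat period, so a
small period-mediated association survives even with DLM coupling switched
off; the coupling-null permutation test therefore freezes period drift.

## Known limitations

* Single evoked component (k = 1) only; kernel (non-linear) CCA is out of
  scope, though `CCATimingFeatures` is the natural hook point.
* One DVM spike per stroke per side; multi-spike DVM bursts are not
  modelled.
* The torque noise level and EMG SNR of the real rig are unknown; generator
  defaults are calibrated only to reproduce the summary statistics above.
* Roll/yaw conditions have no bespoke generator structure; only the pitch
  axis carries condition-dependent signal.
* The strain-gauge calibration matrix of a real load cell is accepted as an
  optional linear map but synthetic data is generated already calibrated.
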