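# tetherpitch

Spike-resolved neuromechanics of pitch control in tethered hawkmoth flight.

Flying insects steer with a handful of muscles, each an effectively single
motor unit whose action-potential timing is precise to the millisecond.
`tetherpitch` implements the complete analysis chain for asking whether the
indirect *power* muscles — the dorsolongitudinal downstroke muscles (DLMs)
and dorsoventral upstroke muscles (DVMs) of *Manduca sexta* — control body
pitch: from raw tethered-flight EMG and six-axis force/torque recordings to
the attribution of within-wingstroke pitch-torque features to DLM spike
timing.  Because the corresponding experimental recordings are not publicly
deposited, the package ships a first-class synthetic-data generator that
emulates the recordings with known ground truth, so every stage is testable
and the published summary statistics are recoverable end to end.

## The analysis

**Wingstroke segmentation.** The vertical force F_z is band-passed with a
zero-phase Chebyshev type-II filter (5–35 Hz for optomotor bouts, 4th-order
10–40 Hz for stimulation sessions) and the instantaneous phase φ(t) is taken
from the analytic signal (Hilbert transform).  Negative-to-positive zero
crossings of φ delimit wingstrokes; spike times are expressed to 0.1 ms
relative to each stroke's t = 0.

**Correlational experiment.** For visually induced pitch-up and pitch-down
turns, per-stroke statistics — the interval t_DVM − t_DLM from the DLM spike
to the first same-side DVM spike, its phase-normalized form, the wingbeat
frequency, and per-individual centered mean torques — are compared between
conditions with two-sided paired t-tests.

**Causal (stimulation) experiment.** Electrical stimulation evokes DLM spikes
at controlled delays (4–40 ms) after detected DVM spikes; natural spikes
falling in the motor-unit refractory period after an evoked spike are
overwritten.  A trial is included only if both DLMs show a muscle action
potential within 5 ms of the stimulus and no earlier spike in that
wingstroke.  Torques are re-referenced from the load-cell frame to the
animal's center of mass, estimated by bounded linear least squares on
quiescent data (τ = r × F).

**Feature extraction.**  Pitch torque of the n valid stimulation wingstrokes
is linearly interpolated to m = 300 samples, assembled into T (n × m), and
paired with the evoked DLM phase vector Y (n × 1).  Canonical correlation
analysis (k = 1) on the z-scored pair T̂, Ŷ yields weights, scores
(T̂·T_weights) and loadings; rank-1 reconstructions

    T̂_recon = scores · T_loadings

are un-z-scored to mN m and converted to angular impulse and effective pitch
velocity change per stroke:

    J  = ∫[t0,t1] τ_x dt          (trapezoidal)
    Δω = J / I_yy,   I_yy = 266.7 g mm² = 2.667·10⁻⁷ kg m²

A linear mixed-effects model (random intercept per individual) tests the
slope of J versus evoked DLM phase.

## Worked example

```python
from tetherpitch import RunConfig, run_correlational

rep = run_correlational(RunConfig(experiment="correlational",
                                  n_individuals=3,
                                  strokes_per_condition=200, seed=42))
for m in ("interval_ms", "wingbeat_freq"):
    s = rep.stats[m]
    print(f"{m}: pitch_up={s['mean_pitch_up']:.2f}  pitch_down={s['mean_pitch_down']:.2f}  "
          f"t={s['statistic']:.2f}  p={s['pvalue']:.2e}  (n_pairs={s['n_pairs']})")
```

prints

```
interval_ms: pitch_up=24.51  pitch_down=17.63  t=76.88  p=7.06e-09  (n_pairs=6)
wingbeat_freq: pitch_up=18.61  pitch_down=23.00  t=-23.34  p=1.83e-03  (n_pairs=3)
```

Three virtual moths flap ~200 strokes per condition; the recovered DLM–DVM
interval is ~24.5 ms when pitching up versus ~17.6 ms when pitching down
(longer delay to the upstroke muscle → nose-up), wingbeat frequency drops in
pitch-up, and the paired tests across same-side muscle pairs (n = 6) and
individuals (n = 3) separate the conditions.  The same `Report` carries the
per-stroke tables, the phase-normalized comparison and the centered-torque
separation (`rep.stats["torque_separation"]`).

A command-line interface wraps the same library:

```
tetherpitch synth --condition pitch_up --duration 20 --seed 7 --out bout.h5
tetherpitch run-correlational --seed 7 --n-individuals 9 --out report/
tetherpitch run-stim --seed 7 --n-individuals 5 --out report_stim/
```

## Layout

| module | contents |
| --- | --- |
| `tetherpitch.config` | `SynthConfig` with per-condition presets |
| `tetherpitch.synth` | ground-truth generator (flight bouts, stimulation sessions, quiescent segments) |
| `tetherpitch.preprocess` | Butterworth low-pass, `COMEstimator`, COM re-referencing |
| `tetherpitch.wingstrokes` | Chebyshev band-pass, Hilbert phase, segmentation, spike-phase assignment, torque centering |
| `tetherpitch.spikes` | `SpikeDetector` (threshold crossing), evoked-MAP validation |
| `tetherpitch.turns` | interval/phase/frequency summaries and paired tests |
| `tetherpitch.features` | torque matrix, `CCATimingFeatures` (k = 1 CCA), reconstruction, J, Δω, mixed-model slope test |
| `tetherpitch.pipeline` | `run_correlational`, `run_stimulation`, reports |
| `tetherpitch.cli` | `tetherpitch` console script |

See `docs/methods.md` for the generative model, parameter choices and known
limitations.
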