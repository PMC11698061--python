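"""Synthesis configuration for tethered-flight recordings.

A :class:`SynthConfig` bundles everything the generator needs to emulate one
experimental condition: wingbeat kinematics, muscle spike timing statistics,
the within-stroke pitch-torque structure and its coupling to downstroke-muscle
(DLM) timing, EMG waveform/noise levels, and the closed-loop stimulation
protocol.  Condition presets carry the summary statistics of the tethered
hawkmoth dataset this package models (pitch-up vs pitch-down optomotor turns,
and the DLM stimulation sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

CONDITIONS = ("pitch_up", "pitch_down", "stim_session", "quiescent")

#: Power-muscle channel names: left/right dorsolongitudinal (downstroke) and
#: dorsoventral (upstroke) muscles.
MUSCLES = ("LDLM", "RDLM", "LDVM", "RDVM")


@dataclass
class SynthConfig:
    """Parameters of the synthetic tethered-flight generator.

    Units are stated per field.  Defaults describe the pitch-up optomotor
    condition; use the :meth:`pitch_up` / :meth:`pitch_down` /
    :meth:`stim_session` / :meth:`quiescent` presets for the named conditions.
    """

    sampling_rate: float = 10_000.0  #: Hz
    condition: str = "pitch_up"

    # --- wingbeat kinematics -------------------------------------------------
    wingbeat_freq_mean: float = 18.6  #: Hz, per-stroke mean
    wingbeat_freq_jitter_sd: float = 0.5  #: Hz, stationary SD of per-stroke jitter
    wingbeat_freq_drift: float = 0.99  #: AR(1) stroke-to-stroke correlation of the jitter
    freq_band: Tuple[float, float] = (15.0, 27.0)  #: Hz, admissible wingbeat range

    # --- muscle spike timing -------------------------------------------------
    dlm_phase_mean: float = 0.327  #: fraction of wingstroke
    dlm_phase_jitter_sd: float = 0.05  #: fraction
    dlm_dvm_interval_mean: float = 24.5  #: ms, first same-side DVM after DLM
    dlm_dvm_interval_jitter_sd: float = 2.0  #: ms
    lr_jitter_sd: float = 0.3  #: ms, independent left/right timing jitter

    # --- pitch torque structure ---------------------------------------------
    torque_osc_cycles: int = 4  #: oscillation cycles per wingstroke (3 or 4)
    torque_amplitude: float = 1.0  #: mN m, base oscillation amplitude
    pitch_offset: float = 0.0  #: mN m, condition mean pitch torque
    coupling_gain: float = 1.5  #: rad of oscillation phase advance per unit DLM-phase deviation
    transient_gain: float = 15.0  #: mN m per unit DLM-phase deviation (additive transient)
    coupled_variance_fraction_target: Optional[float] = None  #: calibrate uncoupled scale
    uncoupled_amp: float = 0.3  #: mN m, stroke-to-stroke uncoupled harmonic variability

    # --- signal levels -------------------------------------------------------
    fz_amplitude: float = 15.0  #: mN, vertical-force oscillation amplitude
    emg_kernel_duration: float = 2.0  #: ms, biphasic spike waveform support
    emg_kernel_amplitude: float = 1.0  #: V
    emg_noise_sd: float = 0.05  #: V
    ft_noise_sd: float = 0.02  #: mN m on torques; 10x on forces (mN)

    # --- stimulation protocol ------------------------------------------------
    stim_delay_range: Tuple[float, float] = (4.0, 40.0)  #: ms after DVM detection
    stim_min_separation: float = 4.0  #: s between stimuli (anti-entrainment)
    evoked_latency: float = 4.0  #: ms from stimulus to evoked DLM spike
    refractory: float = 20.0  #: ms, motor-unit refractory (natural-spike overwrite)
    stim_trigger_muscle: str = "LDVM"

    # --- quiescent / calibration --------------------------------------------
    com_true_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)  #: mm, sensor -> COM
    body_weight: float = 19.6  #: mN, quiescent load (≈2 g moth)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        lo, hi = self.freq_band
        if self.condition != "quiescent" and not (lo <= self.wingbeat_freq_mean <= hi):
            raise ValueError(
                f"wingbeat_freq_mean {self.wingbeat_freq_mean} Hz outside the "
                f"segmentation band {self.freq_band}"
            )
        if not (0.20 <= self.dlm_phase_mean <= 0.55):
            raise ValueError("dlm_phase_mean outside the natural DLM range [0.20, 0.55]")
        dlo, dhi = self.stim_delay_range
        if dlo < 0 or dhi <= dlo:
            raise ValueError("stim_delay_range must satisfy 0 <= low < high")
        if self.evoked_latency <= 0:
            raise ValueError("evoked_latency must be positive")

    # ------------------------------------------------------------------ presets
    @classmethod
    def pitch_up(cls, **overrides) -> "SynthConfig":
        """Pitch-up optomotor condition (lower wingbeat frequency, long DLM-DVM interval)."""
        base = dict(
            condition="pitch_up",
            wingbeat_freq_mean=18.6,
            dlm_dvm_interval_mean=24.5,
            pitch_offset=-0.4,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def pitch_down(cls, **overrides) -> "SynthConfig":
        """Pitch-down optomotor condition (higher wingbeat frequency, short interval)."""
        base = dict(
            condition="pitch_down",
            wingbeat_freq_mean=22.9,
            dlm_dvm_interval_mean=17.6,
            pitch_offset=0.4,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def stim_session(cls, **overrides) -> "SynthConfig":
        """DLM stimulation session (10-40 Hz segmentation variant, coupled torque)."""
        base = dict(
            condition="stim_session",
            wingbeat_freq_mean=20.0,
            dlm_dvm_interval_mean=20.0,
            freq_band=(10.0, 40.0),
            coupled_variance_fraction_target=0.355,
            com_true_offset=(1.5, -2.0, 0.5),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def quiescent(cls, **overrides) -> "SynthConfig":
        """Quiescent tethered moth: constant weight plus noise, no spikes."""
        base = dict(condition="quiescent", com_true_offset=(1.5, -2.0, 0.5))
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=int(seed))

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)
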