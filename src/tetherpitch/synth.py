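"""Synthetic tethered-flight recordings with known ground truth.

Every downstream stage of the pipeline is testable against recordings whose
wingstroke boundaries, spike times and torque structure are known exactly.
The generator emulates, per condition:

* a wingbeat-periodic vertical force whose Hilbert-phase ascending zero
  crossings mark the true wingstroke boundaries (``Fz = A cos(2*pi*phase)``);
* muscle-specific spike timing — one DLM and one first DVM spike per stroke
  per side, with condition-dependent DLM-DVM intervals;
* a 3- or 4-cycle within-stroke pitch-torque oscillation whose phase advances
  linearly as the stroke's first DLM spike occurs earlier, plus an additive
  transient scaled by the same timing deviation (early evoked spikes push
  pitch torque positive immediately and carry net angular impulse);
* closed-loop stimulation sessions: delay-triggered stimuli after DVM spikes,
  evoked DLM spikes at a fixed latency, and refractory "motor overwrite" of
  natural spikes;
* quiescent segments (constant weight vector) for COM calibration.

All randomness flows from ``config.seed``; generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import MUSCLES, SynthConfig
from .preprocess import ForceTorqueSeries, TetherRecording, moment_mNm

_N_HARMONICS = 4  #: uncoupled stroke-to-stroke variability harmonics
_PHI_GRID = 300  #: phase grid used for coupled-variance calibration


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spike_times: Dict[str, np.ndarray]  #: s, per muscle, sorted
    evoked_flags: Dict[str, np.ndarray]  #: bool per spike
    wingstroke_boundaries: np.ndarray  #: s, strictly increasing
    com_offset_mm: np.ndarray
    coupling_gain: float
    transient_gain: float = 0.0
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))  #: s
    stim_delays_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    dlm_phase_deviation: np.ndarray = field(default_factory=lambda: np.empty(0))  #: per stroke
    evoked_first_strokes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    coupled_variance_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        self.wingstroke_boundaries = np.asarray(self.wingstroke_boundaries, dtype=float)
        if np.any(np.diff(self.wingstroke_boundaries) <= 0):
            raise ValueError("wingstroke boundaries must be strictly increasing")
        self.com_offset_mm = np.asarray(self.com_offset_mm, dtype=float).reshape(3)


# ----------------------------------------------------------------- waveform pieces
def transient_shape(phi: np.ndarray) -> np.ndarray:
    """Unit transient waveform w(phi) multiplying the DLM-phase deviation.

    Early negative lobe (phi < 0.25) followed by a broader positive lobe, so
    an *early* spike (negative deviation) pushes torque positive at the start
    of the stroke while the net signed area gives angular impulse a positive
    slope versus spike phase.
    """
    phi = np.asarray(phi, dtype=float)
    w = np.zeros_like(phi)
    m1 = phi < 0.25
    w[m1] = -np.sin(np.pi * phi[m1] / 0.25)
    m2 = (phi >= 0.30) & (phi < 0.95)
    w[m2] = 0.5 * np.sin(np.pi * (phi[m2] - 0.30) / 0.65)
    return w


def emg_kernel(cfg: SynthConfig) -> np.ndarray:
    """Biphasic spike waveform: one sine cycle over the kernel duration."""
    n = max(4, int(round(cfg.emg_kernel_duration * 1e-3 * cfg.sampling_rate)))
    return cfg.emg_kernel_amplitude * np.sin(2 * np.pi * np.arange(n) / n)


def _coupled_rows(cfg: SynthConfig, delta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Noiseless DLM-coupled pitch-torque rows evaluated on a phase grid."""
    k = cfg.torque_osc_cycles
    base = np.sin(2 * np.pi * k * phi)[None, :]
    shifted = np.sin(2 * np.pi * k * phi[None, :] - cfg.coupling_gain * delta[:, None])
    return cfg.torque_amplitude * (shifted - base) + (
        cfg.transient_gain * delta[:, None] * transient_shape(phi)[None, :]
    )


# ----------------------------------------------------------------- planning helpers
def _plan_strokes(cfg: SynthConfig, duration: float, rng: np.random.Generator):
    """Stroke boundaries covering duration (plus margin beyond the record).

    Wingbeat frequency drifts smoothly from stroke to stroke: a stationary
    AR(1) jitter process (correlation ``cfg.wingbeat_freq_drift``) around the
    condition mean, as tethered moths modulate frequency over seconds rather
    than cycle to cycle.  With jitter SD 0 the bout is exactly periodic.
    """
    lo, hi = cfg.freq_band
    rho = cfg.wingbeat_freq_drift
    margin = duration + 2.0 / cfg.wingbeat_freq_mean
    n_max = int(np.ceil(margin * hi)) + 4
    eps = rng.normal(0.0, 1.0, n_max)
    ar = np.empty(n_max)
    ar[0] = eps[0]
    innov = np.sqrt(1.0 - rho**2)
    for k in range(1, n_max):
        ar[k] = rho * ar[k - 1] + innov * eps[k]
    freqs = np.clip(cfg.wingbeat_freq_mean + cfg.wingbeat_freq_jitter_sd * ar, lo, hi)
    bounds = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
    stop = int(np.searchsorted(bounds, margin)) + 1
    return bounds[: max(stop, 3)]


def _plan_natural_spikes(cfg: SynthConfig, bounds: np.ndarray, duration: float, rng):
    """Natural DLM/DVM spike times per muscle for complete in-record strokes."""
    n_rec = int(np.searchsorted(bounds, duration + 1e-9) - 1)
    n_rec = max(n_rec, 0)
    t0 = bounds[:n_rec]
    periods = np.diff(bounds)[:n_rec]
    dlm_phase = np.clip(
        rng.normal(cfg.dlm_phase_mean, cfg.dlm_phase_jitter_sd, n_rec), 0.02, 0.95
    )
    spikes: Dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        jit = rng.normal(0.0, cfg.lr_jitter_sd * 1e-3, n_rec)
        t_dlm = t0 + dlm_phase * periods + jit
        interval = rng.normal(
            cfg.dlm_dvm_interval_mean, cfg.dlm_dvm_interval_jitter_sd, n_rec
        )
        t_dvm = t_dlm + interval * 1e-3
        spikes[f"{side}DLM"] = t_dlm
        spikes[f"{side}DVM"] = t_dvm
    return n_rec, dlm_phase, spikes


def _first_dlm_deviation(
    cfg: SynthConfig, bounds: np.ndarray, n_rec: int, trains: Dict[str, np.ndarray]
) -> np.ndarray:
    """Per-stroke deviation of the first DLM spike phase from the natural mean."""
    t0 = bounds[:n_rec]
    t1 = bounds[1 : n_rec + 1]
    delta = np.zeros(n_rec)
    for k in range(n_rec):
        phases = []
        for side in ("L", "R"):
            times = trains[f"{side}DLM"]
            sel = times[(times >= t0[k]) & (times < t1[k])]
            if sel.size:
                phases.append((sel[0] - t0[k]) / (t1[k] - t0[k]))
        if phases:
            delta[k] = float(np.mean(phases)) - cfg.dlm_phase_mean
    return delta


# ----------------------------------------------------------------- signal assembly
def _render_signals(
    cfg: SynthConfig,
    duration: float,
    bounds: np.ndarray,
    delta: np.ndarray,
    harm: Tuple[np.ndarray, np.ndarray],
    spikes: Dict[str, np.ndarray],
    rng: np.random.Generator,
) -> Tuple[Dict[str, np.ndarray], ForceTorqueSeries]:
    fs = cfg.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # monotone-cubic stroke coordinate: instantaneous frequency varies
    # smoothly across boundaries (a step-FM Fz would distort the band-passed
    # Hilbert phase); with zero jitter this reduces to a linear ramp
    from scipy.interpolate import PchipInterpolator

    u = PchipInterpolator(bounds, np.arange(len(bounds), dtype=float))(t)
    del t
    phi = u - np.floor(u)
    idx = np.minimum(np.floor(u).astype(np.int32), len(bounds) - 2)

    n_strokes_all = len(bounds) - 1
    delta_all = np.zeros(n_strokes_all)
    delta_all[: len(delta)] = delta
    d = delta_all[idx]

    kcyc = cfg.torque_osc_cycles
    tau_x = cfg.torque_amplitude * np.sin(2 * np.pi * kcyc * phi - cfg.coupling_gain * d)
    tau_x += cfg.transient_gain * d * transient_shape(phi)
    a, b = harm
    for h in range(_N_HARMONICS):
        tau_x += a[idx, h] * np.sin(2 * np.pi * (h + 1) * phi)
        tau_x += b[idx, h] * np.cos(2 * np.pi * (h + 1) * phi)
    tau_x += cfg.pitch_offset

    force_noise = cfg.ft_noise_sd * 10.0
    data = np.empty((n, 6))
    data[:, 0] = rng.normal(0.0, force_noise, n)
    data[:, 1] = rng.normal(0.0, force_noise, n)
    data[:, 2] = cfg.fz_amplitude * np.cos(2 * np.pi * u) + rng.normal(0.0, force_noise, n)
    data[:, 3] = tau_x
    data[:, 4] = 0.3 * np.sin(2 * np.pi * u + 1.0)
    data[:, 5] = 0.2 * np.sin(2 * np.pi * u + 2.5)
    # torques above are about the COM; report at the sensor reference point
    rx, ry, rz = (float(v) for v in cfg.com_true_offset)
    fx, fy, fz = data[:, 0], data[:, 1], data[:, 2]
    data[:, 3] += 1e-3 * (ry * fz - rz * fy)
    data[:, 4] += 1e-3 * (rz * fx - rx * fz)
    data[:, 5] += 1e-3 * (rx * fy - ry * fx)
    for j in (3, 4, 5):
        data[:, j] += rng.normal(0.0, cfg.ft_noise_sd, n)
    del u, phi, idx, d, tau_x

    kernel = emg_kernel(cfg).astype(np.float32)
    emg: Dict[str, np.ndarray] = {}
    for muscle in MUSCLES:
        # float32 keeps long sessions in memory; EMG dynamic range is tiny
        ch = rng.standard_normal(n, dtype=np.float32)
        ch *= np.float32(cfg.emg_noise_sd)
        for ts in spikes.get(muscle, ()):
            i = int(round(ts * fs))
            if 0 <= i < n:
                seg = kernel[: n - i]
                ch[i : i + len(seg)] += seg
        emg[muscle] = ch
    return emg, ForceTorqueSeries(fs, data, frame="sensor")


def _draw_harmonics(cfg: SynthConfig, n_strokes: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    scale = cfg.uncoupled_amp / (np.arange(_N_HARMONICS) + 1.0)
    a = rng.normal(0.0, 1.0, (n_strokes, _N_HARMONICS)) * scale
    b = rng.normal(0.0, 1.0, (n_strokes, _N_HARMONICS)) * scale
    return a, b


# ================================================================= public generators
def generate_flight_bout(
    cfg: SynthConfig, duration: float
) -> Tuple[TetherRecording, GroundTruth]:
    """Unstimulated flapping bout for the optomotor (correlational) experiment."""
    if cfg.condition not in ("pitch_up", "pitch_down"):
        raise ValueError("flight bouts require condition pitch_up or pitch_down")
    if duration < 3.0 / cfg.wingbeat_freq_mean:
        raise ValueError("duration must cover at least 3 wingbeat periods")
    rng = np.random.default_rng(cfg.seed)
    bounds = _plan_strokes(cfg, duration, rng)
    n_rec, dlm_phase, spikes = _plan_natural_spikes(cfg, bounds, duration, rng)
    spikes = {m: ts[ts < duration - 1e-9] for m, ts in spikes.items()}
    delta = _first_dlm_deviation(cfg, bounds, n_rec, spikes)
    harm = _draw_harmonics(cfg, len(bounds) - 1, rng)
    emg, ft = _render_signals(cfg, duration, bounds, delta, harm, spikes, rng)

    rec = TetherRecording(
        fs=cfg.sampling_rate,
        emg=emg,
        ft=ft,
        meta={"condition": cfg.condition, "seed": cfg.seed},
    )
    gt = GroundTruth(
        spike_times={m: ts.copy() for m, ts in spikes.items()},
        evoked_flags={m: np.zeros(len(ts), dtype=bool) for m, ts in spikes.items()},
        wingstroke_boundaries=bounds[: n_rec + 1],
        com_offset_mm=np.asarray(cfg.com_true_offset),
        coupling_gain=cfg.coupling_gain,
        transient_gain=cfg.transient_gain,
        dlm_phase_deviation=delta,
    )
    return rec, gt


def generate_stimulation_session(
    cfg: SynthConfig, n_stimuli: int, duration: Optional[float] = None
) -> Tuple[TetherRecording, GroundTruth]:
    """Closed-loop DLM stimulation session.

    Stimuli follow detected DVM spikes by a uniform random delay from
    ``cfg.stim_delay_range`` and are separated by at least
    ``cfg.stim_min_separation``.  Both DLMs receive an evoked spike exactly
    ``cfg.evoked_latency`` after each stimulus; natural DLM spikes scheduled
    within the refractory period after an evoked spike are suppressed
    ("motor overwrite").  When ``cfg.coupled_variance_fraction_target`` is
    set, the uncoupled stroke-to-stroke torque variability is scaled once so
    the DLM-coupled component accounts for that fraction of the variance of
    the (noiseless) stimulated-stroke torque matrix.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    needed = 1.0 + n_stimuli * cfg.stim_min_separation + 1.0
    if duration is None:
        duration = needed
    elif duration < needed:
        raise ValueError(
            f"{n_stimuli} stimuli at >= {cfg.stim_min_separation} s separation "
            f"do not fit in {duration} s"
        )
    rng = np.random.default_rng(cfg.seed)
    bounds = _plan_strokes(cfg, duration, rng)
    n_rec, dlm_phase, natural = _plan_natural_spikes(cfg, bounds, duration, rng)
    natural = {m: ts[ts < duration - 1e-9] for m, ts in natural.items()}

    # -- closed-loop stimulus scheduling -------------------------------------
    trigger = np.sort(natural[cfg.stim_trigger_muscle])
    lo_ms, hi_ms = cfg.stim_delay_range
    stim_times: List[float] = []
    delays: List[float] = []
    t_next = 1.0
    for _ in range(n_stimuli):
        cand = trigger[trigger >= t_next]
        if not cand.size:
            break
        delay = rng.uniform(lo_ms, hi_ms)
        stim = float(cand[0]) + delay * 1e-3
        if stim >= duration - 0.5:
            break
        stim_times.append(stim)
        delays.append(delay)
        t_next = stim + cfg.stim_min_separation
    stim_arr = np.asarray(stim_times)
    evoked_times = stim_arr + cfg.evoked_latency * 1e-3

    # -- motor overwrite: merge evoked spikes, suppress refractory naturals --
    trains: Dict[str, np.ndarray] = {}
    flags: Dict[str, np.ndarray] = {}
    refr = cfg.refractory * 1e-3
    for side in ("L", "R"):
        key = f"{side}DLM"
        nat = natural[key]
        keep = np.ones(len(nat), dtype=bool)
        for ev in evoked_times:
            keep &= ~((nat >= ev) & (nat <= ev + refr))
        times = np.concatenate([nat[keep], evoked_times])
        lab = np.concatenate([np.zeros(keep.sum(), bool), np.ones(len(evoked_times), bool)])
        order = np.argsort(times)
        trains[key] = times[order]
        flags[key] = lab[order]
    for side in ("L", "R"):
        key = f"{side}DVM"
        trains[key] = natural[key]
        flags[key] = np.zeros(len(natural[key]), dtype=bool)

    delta = _first_dlm_deviation(cfg, bounds, n_rec, trains)

    # -- strokes included by the evoked-MAP rule ------------------------------
    # Operational definition (what a detector can know): for both sides the
    # first DLM spike of the stroke containing the evoked response falls
    # within the 5 ms window directly following the stimulus.  Near-tie
    # natural spikes landing inside the window count as evoked.
    window = 5e-3
    t0s, t1s = bounds[:n_rec], bounds[1 : n_rec + 1]
    evoked_first = []
    for stim, ev in zip(stim_arr, evoked_times):
        k = int(np.searchsorted(bounds, ev)) - 1
        if not (0 <= k < n_rec):
            continue
        ok = True
        for side in ("L", "R"):
            times = trains[f"{side}DLM"]
            m = (times >= t0s[k]) & (times < t1s[k])
            if not m.any():
                ok = False
                break
            first = times[np.flatnonzero(m)[0]]
            if not (stim < first <= stim + window):
                ok = False
                break
        if ok:
            evoked_first.append(k)
    evoked_first = np.unique(np.asarray(evoked_first, dtype=int))

    # -- calibrate uncoupled variability against the coupled component --------
    harm = _draw_harmonics(cfg, len(bounds) - 1, rng)
    realized = None
    if cfg.coupled_variance_fraction_target is not None and evoked_first.size >= 2:
        phi = np.arange(_PHI_GRID) / _PHI_GRID
        C = _coupled_rows(cfg, delta[evoked_first], phi)
        C = C - C.mean(axis=0)
        a, b = harm
        U = np.zeros((evoked_first.size, _PHI_GRID))
        for h in range(_N_HARMONICS):
            U += a[evoked_first, h, None] * np.sin(2 * np.pi * (h + 1) * phi)[None, :]
            U += b[evoked_first, h, None] * np.cos(2 * np.pi * (h + 1) * phi)[None, :]
        U = U - U.mean(axis=0)
        cc = np.sum(C**2, axis=0)
        uu = np.sum(U**2, axis=0) + 1e-30
        target = cfg.coupled_variance_fraction_target

        def gap(s: float) -> float:
            return float(np.mean(cc / (cc + s**2 * uu))) - target

        if gap(1e-6) <= 0:
            raise ValueError("coupled component too weak to reach the target fraction")
        scale = brentq(gap, 1e-6, 1e6)
        harm = (a * scale, b * scale)
        realized = float(np.mean(cc / (cc + scale**2 * uu)))

    emg, ft = _render_signals(cfg, duration, bounds, delta, harm, trains, rng)
    rec = TetherRecording(
        fs=cfg.sampling_rate,
        emg=emg,
        ft=ft,
        stim_marks=stim_arr,
        meta={"condition": cfg.condition, "seed": cfg.seed},
    )
    gt = GroundTruth(
        spike_times=trains,
        evoked_flags=flags,
        wingstroke_boundaries=bounds[: n_rec + 1],
        com_offset_mm=np.asarray(cfg.com_true_offset),
        coupling_gain=cfg.coupling_gain,
        transient_gain=cfg.transient_gain,
        stim_times=stim_arr,
        stim_delays_ms=np.asarray(delays),
        dlm_phase_deviation=delta,
        evoked_first_strokes=evoked_first,
        coupled_variance_fraction=realized,
    )
    return rec, gt


def generate_quiescent_segment(
    cfg: SynthConfig, duration: float
) -> Tuple[TetherRecording, GroundTruth]:
    """Quiescent tethered moth: constant weight vector plus noise, no spikes.

    Torques at the sensor are ``r x F`` for the configured true COM offset,
    plus noise — the calibration target for :func:`~tetherpitch.preprocess.estimate_com`.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(round(duration * fs))
    force_noise = cfg.ft_noise_sd * 10.0
    data = np.empty((n, 6))
    weight = np.array([0.0, 0.0, -cfg.body_weight])
    data[:, :3] = weight[None, :] + rng.normal(0.0, force_noise, (n, 3))
    r = np.asarray(cfg.com_true_offset, dtype=float)
    data[:, 3:] = moment_mNm(np.broadcast_to(r, (n, 3)), data[:, :3])
    data[:, 3:] += rng.normal(0.0, cfg.ft_noise_sd, (n, 3))
    emg = {m: rng.normal(0.0, cfg.emg_noise_sd, n) for m in MUSCLES}
    rec = TetherRecording(
        fs=fs,
        emg=emg,
        ft=ForceTorqueSeries(fs, data, frame="sensor"),
        meta={"condition": "quiescent", "seed": cfg.seed},
    )
    gt = GroundTruth(
        spike_times={m: np.empty(0) for m in MUSCLES},
        evoked_flags={m: np.empty(0, dtype=bool) for m in MUSCLES},
        wingstroke_boundaries=np.array([0.0, duration]),
        com_offset_mm=r,
        coupling_gain=cfg.coupling_gain,
        transient_gain=cfg.transient_gain,
    )
    return rec, gt
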