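"""EMG spike detection and stimulation-trial validation.

Each flight power muscle is effectively a single motor unit, so spike sorting
reduces to threshold-crossing detection on the rectified EMG voltage.  A
muscle action potential (MAP) is deemed *evoked* when it falls within a 5 ms
window directly following a stimulation mark; a stimulation trial is valid
only if both DLMs produced an evoked MAP and no natural DLM spike preceded it
within the stimulation wingstroke.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

EVOKED_WINDOW_MS = 5.0  #: post-stimulus window defining an evoked MAP

REJECTION_REASONS = (
    "no_evoked_left",
    "no_evoked_right",
    "prior_natural_spike",
    "outside_window",
    "unsegmented",
)


@dataclass
class SpikeTrain:
    """Spike times (s) of one muscle with natural/evoked/artifact labels."""

    muscle: str
    times: np.ndarray
    labels: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.labels is None:
            self.labels = np.full(self.times.shape, "natural", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def evoked_mask(self) -> np.ndarray:
        return self.labels == "evoked"


@dataclass
class StimulationTrial:
    """One stimulation event and its inclusion status."""

    stim_time: float  #: s
    delay_ms: Optional[float] = None  #: from the triggering DVM spike
    stroke_index: Optional[int] = None
    evoked_phase_left: Optional[float] = None  #: fraction of wingstroke
    evoked_phase_right: Optional[float] = None
    valid: bool = False
    reason: Optional[str] = None


class SpikeDetector(BaseEstimator):
    """Threshold-crossing spike detector on rectified EMG.

    Parameters
    ----------
    threshold : float, optional
        Absolute voltage threshold.  If None, :meth:`fit` sets it to
        ``threshold_factor`` times a robust noise SD (1.4826 x median absolute
        deviation of the channel).
    threshold_factor : float
        Multiplier on the robust noise SD, default 5.
    refractory_ms : float
        Dead time after each detection, default 2 ms (one spike waveform).
    max_rate : float
        Plausibility bound (Hz); a higher detected rate raises a warning that
        the threshold sits in the noise floor.

    Attributes
    ----------
    threshold_ : float
        The threshold in effect after :meth:`fit`.
    """

    def __init__(
        self,
        threshold: Optional[float] = None,
        threshold_factor: float = 5.0,
        refractory_ms: float = 2.0,
        max_rate: float = 100.0,
    ):
        self.threshold = threshold
        self.threshold_factor = threshold_factor
        self.refractory_ms = refractory_ms
        self.max_rate = max_rate

    def fit(self, X: np.ndarray, y=None) -> "SpikeDetector":
        x = np.asarray(X, dtype=float)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            mad = np.median(np.abs(x - np.median(x)))
            self.threshold_ = self.threshold_factor * 1.4826 * mad
        return self

    def predict(self, X: np.ndarray, fs: float = 10_000.0) -> np.ndarray:
        """Spike times (s): first suprathreshold sample of each crossing."""
        x = np.abs(np.asarray(X, dtype=float))
        thr = self.threshold_
        above = x >= thr
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        if above[0]:
            onsets = np.concatenate(([0], onsets))
        dead = self.refractory_ms * 1e-3 * fs
        kept: List[int] = []
        last = -np.inf
        for i in onsets:
            if i - last >= dead:
                kept.append(i)
                last = i
        times = np.asarray(kept, dtype=float) / fs
        n_sec = len(x) / fs
        if n_sec > 0 and len(times) / n_sec > self.max_rate:
            warnings.warn(
                f"detected rate {len(times) / n_sec:.0f} Hz exceeds plausibility "
                f"bound {self.max_rate} Hz; threshold may sit in the noise floor",
                stacklevel=2,
            )
        return times


def detect_spikes(
    emg: np.ndarray,
    fs: float,
    muscle: str = "",
    threshold: Optional[float] = None,
    threshold_factor: float = 5.0,
    refractory_ms: float = 2.0,
) -> SpikeTrain:
    """Detect spikes in one EMG channel via threshold crossing."""
    det = SpikeDetector(
        threshold=threshold,
        threshold_factor=threshold_factor,
        refractory_ms=refractory_ms,
    ).fit(emg)
    times = det.predict(emg, fs=fs)
    return SpikeTrain(muscle=muscle, times=times)


def label_evoked(
    train: SpikeTrain, stim_times: Sequence[float], window_ms: float = EVOKED_WINDOW_MS
) -> SpikeTrain:
    """Label spikes falling in ``(stim, stim + window]`` after any mark as evoked."""
    labels = train.labels.copy()
    stim = np.asarray(stim_times, dtype=float)
    w = window_ms * 1e-3
    for i, t in enumerate(train.times):
        if np.any((t > stim) & (t <= stim + w)):
            labels[i] = "evoked"
    return SpikeTrain(train.muscle, train.times.copy(), labels)


def _first_in_window(times: np.ndarray, lo: float, hi: float) -> Optional[float]:
    sel = times[(times > lo) & (times <= hi)]
    return float(sel[0]) if sel.size else None


def validate_evoked(
    trial: StimulationTrial,
    dlm_trains: Dict[str, SpikeTrain],
    stroke,
    window_ms: float = EVOKED_WINDOW_MS,
) -> StimulationTrial:
    """Apply the trial inclusion rules to one stimulation event.

    Valid iff (a) each DLM has a spike in ``(stim, stim + window]`` and
    (b) for each DLM, no earlier spike exists within the stimulation
    wingstroke.  ``stroke`` is the segmented wingstroke containing the evoked
    response (None marks the trial unsegmented).  Always returns a labeled
    trial; on rejection, ``reason`` is one of :data:`REJECTION_REASONS`.
    """
    stim = trial.stim_time
    w = window_ms * 1e-3
    if stroke is None:
        trial.valid = False
        trial.reason = "unsegmented"
        return trial

    phases = {}
    for side, key, reason in (("left", "LDLM", "no_evoked_left"), ("right", "RDLM", "no_evoked_right")):
        train = dlm_trains[key]
        t_evoked = _first_in_window(train.times, stim, stim + w)
        if t_evoked is None:
            near = _first_in_window(train.times, stim + w, stim + 2 * w)
            trial.valid = False
            trial.reason = "outside_window" if near is not None else reason
            return trial
        earlier = train.times[(train.times >= stroke.t0) & (train.times < t_evoked)]
        if earlier.size:
            trial.valid = False
            trial.reason = "prior_natural_spike"
            return trial
        phases[side] = (t_evoked - stroke.t0) / stroke.period

    trial.evoked_phase_left = phases["left"]
    trial.evoked_phase_right = phases["right"]
    trial.stroke_index = getattr(stroke, "index", trial.stroke_index)
    trial.valid = True
    trial.reason = None
    return trial


def spike_table(trains: Iterable[SpikeTrain]):
    """Long-format spike table (muscle, time_ms, evoked_flag) as a DataFrame."""
    import pandas as pd

    rows = []
    for tr in trains:
        for t, lab in zip(tr.times, tr.labels):
            rows.append({"muscle": tr.muscle, "time_ms": t * 1e3, "evoked_flag": lab == "evoked"})
    return pd.DataFrame(rows, columns=["muscle", "time_ms", "evoked_flag"])
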