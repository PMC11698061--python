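"""Force/torque calibration: low-pass filtering and center-of-mass referencing.

The load cell measures forces (mN) and torques (mN m) at the sensor reference
point.  Torques are re-referenced to the animal's center of mass (COM) by
``tau_COM = tau_sensor - r x F`` with the offset ``r`` (mm) estimated from a
quiescent segment by bounded linear least squares.  Sign convention: positive
pitch torque (tau_x) is nose-down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator, TransformerMixin

FT_CHANNELS = ("fx", "fy", "fz", "tau_x", "tau_y", "tau_z")

#: mm x mN -> mN m
_MOMENT_SCALE = 1e-3


def moment_mNm(r_mm: np.ndarray, force_mN: np.ndarray) -> np.ndarray:
    """Moment ``r x F`` of forces (mN) about an offset (mm), in mN m."""
    return np.cross(np.asarray(r_mm, dtype=float), np.asarray(force_mN, dtype=float)) * _MOMENT_SCALE


@dataclass
class ForceTorqueSeries:
    """Six-channel force/torque time series.

    ``data`` has shape (n, 6) ordered (Fx, Fy, Fz) in mN then
    (tau_x, tau_y, tau_z) in mN m.  ``frame`` records the torque reference
    point: ``"sensor"`` or ``"com"``.
    """

    fs: float
    data: np.ndarray
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("ForceTorqueSeries.data must have shape (n, 6)")
        if self.frame not in ("sensor", "com"):
            raise ValueError(f"unknown frame {self.frame!r}")

    # convenience views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def force(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def torque(self) -> np.ndarray:
        return self.data[:, 3:]

    @property
    def fz(self) -> np.ndarray:
        return self.data[:, 2]

    @property
    def tau_x(self) -> np.ndarray:
        return self.data[:, 3]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, FT_CHANNELS.index(name)]

    def copy(self) -> "ForceTorqueSeries":
        return ForceTorqueSeries(self.fs, self.data.copy(), self.frame)


@dataclass
class TetherRecording:
    """Synchronized raw multichannel tethered-flight recording."""

    fs: float
    emg: Dict[str, np.ndarray]  #: muscle id -> voltage series (V)
    ft: ForceTorqueSeries
    stim_marks: np.ndarray = field(default_factory=lambda: np.empty(0))  #: s
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stim_marks = np.asarray(self.stim_marks, dtype=float)
        n = self.ft.n_samples
        for muscle, v in self.emg.items():
            if len(v) != n:
                raise ValueError(f"EMG channel {muscle} length {len(v)} != {n}")
        span = n / self.fs
        if self.stim_marks.size and (
            self.stim_marks.min() < 0 or self.stim_marks.max() > span
        ):
            raise ValueError("stimulation marks outside the recorded span")

    @property
    def duration(self) -> float:
        return self.ft.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.ft.time


@dataclass
class COMEstimate:
    """Estimated sensor-to-COM offset (mm) with fit residual (mN m RMS)."""

    offset_mm: np.ndarray
    residual_rms: float
    bounds_mm: Tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        self.offset_mm = np.asarray(self.offset_mm, dtype=float).reshape(3)
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")


# --------------------------------------------------------------------------- filtering
def lowpass_ft(
    series: ForceTorqueSeries,
    cutoff: float = 1000.0,
    order: int = 8,
    in_place: bool = False,
) -> ForceTorqueSeries:
    """Zero-phase Butterworth low-pass of all six channels.

    An ``order``-th order Butterworth design applied forward-backward
    (magnitude response squared, no phase lag), cutoff in Hz.  With
    ``in_place`` the input buffer is overwritten column by column (bounded
    peak memory on long sessions).
    """
    nyq = series.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=series.fs, output="sos")
    if in_place:
        for j in range(6):
            series.data[:, j] = signal.sosfiltfilt(sos, series.data[:, j])
        return series
    out = signal.sosfiltfilt(sos, series.data, axis=0)
    return ForceTorqueSeries(series.fs, out, series.frame)


# --------------------------------------------------------------------------- COM
class COMEstimator(BaseEstimator, TransformerMixin):
    """Bounded least-squares estimate of the sensor-to-COM offset.

    The quiescent torque model is ``tau(t) = r x F(t)``, linear in the offset
    ``r`` (mm).  :meth:`fit` minimizes ``sum_t ||tau_t - r x F_t||^2`` subject
    to a box constraint; :meth:`transform` re-references torques to the COM.

    Parameters
    ----------
    bounds_mm : float or (lo, hi)
        Box bounds on each component of ``r``; a scalar ``b`` means ``±b``.

    Attributes
    ----------
    offset_mm_ : ndarray (3,)
        Estimated offset, mm.
    residual_rms_ : float
        RMS of the residual torque, mN m.
    """

    def __init__(self, bounds_mm: float | Tuple[float, float] = 10.0):
        self.bounds_mm = bounds_mm

    def _bounds(self) -> Tuple[float, float]:
        if np.isscalar(self.bounds_mm):
            b = float(self.bounds_mm)
            return (-b, b)
        lo, hi = self.bounds_mm
        return (float(lo), float(hi))

    def fit(self, X: ForceTorqueSeries, y=None) -> "COMEstimator":
        force = X.force
        torque = X.torque
        if X.n_samples < X.fs:
            raise ValueError("quiescent segment must be at least 1 s long")
        if np.allclose(force, 0.0):
            raise ValueError("degenerate all-zero force: COM offset unidentifiable")
        # tau = r x F  ->  A r = tau with per-sample blocks built from F
        n = force.shape[0]
        A = np.zeros((3 * n, 3))
        fx, fy, fz = force[:, 0], force[:, 1], force[:, 2]
        A[0::3, 1] = fz
        A[0::3, 2] = -fy
        A[1::3, 0] = -fz
        A[1::3, 2] = fx
        A[2::3, 0] = fy
        A[2::3, 1] = -fx
        A *= _MOMENT_SCALE
        b = torque.reshape(-1)
        lo, hi = self._bounds()
        res = lsq_linear(A, b, bounds=(lo, hi))
        self.offset_mm_ = res.x
        self.residual_rms_ = float(np.sqrt(np.mean((A @ res.x - b) ** 2)))
        return self

    def transform(self, X: ForceTorqueSeries) -> ForceTorqueSeries:
        return transform_to_com(X, self.estimate_)

    @property
    def estimate_(self) -> COMEstimate:
        return COMEstimate(self.offset_mm_, self.residual_rms_, self._bounds())


def estimate_com(
    quiescent: ForceTorqueSeries, bounds_mm: float | Tuple[float, float] = 10.0
) -> COMEstimate:
    """Estimate the sensor-to-COM offset from a quiescent segment."""
    return COMEstimator(bounds_mm=bounds_mm).fit(quiescent).estimate_


def transform_to_com(
    series: ForceTorqueSeries, com: COMEstimate, in_place: bool = False
) -> ForceTorqueSeries:
    """Re-reference torques to the COM: ``tau_COM = tau_sensor - r x F``.

    Forces are unchanged.  Rejects series already in the COM frame to prevent
    double transformation.
    """
    if series.frame == "com":
        raise ValueError("series already in COM frame (double transform)")
    out = series.data if in_place else series.data.copy()
    rx, ry, rz = com.offset_mm
    fx, fy, fz = out[:, 0], out[:, 1], out[:, 2]
    out[:, 3] -= _MOMENT_SCALE * (ry * fz - rz * fy)
    out[:, 4] -= _MOMENT_SCALE * (rz * fx - rx * fz)
    out[:, 5] -= _MOMENT_SCALE * (rx * fy - ry * fx)
    if in_place:
        series.frame = "com"
        return series
    return ForceTorqueSeries(series.fs, out, frame="com")
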