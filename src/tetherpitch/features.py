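"""Pitch-torque features covarying with evoked DLM phase, and their mechanics.

The within-stroke pitch torque of every valid stimulation wingstroke is
linearly interpolated to ``m = 300`` samples and assembled into an ``n x m``
matrix ``T``; the evoked DLM phase forms the ``n x 1`` timing vector ``Y``.
Canonical correlation analysis (k = 1) on the z-scored pair extracts the
torque feature maximally correlated with evoked timing.  Reconstructions
(scores times loadings, un-z-scored) are converted to angular impulse

    J = integral of tau_x dt over [t0, t1]   (trapezoidal)

and to the effective pitch angular velocity change over the wingstroke

    delta_omega = J / I_yy,

with the hawkmoth pitch moment of inertia I_yy = 266.7 g mm^2
(2.667e-7 kg m^2).  Positive pitch torque is nose-down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .wingstrokes import Wingstroke

#: Pitch moment of inertia for Manduca sexta, kg m^2 (266.7 g mm^2).
I_YY_KG_M2 = 2.667e-7

#: Torque rows are interpolated to this many samples per wingstroke.
M_SAMPLES = 300

_MNM_TO_NM = 1e-3


# ----------------------------------------------------------------- torque matrix
@dataclass
class TorqueMatrix:
    """Within-stroke pitch-torque matrix with z-scoring parameters.

    ``T`` is (n strokes, m) in mN m, rows linearly interpolated onto ``m``
    equispaced points over each stroke's ``[t0, t1)``.  ``orig_times`` keeps
    each stroke's original sample times for resampling reconstructions back.
    """

    T: np.ndarray
    col_mean: np.ndarray
    col_sd: np.ndarray
    strokes: List[Wingstroke]
    orig_times: List[np.ndarray]
    orig_values: List[np.ndarray]
    zero_variance: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n(self) -> int:
        return self.T.shape[0]

    @property
    def m(self) -> int:
        return self.T.shape[1]

    @property
    def zscored(self) -> np.ndarray:
        return (self.T - self.col_mean) / self.col_sd

    def zscore_rows(self, rows: np.ndarray) -> np.ndarray:
        return (rows - self.col_mean) / self.col_sd

    def unzscore_rows(self, rows_z: np.ndarray) -> np.ndarray:
        return rows_z * self.col_sd + self.col_mean


def build_torque_matrix(
    strokes: Sequence[Wingstroke],
    tau_x: np.ndarray,
    fs: float,
    m: int = M_SAMPLES,
) -> TorqueMatrix:
    """Assemble the n x m pitch-torque matrix for the given wingstrokes."""
    if len(strokes) < 2:
        raise ValueError("need at least 2 strokes to build a torque matrix")
    rows = np.empty((len(strokes), m))
    orig_t: List[np.ndarray] = []
    orig_v: List[np.ndarray] = []
    for i, s in enumerate(strokes):
        i0 = int(np.ceil(s.t0 * fs - 1e-9))
        i1 = min(int(np.ceil(s.t1 * fs - 1e-9)), len(tau_x))
        if i1 - i0 < 2:
            raise ValueError(f"stroke {s.index} shorter than 2 samples")
        t = np.arange(i0, i1) / fs
        v = np.asarray(tau_x[i0:i1], dtype=float)
        grid = s.t0 + (s.t1 - s.t0) * np.arange(m) / m
        rows[i] = np.interp(grid, t, v)
        orig_t.append(t)
        orig_v.append(v)
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    zero = sd == 0
    sd = np.where(zero, 1.0, sd)
    return TorqueMatrix(rows, mean, sd, list(strokes), orig_t, orig_v, zero)


# ----------------------------------------------------------------- CCA (k = 1)
class CCATimingFeatures(BaseEstimator):
    """Single-component CCA between torque waveforms and evoked DLM phase.

    For a univariate timing vector the canonical torque direction is the
    ridge-regularized regression direction ``w ~ (X'X + ridge*n*I)^-1 X'y``
    (normalized); scores are ``X w`` and loadings are the least-squares map
    from scores back to the z-scored matrix, so ``scores @ loadings`` is the
    rank-1 reconstruction.  The direction is oriented so scores correlate
    positively with the timing vector.

    Parameters
    ----------
    ridge : float
        Ridge added to the torque covariance (relative to its mean diagonal);
        stabilizes the rank-deficient n < m case.

    Attributes
    ----------
    x_weights_ : ndarray (m,)
        Unit-norm projection vector.
    x_loadings_ : ndarray (m,)
        Feature vector mapping scores to the z-scored matrix.
    scores_ : ndarray (n,)
        Latent values of the training matrix.
    canonical_correlation_ : float
        Pearson correlation between scores and the timing vector.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CCATimingFeatures":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        n, m = X.shape
        if n < 3:
            raise ValueError("CCA requires at least 3 strokes")
        if np.std(y) == 0:
            raise ValueError("timing vector is constant: canonical direction undefined")
        if n <= m:
            warnings.warn(
                f"n={n} <= m={m}: torque covariance is rank deficient; ridge "
                "regularization in effect (spurious perfect correlation risk)",
                stacklevel=2,
            )
        cov = X.T @ X
        lam = self.ridge * np.trace(cov) / m
        w = np.linalg.solve(cov + lam * np.eye(m), X.T @ y)
        w /= np.linalg.norm(w)
        scores = X @ w
        r = float(np.corrcoef(scores, y)[0, 1])
        if r < 0:
            w, scores, r = -w, -scores, -r
        denom = float(scores @ scores)
        loadings = (scores @ X) / denom
        self.x_weights_ = w
        self.x_loadings_ = loadings
        self.scores_ = scores
        self.canonical_correlation_ = r
        self.n_features_in_ = m
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.x_weights_

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.outer(np.asarray(scores, dtype=float).reshape(-1), self.x_loadings_)


def fit_cca(
    matrix: TorqueMatrix, evoked_phase: np.ndarray, ridge: float = 1e-6
) -> CCATimingFeatures:
    """Fit the k=1 CCA on the z-scored torque matrix and timing vector."""
    y = np.asarray(evoked_phase, dtype=float).reshape(-1)
    if len(y) != matrix.n:
        raise ValueError("timing vector length does not match the torque matrix")
    yz = (y - y.mean()) / y.std(ddof=1)
    Xz = matrix.zscored
    if matrix.zero_variance.any():
        Xz = Xz.copy()
        Xz[:, matrix.zero_variance] = 0.0
    return CCATimingFeatures(ridge=ridge).fit(Xz, yz)


def reconstruct(model: CCATimingFeatures, matrix: TorqueMatrix) -> np.ndarray:
    """Rank-1 reconstruction of the torque matrix in real units (mN m)."""
    recon_z = model.inverse_transform(model.transform(matrix.zscored))
    return matrix.unzscore_rows(recon_z)


def variance_explained(
    matrix: TorqueMatrix, recon: np.ndarray, scale: str = "zscore"
) -> float:
    """Fraction of torque-matrix variance captured by a reconstruction.

    ``1 - SS(residual) / SS(total)`` computed on the z-scored matrix by
    default (each interpolated sample contributes equally); ``scale="raw"``
    uses mN m units.
    """
    if recon.shape != matrix.T.shape:
        raise ValueError("reconstruction shape does not match the matrix")
    if scale == "zscore":
        X = matrix.zscored
        R = matrix.zscore_rows(recon)
    elif scale == "raw":
        X = matrix.T - matrix.col_mean
        R = recon - matrix.col_mean
    else:
        raise ValueError(f"unknown scale {scale!r}")
    ss_tot = float(np.sum(X**2))
    if ss_tot == 0:
        raise ValueError("torque matrix has zero total variance")
    return 1.0 - float(np.sum((X - R) ** 2)) / ss_tot


def resample_to_original(matrix: TorqueMatrix, recon: np.ndarray) -> List[np.ndarray]:
    """Resample reconstruction rows from m points back to each stroke's samples."""
    out = []
    for i, s in enumerate(matrix.strokes):
        grid = s.t0 + (s.t1 - s.t0) * np.arange(matrix.m) / matrix.m
        out.append(np.interp(matrix.orig_times[i], grid, recon[i]))
    return out


# ----------------------------------------------------------------- mechanics
def angular_impulse(
    trace_mNm: np.ndarray,
    t0: Optional[float] = None,
    t1: Optional[float] = None,
    times: Optional[np.ndarray] = None,
) -> float:
    """Angular impulse J (N m s): trapezoidal integral of pitch torque.

    Provide either sample ``times`` (s) or the interval ``[t0, t1]`` for a
    uniformly sampled trace.
    """
    trace = np.asarray(trace_mNm, dtype=float)
    if times is None:
        if t0 is None or t1 is None or t1 <= t0:
            raise ValueError("need times or a valid interval t1 > t0")
        times = np.linspace(t0, t1, len(trace))
    return float(np.trapezoid(trace * _MNM_TO_NM, np.asarray(times, dtype=float)))


def delta_omega(J: float) -> float:
    """Effective pitch angular velocity change (deg/s) from angular impulse."""
    return float(np.degrees(np.asarray(J) / I_YY_KG_M2))


def stroke_mechanics(
    matrix: TorqueMatrix, recon: np.ndarray, evoked_phase: np.ndarray
) -> "pd.DataFrame":
    """Per-stroke table of evoked phase, J and delta-omega.

    Columns carry the mechanics of both the raw torque and the feature
    reconstruction (resampled to each stroke's original sample count).
    """
    import pandas as pd

    recon_orig = resample_to_original(matrix, recon)
    rows = []
    for i, s in enumerate(matrix.strokes):
        t = matrix.orig_times[i]
        j_raw = angular_impulse(matrix.orig_values[i], times=t)
        j_feat = angular_impulse(recon_orig[i], times=t)
        rows.append(
            {
                "stroke": s.index,
                "evoked_phase": float(evoked_phase[i]),
                "J_raw": j_raw,
                "J_feature": j_feat,
                "delta_omega_raw": delta_omega(j_raw),
                "delta_omega_feature": delta_omega(j_feat),
                "tau_x_mean": float(np.mean(matrix.orig_values[i])),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- slope test
def slope_test(
    x: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> Dict[str, object]:
    """Random-intercept linear model slope of y on x across individuals.

    Fits ``y ~ x`` with a per-group random intercept; reports the fixed-slope
    estimate and its p-value.  On a singular or non-converging fit, falls
    back to per-group OLS slopes with a one-sample t-test (``flagged=True``).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("slope test needs at least 2 groups")
    for g in uniq:
        if np.sum(groups == g) < 3:
            raise ValueError("each group needs at least 3 points")
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
        slope = float(fit.params[1])
        p = float(fit.pvalues[1])
        if np.isfinite(slope) and np.isfinite(p):
            return {"slope": slope, "pvalue": p, "method": "mixedlm", "flagged": False}
    except (np.linalg.LinAlgError, ValueError):
        pass
    slopes = [np.polyfit(x[groups == g], y[groups == g], 1)[0] for g in uniq]
    t = stats.ttest_1samp(slopes, 0.0)
    return {
        "slope": float(np.mean(slopes)),
        "pvalue": float(t.pvalue),
        "method": "per_group_ols",
        "flagged": True,
    }
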