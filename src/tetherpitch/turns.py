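"""Condition-wise DLM-DVM timing, wingbeat frequency and torque separation.

The correlational analysis compares pitch-up and pitch-down optomotor turns:
per same-side DLM-DVM pair, the interval from the DLM spike (reference 0) to
the first DVM spike of each wingstroke, its phase-normalized variant
(interval / period), the wingbeat frequency, and the per-individual centered
mean torques — with two-sided paired t-tests across pairs or individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .wingstrokes import Wingstroke

SIDES = ("left", "right")
_METRICS = ("interval_ms", "dvm_phase", "wingbeat_freq")


def dlm_dvm_interval(stroke: Wingstroke, side: str) -> Tuple[float, float, bool]:
    """Interval (ms) and phase fraction from the DLM spike to the first DVM spike.

    Uses the stroke's quantized in-stroke spike times (0.1 ms).  Returns
    ``(interval_ms, phase_fraction, negative_flag)``; the flag marks a DVM
    spike preceding the DLM.  Raises if either muscle has no spike in the
    stroke.
    """
    prefix = side[0].upper()
    dlm = stroke.first_spike(f"{prefix}DLM")
    dvm = stroke.first_spike(f"{prefix}DVM")
    if dlm is None or dvm is None:
        raise ValueError(f"stroke {stroke.index} lacks a {side} DLM or DVM spike")
    interval = dvm[0] - dlm[0]
    return interval, interval / (stroke.period * 1e3), interval < 0


def interval_frame(stroke_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-stroke per-side interval table from a wingstroke table.

    Strokes lacking either spike on a side are excluded listwise for that
    side; the returned frame carries one row per (stroke, side) with the
    interval in ms and as a phase fraction.
    """
    rows = []
    for side in SIDES:
        p = side[0]
        sub = stroke_frame.dropna(subset=[f"{p}dlm_t_ms", f"{p}dvm_t_ms"])
        if not len(sub):
            continue
        interval = sub[f"{p}dvm_t_ms"] - sub[f"{p}dlm_t_ms"]
        rows.append(
            pd.DataFrame(
                {
                    "individual": sub["individual"],
                    "condition": sub["condition"],
                    "side": side,
                    "stroke": sub["stroke"],
                    "interval_ms": interval,
                    "dvm_phase": interval / (sub["period"] * 1e3),
                    "wingbeat_freq": sub["wingbeat_freq"],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["individual", "condition", "side", "stroke", *_METRICS]
        )
    return pd.concat(rows, ignore_index=True)


def condition_summaries(intervals: pd.DataFrame) -> pd.DataFrame:
    """Mean interval/phase/frequency per (individual, side, condition) pair."""
    g = intervals.groupby(["individual", "side", "condition"], as_index=False)
    out = g.agg(
        interval_ms=("interval_ms", "mean"),
        dvm_phase=("dvm_phase", "mean"),
        wingbeat_freq=("wingbeat_freq", "mean"),
        n_strokes=("stroke", "count"),
    )
    return out


def condition_compare(
    summaries: pd.DataFrame,
    metric: str,
    conditions: Tuple[str, str] = ("pitch_up", "pitch_down"),
    pair_on: Optional[Sequence[str]] = None,
) -> Dict[str, object]:
    """Two-sided paired t-test on per-pair condition means.

    Pairs are (individual, side) for timing metrics and individual for
    wingbeat frequency (frequency is a whole-animal quantity).  Returns the
    statistic, degrees of freedom, p-value and the paired means.
    """
    if metric not in summaries.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if pair_on is None:
        pair_on = ["individual"] if metric == "wingbeat_freq" else ["individual", "side"]
    wide = (
        summaries.groupby([*pair_on, "condition"])[metric]
        .mean()
        .unstack("condition")
        .dropna(subset=list(conditions))
    )
    if len(wide) < 2:
        raise ValueError("paired test undefined with fewer than 2 complete pairs")
    a, b = wide[conditions[0]].to_numpy(), wide[conditions[1]].to_numpy()
    d = a - b
    if np.std(d, ddof=1) == 0:
        # degenerate paired differences: identical values -> t=0, p=1
        t_stat = 0.0 if np.allclose(d.mean(), 0.0) else float(np.sign(d.mean()) * np.inf)
        p_val = 1.0 if t_stat == 0.0 else 0.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return {
        "metric": metric,
        "statistic": t_stat,
        "df": int(len(a) - 1),
        "pvalue": p_val,
        "n_pairs": int(len(a)),
        "mean_" + conditions[0]: float(a.mean()),
        "mean_" + conditions[1]: float(b.mean()),
        "pair_means": wide.reset_index(),
    }


def torque_separation(
    centered_frame: pd.DataFrame,
    conditions: Tuple[str, str] = ("pitch_up", "pitch_down"),
    axes: Sequence[str] = ("tau_x", "tau_y", "tau_z"),
) -> Dict[str, object]:
    """Per-individual per-condition centered torque means with paired tests.

    Expects the output of :func:`~tetherpitch.wingstrokes.centered_mean_torques`.
    Each axis gets a two-sided paired t-test across individuals on the
    condition means of the centered per-stroke torques.
    """
    per_ind = centered_frame.groupby(["individual", "condition"], as_index=False)[
        [f"{ax}_centered" for ax in axes]
    ].mean()
    counts = centered_frame.groupby(["individual", "condition"]).size()
    if (counts < 2).any():
        raise ValueError("each (individual, condition) cell needs at least 2 strokes")
    tests = {}
    for ax in axes:
        wide = per_ind.pivot(
            index="individual", columns="condition", values=f"{ax}_centered"
        ).dropna(subset=list(conditions))
        if len(wide) < 2:
            raise ValueError("paired test undefined with fewer than 2 individuals")
        res = stats.ttest_rel(wide[conditions[0]], wide[conditions[1]])
        tests[ax] = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
    return {"condition_means": per_ind, "tests": tests}
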