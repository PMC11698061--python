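"""End-to-end orchestration of the two experiments.

``run_correlational`` drives the optomotor-turn analysis: synthesize pitch-up
and pitch-down bouts per individual, low-pass the force/torque channels,
segment wingstrokes from the Hilbert phase of band-passed Fz (5-35 Hz
variant), detect spikes, and compare DLM-DVM interval, wingbeat frequency,
DVM phase and centered torques between conditions with paired t-tests.

``run_stimulation`` drives the causal experiment: synthesize closed-loop DLM
stimulation sessions, estimate the COM from a quiescent segment and
re-reference torques, segment with the 10-40 Hz variant, validate evoked
trials, and run the CCA feature chain (torque matrix, reconstruction,
variance accounting, angular impulse, delta-omega, cross-individual slope
test) independently per individual, as well as the equal-count decile summary
of stimulation phase.
"""

from __future__ import annotations

import gc
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess as pre
from . import spikes as spk
from . import turns
from . import wingstrokes as ws
from .config import MUSCLES, SynthConfig
from .synth import generate_flight_bout, generate_quiescent_segment, generate_stimulation_session

FILTER_VARIANTS = {
    "correlational_5_35": {"band": (5.0, 35.0), "order": 6},
    "stimulation_10_40": {"band": (10.0, 40.0), "order": 4},
}

_VARIANT_FOR_EXPERIMENT = {
    "correlational": "correlational_5_35",
    "stimulation": "stimulation_10_40",
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    experiment: str = "correlational"
    n_individuals: int = 9
    strokes_per_condition: int = 500  #: correlational bout length target
    n_stimuli: int = 480  #: stimulation events per individual
    seed: int = 0
    filter_variant: Optional[str] = None  #: defaults to the experiment's variant
    lowpass_cutoff: float = 1000.0
    spike_threshold_factor: float = 5.0
    individual_offset_sd: float = 0.2  #: mN m, per-individual baseline pitch torque
    condition_params: Dict[str, dict] = field(default_factory=dict)  #: preset overrides
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in _VARIANT_FOR_EXPERIMENT:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.filter_variant is None:
            self.filter_variant = _VARIANT_FOR_EXPERIMENT[self.experiment]
        if self.filter_variant != _VARIANT_FOR_EXPERIMENT[self.experiment]:
            raise ValueError(
                f"filter variant {self.filter_variant!r} does not match "
                f"experiment {self.experiment!r}"
            )


@dataclass
class Report:
    """Tables, test results and provenance of one run."""

    tables: Dict[str, pd.DataFrame]
    stats: Dict[str, object]
    counts: Dict[str, object]
    provenance: Dict[str, object]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-unit seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _process_recording(
    rec, variant: str, cutoff: float, threshold_factor: float, free_emg: bool = False
):
    """Shared chain: low-pass (in place), segment via Hilbert phase, detect,
    assign.  ``free_emg`` drops each EMG channel after detection to bound
    memory on long stimulation sessions."""
    v = FILTER_VARIANTS[variant]
    ft = pre.lowpass_ft(rec.ft, cutoff=cutoff, in_place=True)
    fz_bp = ws.bandpass_fz(ft.fz, rec.fs, band=v["band"], order=v["order"])
    phase = ws.hilbert_phase(fz_bp, rec.fs)
    del fz_bp
    strokes = ws.segment_wingstrokes(phase, ft, valid_freq_band=v["band"])
    del phase
    trains = {}
    for m in MUSCLES:
        trains[m] = spk.detect_spikes(
            rec.emg[m], rec.fs, muscle=m, threshold_factor=threshold_factor
        )
        if free_emg:
            del rec.emg[m]
    strokes, unassigned = ws.assign_spike_phases(trains, strokes)
    if rec.stim_marks.size:
        ws.assign_stim_marks(rec.stim_marks, strokes)
    return ft, strokes, trains, unassigned


# ================================================================ correlational
def run_correlational(cfg: RunConfig) -> Report:
    """Optomotor-turn experiment: synthesize, segment, compare conditions."""
    if cfg.experiment != "correlational":
        raise ValueError("config is not a correlational run")
    seeds = _child_seeds(cfg.seed, 3 * cfg.n_individuals * 2)
    rng_offsets = np.random.default_rng(int(seeds[-1]))
    frames: List[pd.DataFrame] = []
    counts = {"strokes_total": 0, "strokes_valid": 0, "spikes_unassigned": 0}
    k = 0
    for i in range(cfg.n_individuals):
        ind = f"moth{i + 1:02d}"
        baseline = rng_offsets.normal(0.0, cfg.individual_offset_sd)
        for cond in ("pitch_up", "pitch_down"):
            preset = getattr(SynthConfig, cond)
            overrides = dict(cfg.condition_params.get(cond, {}))
            overrides["seed"] = int(seeds[k])
            k += 1
            scfg = preset(**overrides)
            scfg = scfg.replace(pitch_offset=scfg.pitch_offset + baseline)
            duration = (cfg.strokes_per_condition + 4) / scfg.wingbeat_freq_mean
            rec, _ = generate_flight_bout(scfg, duration)
            _, strokes, _, unassigned = _process_recording(
                rec, cfg.filter_variant, cfg.lowpass_cutoff, cfg.spike_threshold_factor
            )
            counts["strokes_total"] += len(strokes)
            counts["strokes_valid"] += sum(s.valid for s in strokes)
            counts["spikes_unassigned"] += unassigned
            frames.append(ws.strokes_to_frame(strokes, individual=ind, condition=cond))
    stroke_frame = pd.concat(frames, ignore_index=True)
    intervals = turns.interval_frame(stroke_frame)
    summaries = turns.condition_summaries(intervals)
    stats: Dict[str, object] = {}
    for metric in ("interval_ms", "dvm_phase", "wingbeat_freq"):
        res = turns.condition_compare(summaries, metric)
        res.pop("pair_means")
        stats[metric] = res
    centered = ws.centered_mean_torques(stroke_frame)
    sep = turns.torque_separation(centered)
    stats["torque_separation"] = sep["tests"]
    tables = {
        "strokes": stroke_frame,
        "condition_summaries": summaries,
        "torque_condition_means": sep["condition_means"],
    }
    return Report(tables, stats, counts, _provenance(cfg))


# ================================================================ stimulation
def run_stimulation(cfg: RunConfig) -> Report:
    """Stimulation experiment: per-individual CCA feature chain."""
    if cfg.experiment != "stimulation":
        raise ValueError("config is not a stimulation run")
    seeds = _child_seeds(cfg.seed, 2 * cfg.n_individuals)
    mech_frames: List[pd.DataFrame] = []
    summary_rows: List[dict] = []
    validity_rows: List[dict] = []
    decile_frames: List[pd.DataFrame] = []
    counts: Dict[str, object] = {"individuals": {}}
    overrides = dict(cfg.condition_params.get("stim_session", {}))

    for i in range(cfg.n_individuals):
        ind = f"moth{i + 1:02d}"
        scfg = SynthConfig.stim_session(seed=int(seeds[2 * i]), **overrides)
        rec, gt = generate_stimulation_session(scfg, cfg.n_stimuli)
        qcfg = scfg.replace(condition="quiescent", seed=int(seeds[2 * i + 1]))
        qrec, _ = generate_quiescent_segment(qcfg, 5.0)

        com = pre.estimate_com(pre.lowpass_ft(qrec.ft, cutoff=cfg.lowpass_cutoff))
        del qrec
        pre.transform_to_com(rec.ft, com, in_place=True)
        ft, strokes, trains, _ = _process_recording(
            rec, cfg.filter_variant, cfg.lowpass_cutoff, cfg.spike_threshold_factor,
            free_emg=True,
        )
        dlm_trains = {m: spk.label_evoked(trains[m], rec.stim_marks) for m in ("LDLM", "RDLM")}

        valid_strokes, phases, reasons = _validate_trials(rec.stim_marks, dlm_trains, strokes)
        n_valid = len(valid_strokes)
        conservation = n_valid + sum(reasons.values())
        assert conservation == len(rec.stim_marks), "trial accounting mismatch"
        validity_rows.append({"individual": ind, "n_stimuli": len(rec.stim_marks), "n_valid": n_valid, **reasons})
        counts["individuals"][ind] = {"n_stimuli": int(len(rec.stim_marks)), "n_valid": int(n_valid)}

        if n_valid < 3:
            summary_rows.append({"individual": ind, "n_valid": n_valid})
            del rec, ft
            gc.collect()
            continue

        matrix = feat.build_torque_matrix(valid_strokes, ft.tau_x, rec.fs)
        del rec, ft, trains, dlm_trains
        gc.collect()
        y = np.asarray(phases)
        model = feat.fit_cca(matrix, y)
        recon = feat.reconstruct(model, matrix)
        explained = feat.variance_explained(matrix, recon)
        mech = feat.stroke_mechanics(matrix, recon, y)
        mech.insert(0, "individual", ind)
        mech_frames.append(mech)

        dec = _decile_summary(mech, matrix)
        dec.insert(0, "individual", ind)
        decile_frames.append(dec)
        span = float(
            dec["delta_omega_feature"].iloc[-1] - dec["delta_omega_feature"].iloc[0]
        )
        summary_rows.append(
            {
                "individual": ind,
                "n_valid": n_valid,
                "canonical_correlation": model.canonical_correlation_,
                "variance_explained": explained,
                "variance_unexplained": 1.0 - explained,
                "delta_omega_span": span,
            }
        )

    tables = {
        "cca_summary": pd.DataFrame(summary_rows),
        "trial_validity": pd.DataFrame(validity_rows),
        "mechanics": pd.concat(mech_frames, ignore_index=True) if mech_frames else pd.DataFrame(),
        "decile_torque": pd.concat(decile_frames, ignore_index=True) if decile_frames else pd.DataFrame(),
    }
    stats: Dict[str, object] = {}
    if mech_frames:
        mech_all = tables["mechanics"]
        stats["slope_J_feature"] = feat.slope_test(
            mech_all["evoked_phase"], mech_all["J_feature"], mech_all["individual"]
        )
        fitted = tables["cca_summary"].dropna(subset=["variance_unexplained"])
        stats["mean_unexplained_pct"] = float(100 * fitted["variance_unexplained"].mean())
        stats["min_delta_omega_span"] = float(fitted["delta_omega_span"].min())
    return Report(tables, stats, counts, _provenance(cfg))


def _validate_trials(stim_marks, dlm_trains, strokes):
    """Run the inclusion rules for every stimulus; collect valid strokes."""
    reasons = {r: 0 for r in spk.REJECTION_REASONS}
    valid_strokes: List[ws.Wingstroke] = []
    phases: List[float] = []
    if strokes:
        t0s = np.array([s.t0 for s in strokes])
    for stim in stim_marks:
        trial = spk.StimulationTrial(stim_time=float(stim))
        stroke = None
        # stimulation wingstroke = stroke containing the evoked response
        t_ev = spk._first_in_window(dlm_trains["LDLM"].times, stim, stim + 5e-3)
        anchor = t_ev if t_ev is not None else stim
        if strokes:
            j = int(np.searchsorted(t0s, anchor, side="right") - 1)
            if 0 <= j < len(strokes) and anchor < strokes[j].t1 and strokes[j].valid:
                stroke = strokes[j]
        trial = spk.validate_evoked(trial, dlm_trains, stroke)
        if trial.valid:
            valid_strokes.append(stroke)
            phases.append(0.5 * (trial.evoked_phase_left + trial.evoked_phase_right))
        else:
            reasons[trial.reason] += 1
    return valid_strokes, phases, reasons


def _decile_summary(mech: pd.DataFrame, matrix: feat.TorqueMatrix) -> pd.DataFrame:
    """Equal-count decile bins of evoked phase with mean mechanics per bin."""
    n_bins = min(10, max(2, len(mech) // 3))
    order = np.argsort(mech["evoked_phase"].to_numpy(), kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins):
        sub = mech.iloc[idx]
        rows.append(
            {
                "decile": b,
                "n": len(idx),
                "evoked_phase_mean": float(sub["evoked_phase"].mean()),
                "delta_omega_feature": float(sub["delta_omega_feature"].mean()),
                "delta_omega_raw": float(sub["delta_omega_raw"].mean()),
                "J_feature": float(sub["J_feature"].mean()),
                "tau_x_mean": float(sub["tau_x_mean"].mean()),
            }
        )
    return pd.DataFrame(rows)


# ================================================================ reporting
def _provenance(cfg: RunConfig) -> Dict[str, object]:
    from . import __version__

    d = asdict(cfg)
    return {"config": d, "seed": cfg.seed, "version": __version__, "timestamp": time.time()}


def write_report(report: Report, out_dir: str | Path) -> Path:
    """Write tables as CSV and stats/counts/provenance as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    payload = {
        "stats": _jsonable(report.stats),
        "counts": _jsonable(report.counts),
        "provenance": _jsonable({**report.provenance, "timestamp": None}),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
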