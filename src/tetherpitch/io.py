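"""Recording and ground-truth serialization (HDF5 with a CSV alternative).

Layout of a recording file: one group per trial with datasets
``/emg/<muscle>``, ``/ft/<axis>`` (fx, fy, fz, tau_x, tau_y, tau_z) and
``/stim`` (event times, s); sampling rate, torque frame and metadata are
root attributes.  Ground truth is exported as a spike table CSV
(muscle, time_ms, evoked_flag).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .preprocess import FT_CHANNELS, COMEstimate, ForceTorqueSeries, TetherRecording
from .synth import GroundTruth


def write_recording_h5(path: str | Path, rec: TetherRecording) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = rec.fs
        f.attrs["frame"] = rec.ft.frame
        f.attrs["meta"] = json.dumps(rec.meta, default=str)
        g = f.create_group("emg")
        for muscle, v in rec.emg.items():
            g.create_dataset(muscle, data=v)
        g = f.create_group("ft")
        for j, name in enumerate(FT_CHANNELS):
            g.create_dataset(name, data=rec.ft.data[:, j])
        f.create_dataset("stim", data=rec.stim_marks)
    return path


def read_recording_h5(path: str | Path) -> TetherRecording:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        meta = json.loads(f.attrs.get("meta", "{}"))
        emg = {m: f["emg"][m][:] for m in f["emg"]}
        data = np.column_stack([f["ft"][name][:] for name in FT_CHANNELS])
        ft = ForceTorqueSeries(fs, data, frame=str(f.attrs.get("frame", "sensor")))
        stim = f["stim"][:] if "stim" in f else np.empty(0)
    return TetherRecording(fs=fs, emg=emg, ft=ft, stim_marks=stim, meta=meta)


def write_recording_csv(path: str | Path, rec: TetherRecording) -> Path:
    """Flat CSV alternative: time plus every channel as a column."""
    path = Path(path)
    cols = {"time_s": rec.time}
    for m, v in rec.emg.items():
        cols[f"emg_{m}"] = v
    for j, name in enumerate(FT_CHANNELS):
        cols[name] = rec.ft.data[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def ground_truth_spike_table(gt: GroundTruth) -> pd.DataFrame:
    rows = []
    for muscle, times in gt.spike_times.items():
        flags = gt.evoked_flags.get(muscle, np.zeros(len(times), dtype=bool))
        for t, ev in zip(times, flags):
            rows.append({"muscle": muscle, "time_ms": t * 1e3, "evoked_flag": bool(ev)})
    return pd.DataFrame(rows, columns=["muscle", "time_ms", "evoked_flag"])


def write_ground_truth_csv(path: str | Path, gt: GroundTruth) -> Path:
    path = Path(path)
    ground_truth_spike_table(gt).to_csv(path, index=False)
    return path


def write_com_json(path: str | Path, com: COMEstimate) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "offset_mm": com.offset_mm.tolist(),
                "residual_rms_mNm": com.residual_rms,
                "bounds_mm": list(com.bounds_mm),
            },
            fh,
            indent=2,
        )
    return path


def read_com_json(path: str | Path) -> COMEstimate:
    with open(path) as fh:
        d = json.load(fh)
    return COMEstimate(np.asarray(d["offset_mm"]), d["residual_rms_mNm"], tuple(d["bounds_mm"]))
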