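"""Shared fixtures: processed synthetic bouts reused across test modules."""

import warnings

import numpy as np
import pytest

from tetherpitch import preprocess as pre
from tetherpitch import spikes as spk
from tetherpitch import wingstrokes as ws
from tetherpitch.config import MUSCLES, SynthConfig
from tetherpitch.pipeline import RunConfig, _process_recording, _validate_trials
from tetherpitch.synth import generate_flight_bout, generate_stimulation_session


def process_flight(rec, variant="correlational_5_35"):
    return _process_recording(rec, variant, 1000.0, 5.0)


@pytest.fixture(scope="session")
def flight_small():
    """30 s pitch-up bout, fully processed (segmentation + spike assignment)."""
    cfg = SynthConfig.pitch_up(seed=3)
    rec, gt = generate_flight_bout(cfg, 30.0)
    ft, strokes, trains, unassigned = process_flight(rec)
    frame = ws.strokes_to_frame(strokes, individual="m1", condition="pitch_up")
    return {
        "cfg": cfg,
        "rec": rec,
        "gt": gt,
        "ft": ft,
        "strokes": strokes,
        "trains": trains,
        "unassigned": unassigned,
        "frame": frame,
    }


@pytest.fixture(scope="session")
def stim_small():
    """Short stimulation session (1 s spacing) with the full feature chain."""
    cfg = SynthConfig.stim_session(seed=5, stim_min_separation=1.0)
    rec, gt = generate_stimulation_session(cfg, 180)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ft, strokes, trains, _ = _process_recording(rec, "stimulation_10_40", 1000.0, 5.0)
    dlm = {m: spk.label_evoked(trains[m], rec.stim_marks) for m in ("LDLM", "RDLM")}
    valid_strokes, phases, reasons = _validate_trials(rec.stim_marks, dlm, strokes)
    return {
        "cfg": cfg,
        "rec": rec,
        "gt": gt,
        "ft": ft,
        "strokes": strokes,
        "trains": trains,
        "dlm_trains": dlm,
        "valid_strokes": valid_strokes,
        "phases": np.asarray(phases),
        "reasons": reasons,
    }
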