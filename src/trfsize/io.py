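"""File I/O: dataset containers, model serialization, and format readers.

Datasets travel as one HDF5 file per trial set plus a JSON sidecar carrying
the sampling rate, feature names, trial roles, seed, and generator config.
Real-world inputs are read with the usual tools: WAV via scipy, Praat
TextGrid interval tiers via a small parser, tabular annotations via pandas,
EDF via mne.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .containers import (EEGRecording, FeatureMatrix, PhonemeAnnotation,
                         PitchTrack, Trial, TrialSet)
from .encoding import TRFModel

__all__ = [
    "save_trialset", "load_trialset", "save_trf_model", "load_trf_model",
    "read_wav", "read_textgrid", "read_label_file", "read_pitch_track",
    "read_edf", "scores_to_csv",
]


def save_trialset(path, trialset: TrialSet, seed: Optional[int] = None,
                  config: Optional[dict] = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for i, t in enumerate(trialset.trials):
            g = h5.create_group(f"trial{i:05d}")
            g.attrs["trial_id"] = t.trial_id
            g.attrs["role"] = t.role
            g.create_dataset("features", data=t.features.values)
            g.create_dataset("eeg", data=t.eeg.values)
    sidecar = {
        "sampling_rate": trialset.sampling_rate,
        "feature_names": trialset.trials[0].features.feature_names,
        "channel_names": trialset.trials[0].eeg.channel_names,
        "roles": {t.trial_id: t.role for t in trialset.trials},
        "repeat_groups": trialset.repeat_groups,
        "seed": seed,
        "config": config,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def load_trialset(path) -> TrialSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    rate = meta["sampling_rate"]
    fnames = meta["feature_names"]
    cnames = meta["channel_names"]
    trials: List[Trial] = []
    with h5py.File(path, "r") as h5:
        for key in sorted(h5.keys()):
            g = h5[key]
            tid = g.attrs["trial_id"]
            trials.append(Trial(
                tid,
                FeatureMatrix(g["features"][()], fnames, rate),
                EEGRecording(g["eeg"][()], cnames, rate),
                g.attrs["role"],
            ))
    return TrialSet(trials, rate, meta.get("repeat_groups") or {})


def save_trf_model(path, model: TRFModel) -> None:
    with h5py.File(Path(path), "w") as h5:
        h5.create_dataset("weights", data=model.weights)
        h5.create_dataset("delay_grid", data=model.delay_grid)
        h5.attrs["alpha"] = model.alpha
        h5.attrs["feature_names"] = json.dumps(model.feature_names)
        h5.attrs["training_seconds"] = model.training_seconds
        h5.attrs["n_train_trials"] = model.n_train_trials


def load_trf_model(path) -> TRFModel:
    with h5py.File(Path(path), "r") as h5:
        return TRFModel(
            h5["weights"][()], h5["delay_grid"][()],
            float(h5.attrs["alpha"]),
            json.loads(h5.attrs["feature_names"]),
            training_seconds=float(h5.attrs["training_seconds"]),
            n_train_trials=int(h5.attrs["n_train_trials"]),
        )


def read_wav(path) -> Tuple[np.ndarray, float]:
    """Mono or multichannel WAV as float64 in [-1, 1], plus its rate."""
    from scipy.io import wavfile

    rate, data = wavfile.read(Path(path))
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


_TG_NUM = re.compile(r"(?:xmin|xmax|number)\s*=\s*([-\d.eE+]+)")
_TG_TEXT = re.compile(r'(?:text|mark)\s*=\s*"((?:[^"]|"")*)"')
_TG_NAME = re.compile(r'name\s*=\s*"((?:[^"]|"")*)"')


def read_textgrid(path, tier: Optional[str] = None) -> PhonemeAnnotation:
    """Intervals of one tier of a (long-format, text) Praat TextGrid.

    ``tier`` selects the tier by name (e.g. "phones"); by default the first
    interval tier is used.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    tiers: Dict[str, List[Tuple[str, float, float]]] = {}
    current: Optional[str] = None
    xmin = xmax = None
    order: List[str] = []
    for line in text.splitlines():
        line = line.strip()
        if "class" in line and "IntervalTier" in line:
            current = "__pending__"
            continue
        if current is not None:
            m = _TG_NAME.search(line)
            if m and current == "__pending__":
                current = m.group(1)
                tiers[current] = []
                order.append(current)
                continue
        if current in (None, "__pending__"):
            continue
        if line.startswith("xmin"):
            xmin = float(_TG_NUM.search(line).group(1))
        elif line.startswith("xmax"):
            xmax = float(_TG_NUM.search(line).group(1))
        else:
            m = _TG_TEXT.search(line)
            if m and xmin is not None and xmax is not None and xmax > xmin:
                tiers[current].append((m.group(1).replace('""', '"'),
                                       xmin, xmax))
                xmin = xmax = None
    if not order:
        raise ValueError(f"no interval tier found in {path}")
    name = tier if tier is not None else order[0]
    if name not in tiers:
        raise ValueError(f"tier {tier!r} not found; available: {order}")
    # drop the tier-header xmin/xmax pair that precedes the first interval
    intervals = [iv for iv in tiers[name]]
    return PhonemeAnnotation(intervals)


def read_label_file(path) -> PhonemeAnnotation:
    """3-column (label, start, end) tab- or whitespace-separated file."""
    df = pd.read_csv(Path(path), sep=r"\s+", header=None,
                     names=["label", "start", "end"], comment="#")
    return PhonemeAnnotation(
        [(str(r.label), float(r.start), float(r.end))
         for r in df.itertuples()])


def read_pitch_track(path) -> PitchTrack:
    """Two-column (time s, f0 Hz) text file; 0 marks unvoiced frames."""
    arr = np.loadtxt(Path(path), delimiter=None, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        arr = np.loadtxt(Path(path), delimiter=",", comments="#", ndmin=2)
    return PitchTrack(arr[:, 0], arr[:, 1])


def read_edf(path) -> EEGRecording:
    """EEG from an EDF file, via mne (I/O adapter only)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data(), list(raw.ch_names),
                        float(raw.info["sfreq"]))


def scores_to_csv(path, per_channel: np.ndarray,
                  channel_names: List[str]) -> None:
    pd.DataFrame({"channel": channel_names,
                  "r": per_channel}).to_csv(Path(path), index=False)
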