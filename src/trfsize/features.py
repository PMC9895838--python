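"""Stimulus feature computation from real inputs.

Acoustic envelope (Hilbert magnitude, 25 Hz 3rd-order Butterworth low-pass),
binary phonological onset matrices from phoneme annotations, pitch-track
ingestion, and match-filter alignment of recorded audio against presented
stimuli.
"""
from __future__ import annotations

from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .containers import FeatureMatrix, PhonemeAnnotation, PitchTrack

__all__ = [
    "PHONOLOGICAL_FEATURES",
    "load_phoneme_feature_table",
    "extract_envelope",
    "phonological_onset_matrix",
    "pitch_feature",
    "align_match_filter",
    "zscore_continuous",
]

#: fixed row order of the 14 phonological features
PHONOLOGICAL_FEATURES = [
    "sonorant", "obstruent", "voiced", "back", "front", "low", "high",
    "dorsal", "coronal", "labial", "syllabic", "plosive", "fricative",
    "nasal",
]

#: annotation labels treated as silence and skipped
SILENCE_LABELS = {"", "sp", "sil", "spn", "pau", "h#"}


def load_phoneme_feature_table(path: Optional[str] = None) -> pd.DataFrame:
    """Phoneme -> 14-feature binary table (rows: ARPAbet, columns: features).

    The shipped table is one explicit convention for mapping ARPAbet phoneme
    labels onto place/manner classes; pass ``path`` to override it with a CSV
    of the same layout.
    """
    if path is None:
        ref = resources.files("trfsize.data").joinpath("arpabet_features.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, index_col="phoneme")
    else:
        table = pd.read_csv(path, index_col="phoneme")
    missing = [c for c in PHONOLOGICAL_FEATURES if c not in table.columns]
    if missing:
        raise ValueError(f"mapping table lacks feature columns: {missing}")
    return table[PHONOLOGICAL_FEATURES].astype(int)


def _resample_to(x: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    """Polyphase rational resampling (zero-phase)."""
    if rate == target_rate:
        return x
    frac = Fraction(target_rate / rate).limit_denominator(10_000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def extract_envelope(audio: np.ndarray, rate: float,
                     target_rate: float) -> FeatureMatrix:
    """Acoustic envelope: |analytic signal|, 25 Hz low-passed, resampled.

    The magnitude of the Hilbert analytic signal is low-pass filtered with a
    zero-phase 3rd-order Butterworth (25 Hz cutoff) and polyphase-resampled
    to ``target_rate``; tiny negative filter ripple is clipped to zero.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono; downmix multichannel input "
                         "before envelope extraction")
    if rate <= 2 * 25.0:
        raise ValueError("audio rate must exceed 50 Hz for a 25 Hz low-pass")
    env = np.abs(signal.hilbert(audio))
    sos = signal.butter(3, 25.0 / (rate / 2), btype="low", output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = _resample_to(env, rate, target_rate)
    env = np.clip(env, 0.0, None)
    return FeatureMatrix(env[None, :], ["envelope"], target_rate)


def phonological_onset_matrix(
    annotation: PhonemeAnnotation,
    duration: float,
    target_rate: float,
    mapping: Optional[pd.DataFrame] = None,
    skip_unknown: bool = False,
) -> FeatureMatrix:
    """Binary onset matrix: one impulse per phoneme start per active feature.

    Each phoneme interval places a 1 at the sample nearest its start time
    (ties round down) in every feature row its mapping entry activates.
    Silence markers are skipped; unknown labels raise unless
    ``skip_unknown``.
    """
    if mapping is None:
        mapping = load_phoneme_feature_table()
    n = int(round(duration * target_rate))
    out = np.zeros((len(PHONOLOGICAL_FEATURES), n))
    for label, start, _end in annotation.intervals:
        key = label.strip().upper()
        if label.strip().lower() in SILENCE_LABELS or key in SILENCE_LABELS:
            continue
        key = "".join(ch for ch in key if not ch.isdigit())  # strip stress
        if key not in mapping.index:
            if skip_unknown:
                continue
            raise ValueError(f"unknown phoneme label {label!r}")
        idx = int(np.floor(start * target_rate + 0.5 - 1e-12))
        if 0 <= idx < n:
            out[:, idx] = np.maximum(out[:, idx],
                                     mapping.loc[key].to_numpy())
    return FeatureMatrix(out, list(PHONOLOGICAL_FEATURES), target_rate)


def pitch_feature(track: PitchTrack, duration: float,
                  target_rate: float) -> FeatureMatrix:
    """Sample-and-hold f0 onto the target grid; unvoiced spans stay 0."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * target_rate))
    grid = np.arange(n) / target_rate
    idx = np.searchsorted(track.times, grid, side="right") - 1
    row = np.where(idx >= 0, track.f0[np.clip(idx, 0, None)], 0.0)
    return FeatureMatrix(row[None, :], ["pitch"], target_rate)


def align_match_filter(
    recorded: np.ndarray,
    recorded_rate: float,
    stimulus: np.ndarray,
    stimulus_rate: float,
    threshold: float = 0.5,
) -> Tuple[Optional[int], Optional[int], float]:
    """Locate a presented stimulus inside a recorded audio channel.

    Slides the stimulus along the recording and computes the normalized
    cross-correlation at every offset; the onset is the argmax.  Returns
    ``(onset, offset, peak_score)`` in samples of the recorded channel, or
    ``(None, None, best_score)`` when the peak falls below ``threshold``.
    """
    recorded = np.asarray(recorded, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    if recorded_rate != stimulus_rate:
        stimulus = _resample_to(stimulus, stimulus_rate, recorded_rate)
    m = len(stimulus)
    if m > len(recorded):
        raise ValueError("stimulus is longer than the recorded channel")
    stim = stimulus - stimulus.mean()
    stim_norm = np.linalg.norm(stim)
    if stim_norm == 0:
        raise ValueError("stimulus has zero variance")
    # numerator: correlation of recording with zero-mean stimulus
    num = signal.fftconvolve(recorded, stim[::-1], mode="valid")
    # sliding norms of the recording windows
    csum = np.concatenate([[0.0], np.cumsum(recorded)])
    csum2 = np.concatenate([[0.0], np.cumsum(recorded ** 2)])
    win_sum = csum[m:] - csum[:-m]
    win_sq = csum2[m:] - csum2[:-m]
    win_var = np.clip(win_sq - win_sum ** 2 / m, 0.0, None)
    denom = np.sqrt(win_var) * stim_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 0, num / denom, 0.0)
    onset = int(np.argmax(ncc))
    peak = float(np.clip(ncc[onset], -1.0, 1.0))
    if peak < threshold:
        return None, None, peak
    return onset, onset + m - 1, peak


def zscore_continuous(trials, feature_names: Sequence[str] = ("envelope",
                                                              "pitch"),
                      center: bool = True) -> None:
    """Z-score the named continuous feature rows in place.

    Mean and SD are computed over the ``train`` trials only and applied to
    every trial, so no test-set statistics leak into the fit.
    """
    train = [t for t in trials.trials if t.role == "train"]
    if not train:
        raise ValueError("no training trials to compute normalization from")
    names = train[0].features.feature_names
    for name in feature_names:
        if name not in names:
            continue
        i = names.index(name)
        pooled = np.concatenate([t.features.values[i] for t in train])
        mu = pooled.mean() if center else 0.0
        sd = pooled.std()
        if sd == 0:
            continue
        for t in trials.trials:
            t.features.values[i] = (t.features.values[i] - mu) / sd
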