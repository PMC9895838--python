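"""Core data containers shared across the package.

The containers are deliberately thin: plain arrays plus the metadata needed
to keep stimulus features and EEG aligned (sampling rate, names, trial roles).
All heavy computation lives in the functional modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FeatureMatrix",
    "EEGRecording",
    "GroundTruthTRF",
    "NoiseSpec",
    "Trial",
    "TrialSet",
    "PhonemeAnnotation",
    "PitchTrack",
]


@dataclass
class FeatureMatrix:
    """Time-aligned stimulus representation: named feature rows x samples."""

    values: np.ndarray  # (n_features, n_samples)
    feature_names: List[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.feature_names = list(self.feature_names)
        if self.values.shape[0] != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[0]} rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), list(self.feature_names),
                             self.sampling_rate)


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples at a stated rate."""

    values: np.ndarray  # (n_channels, n_samples)
    channel_names: List[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.channel_names = list(self.channel_names)
        if self.values.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[0]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EEG values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.values.copy(), list(self.channel_names),
                            self.sampling_rate)


@dataclass
class GroundTruthTRF:
    """Known receptive-field weights used to synthesize EEG.

    weights[f, d, c] is the response of channel ``c`` to feature ``f`` at
    delay ``delay_grid[d]`` seconds.  Delays start at 0 and are spaced at
    one EEG sample; all weight mass lies within [0, 0.6] s.
    """

    weights: np.ndarray  # (n_features, n_delays, n_channels)
    delay_grid: np.ndarray  # seconds, ascending from 0
    feature_names: List[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.delay_grid = np.asarray(self.delay_grid, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.delay_grid[0] != 0:
            raise ValueError("delay grid must start at 0")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    @property
    def n_delays(self) -> int:
        return self.weights.shape[1]


@dataclass
class NoiseSpec:
    """Additive-noise description for the EEG simulator.

    snr_db may be ``numpy.inf`` for a noiseless simulation; ``spectrum`` is
    "pink" (1/f amplitude, EEG-like) or "white".  ``per_channel_scale``
    multiplies the noise of each channel *after* SNR matching, so values
    other than 1 deliberately detune the realized SNR per channel.
    """

    snr_db: float
    spectrum: str = "pink"
    per_channel_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.spectrum not in ("white", "pink"):
            raise ValueError("spectrum must be 'white' or 'pink'")


@dataclass
class Trial:
    trial_id: str
    features: FeatureMatrix
    eeg: EEGRecording
    role: str  # train | test | test-repeat

    def __post_init__(self) -> None:
        if self.role not in ("train", "test", "test-repeat"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.features.n_samples != self.eeg.n_samples:
            raise ValueError(
                f"trial {self.trial_id}: features have "
                f"{self.features.n_samples} samples but EEG has "
                f"{self.eeg.n_samples}"
            )
        if self.features.sampling_rate != self.eeg.sampling_rate:
            raise ValueError(f"trial {self.trial_id}: rate mismatch")


@dataclass
class TrialSet:
    """Ordered trials plus the repeated-test bookkeeping."""

    trials: List[Trial]
    sampling_rate: float
    repeat_groups: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial ids must be unique")
        by_id = {t.trial_id: t for t in self.trials}
        for stim, members in self.repeat_groups.items():
            for m in members:
                if by_id[m].role != "test-repeat":
                    raise ValueError(
                        f"repeat-group member {m} has role {by_id[m].role!r}"
                    )

    def __len__(self) -> int:
        return len(self.trials)

    def by_role(self, role: str) -> List[Trial]:
        return [t for t in self.trials if t.role == role]

    @property
    def train_trials(self) -> List[Trial]:
        return self.by_role("train")

    def test_pairs(self) -> List[Tuple[FeatureMatrix, np.ndarray]]:
        """Held-out (features, response) pairs used for scoring.

        For repeated-test designs the response is the average EEG across the
        repeats of each test stimulus; for continuous splits each ``test``
        trial is returned as-is.
        """
        pairs: List[Tuple[FeatureMatrix, np.ndarray]] = []
        by_id = {t.trial_id: t for t in self.trials}
        if self.repeat_groups:
            for stim in sorted(self.repeat_groups):
                members = [by_id[m] for m in self.repeat_groups[stim]]
                avg = np.mean([m.eeg.values for m in members], axis=0)
                pairs.append((members[0].features, avg))
        for t in self.by_role("test"):
            pairs.append((t.features, t.eeg.values))
        return pairs


@dataclass
class PhonemeAnnotation:
    """Ordered phoneme intervals: (label, start s, end s), non-overlapping."""

    intervals: List[Tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"interval {label!r}: start {start} >= end {end}")
            if start < prev_end:
                raise ValueError(f"interval {label!r} overlaps its predecessor")
            prev_end = end


@dataclass
class PitchTrack:
    """Fundamental-frequency track: f0 in Hz, 0 where unvoiced."""

    times: np.ndarray
    f0: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.f0.shape:
            raise ValueError("times and f0 must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(self.f0 < 0):
            raise ValueError("f0 must be nonnegative")
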