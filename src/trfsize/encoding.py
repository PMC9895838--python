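"""Multivariate temporal receptive field (mTRF) estimation.

The forward model predicts each EEG channel as a linear combination of
time-lagged stimulus features,

    EEG(t, n) = sum_f sum_tau w(f, tau, n) s(f, t - tau) + eps(t, n),

with delays tau on [0, 0.6] s.  Weights are fitted per channel by ridge
regression; the regularization strength is selected by cross-validation over
a log-spaced grid and shared across channels.  ``TemporalReceptiveField`` /
``TRFResults`` expose the statsmodels-style fit interface; the functional
layer underneath (``build_lagged_design``, ``ridge_fit``, ``select_alpha``,
``predict``, ``score``) is what the sufficiency analysis drives in bulk.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .containers import EEGRecording, FeatureMatrix, Trial, TrialSet

__all__ = [
    "LaggedDesign",
    "TRFModel",
    "RidgeConfig",
    "default_alpha_grid",
    "build_lagged_design",
    "ridge_fit",
    "select_alpha",
    "predict",
    "score",
    "TemporalReceptiveField",
    "TRFResults",
]


def default_alpha_grid() -> np.ndarray:
    """15 log-spaced ridge strengths from 1e2 to 1e8 inclusive."""
    return np.logspace(2, 8, 15)


@dataclass
class RidgeConfig:
    alphas: np.ndarray = field(default_factory=default_alpha_grid)
    n_folds: int = 5
    delay_span: Tuple[float, float] = (0.0, 0.6)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.size == 0:
            raise ValueError("alpha grid is empty")
        if np.any(self.alphas <= 0) or np.any(np.diff(self.alphas) <= 0):
            raise ValueError("alphas must be positive and ascending")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class LaggedDesign:
    """Time-lagged design matrix with a (feature, delay) -> column index."""

    matrix: np.ndarray  # (n_samples, n_features * n_delays)
    delay_grid: np.ndarray  # seconds
    feature_names: List[str]

    @property
    def n_delays(self) -> int:
        return len(self.delay_grid)

    def column(self, feature: Union[int, str], delay_index: int) -> int:
        if isinstance(feature, str):
            feature = self.feature_names.index(feature)
        return feature * self.n_delays + delay_index


@dataclass
class TRFModel:
    """Fitted mTRF weights, (feature, delay, channel)."""

    weights: np.ndarray
    delay_grid: np.ndarray
    alpha: float
    feature_names: List[str]
    training_seconds: float = np.nan
    n_train_trials: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.delay_grid = np.asarray(self.delay_grid, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("fitted weights must be finite")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.delay_grid[1] - self.delay_grid[0])


def build_lagged_design(features: FeatureMatrix,
                        delay_span: Tuple[float, float],
                        rate: float) -> LaggedDesign:
    """Stack time-shifted copies of every feature row.

    Column (f, d) at row t holds s(f, t - d); samples before the trial onset
    are zero (trials carry no cross-trial stimulus history).  The number of
    delays is floor(d_max * rate) + 1, covering 0..d_max inclusive.
    """
    lo, d_max = delay_span
    if lo != 0:
        raise ValueError("delay span must start at 0")
    n_delays = int(np.floor(d_max * rate)) + 1
    if n_delays < 2:
        raise ValueError(f"d_max={d_max} s at {rate} Hz yields no usable "
                         "delays")
    s = features.values
    n_feat, n_samp = s.shape
    X = np.zeros((n_samp, n_feat * n_delays))
    for f in range(n_feat):
        for d in range(n_delays):
            X[d:, f * n_delays + d] = s[f, :n_samp - d]
    delay_grid = np.arange(n_delays) / rate
    return LaggedDesign(X, delay_grid, list(features.feature_names))


def _solve_ridge(gram: np.ndarray, xty: np.ndarray,
                 alpha: float) -> np.ndarray:
    a = gram + alpha * np.eye(gram.shape[0])
    return np.linalg.solve(a, xty)


def ridge_fit(design: LaggedDesign, response: EEGRecording,
              alpha: float) -> TRFModel:
    """Per-channel ridge solution of (X'X + alpha I) w = X'Y."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = design.matrix
    Y = response.values.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"design has {X.shape[0]} rows but response has "
                         f"{Y.shape[0]} samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in design or response")
    w = _solve_ridge(X.T @ X, X.T @ Y, alpha)
    n_delays = design.n_delays
    weights = w.reshape(len(design.feature_names), n_delays, -1)
    rate = 1.0 / (design.delay_grid[1] - design.delay_grid[0])
    return TRFModel(weights, design.delay_grid, float(alpha),
                    list(design.feature_names),
                    training_seconds=X.shape[0] / rate, n_train_trials=1)


def score(predicted: EEGRecording, actual: EEGRecording
          ) -> Tuple[np.ndarray, float]:
    """Per-channel Pearson correlation over time plus its unweighted mean.

    Channels with zero variance in either signal are returned as NaN and
    excluded from the mean.
    """
    if predicted.values.shape != actual.values.shape:
        raise ValueError("predicted and actual shapes differ")
    return _score_arrays(predicted.values, actual.values)


def _score_arrays(pred: np.ndarray, act: np.ndarray
                  ) -> Tuple[np.ndarray, float]:
    if pred.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    p = pred - pred.mean(axis=1, keepdims=True)
    a = act - act.mean(axis=1, keepdims=True)
    sp = np.sqrt((p ** 2).sum(axis=1))
    sa = np.sqrt((a ** 2).sum(axis=1))
    denom = sp * sa
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (p * a).sum(axis=1) / denom, np.nan)
    valid = np.isfinite(r)
    mean = float(r[valid].mean()) if valid.any() else np.nan
    return r, mean


def predict(model: TRFModel, features: FeatureMatrix) -> EEGRecording:
    """Predicted EEG = lagged design x weights (linear in the features)."""
    rate = features.sampling_rate
    if not np.isclose(1.0 / rate, model.delay_grid[1] - model.delay_grid[0]):
        raise ValueError(
            f"feature rate {rate} Hz does not match the model delay grid "
            f"spacing {model.delay_grid[1] - model.delay_grid[0]:.6g} s"
        )
    if list(features.feature_names) != list(model.feature_names):
        raise ValueError("feature names/order do not match the model")
    design = build_lagged_design(features,
                                 (0.0, float(model.delay_grid[-1])), rate)
    w = model.weights.reshape(-1, model.n_channels)
    pred = (design.matrix @ w).T
    names = [f"pred{c:03d}" for c in range(model.n_channels)]
    return EEGRecording(pred, names, rate)


# ---------------------------------------------------------------------------
# Gram-matrix machinery shared by cross-validation and the learning curves
# ---------------------------------------------------------------------------

def _trial_design(trial: Trial, delay_span: Tuple[float, float]
                  ) -> np.ndarray:
    return build_lagged_design(trial.features, delay_span,
                               trial.features.sampling_rate).matrix


def _gram_pieces(trials: Sequence[Trial],
                 delay_span: Tuple[float, float]):
    """Per-trial (X'X, X'Y) so subset Grams are sums over trials."""
    grams, xtys = [], []
    for t in trials:
        X = _trial_design(t, delay_span)
        Y = t.eeg.values.T
        grams.append(X.T @ X)
        xtys.append(X.T @ Y)
    return grams, xtys


def _eig_sweep(gram: np.ndarray, xty: np.ndarray,
               alphas: np.ndarray) -> List[np.ndarray]:
    """Ridge solutions for every alpha from one eigendecomposition."""
    evals, vecs = np.linalg.eigh(gram)
    proj = vecs.T @ xty
    return [vecs @ (proj / (evals + a)[:, None]) for a in alphas]


def select_alpha(train_trials: Union[TrialSet, Sequence[Trial]],
                 config: Optional[RidgeConfig] = None,
                 seed: int = 0) -> Tuple[float, np.ndarray]:
    """Cross-validated choice of the ridge strength.

    Trials are split into ``n_folds`` contiguous folds; for each alpha the
    model is fitted on the remaining folds and scored on the held-out fold
    (correlation averaged over channels first, then folds).  Returns the
    maximizing alpha (ties broken toward stronger regularization) and the
    per-alpha mean validation correlations.  Deterministic for a fixed fold
    partition; ``seed`` is accepted for interface symmetry.
    """
    config = config or RidgeConfig()
    trials = (train_trials.train_trials if isinstance(train_trials, TrialSet)
              else list(train_trials))
    if len(trials) < config.n_folds:
        raise ValueError(f"{len(trials)} trials < n_folds={config.n_folds}")
    folds = np.array_split(np.arange(len(trials)), config.n_folds)
    grams, xtys = _gram_pieces(trials, config.delay_span)
    total_g = np.sum(grams, axis=0)
    total_b = np.sum(xtys, axis=0)
    fold_scores = np.zeros((config.n_folds, len(config.alphas)))
    for k, val_idx in enumerate(folds):
        g = total_g - np.sum([grams[i] for i in val_idx], axis=0)
        b = total_b - np.sum([xtys[i] for i in val_idx], axis=0)
        ws = _eig_sweep(g, b, config.alphas)
        Xv = np.vstack([_trial_design(trials[i], config.delay_span)
                        for i in val_idx])
        Yv = np.hstack([trials[i].eeg.values for i in val_idx])
        for ai, w in enumerate(ws):
            _, mean_r = _score_arrays((Xv @ w).T, Yv)
            fold_scores[k, ai] = mean_r
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_alpha = np.nanmean(fold_scores, axis=0)
    if not np.any(np.isfinite(per_alpha)):
        # degenerate (e.g. constant response): fall back to the strongest
        # regularization
        return float(config.alphas[-1]), per_alpha
    finite = np.where(np.isfinite(per_alpha), per_alpha, -np.inf)
    best = finite.max()
    chosen = int(np.flatnonzero(finite >= best - 1e-15).max())
    return float(config.alphas[chosen]), per_alpha


def fit_trials(trials: Sequence[Trial], alpha: float,
               delay_span: Tuple[float, float] = (0.0, 0.6)) -> TRFModel:
    """Ridge fit on stacked per-trial designs (zero history per trial)."""
    grams, xtys = _gram_pieces(trials, delay_span)
    w = _solve_ridge(np.sum(grams, axis=0), np.sum(xtys, axis=0), alpha)
    rate = trials[0].features.sampling_rate
    n_delays = int(np.floor(delay_span[1] * rate)) + 1
    names = list(trials[0].features.feature_names)
    seconds = sum(t.features.n_samples for t in trials) / rate
    return TRFModel(w.reshape(len(names), n_delays, -1),
                    np.arange(n_delays) / rate, float(alpha), names,
                    training_seconds=seconds, n_train_trials=len(trials))


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class TemporalReceptiveField:
    """Forward encoding model over a :class:`TrialSet`.

    Parameters
    ----------
    trials
        Dataset with train/test roles.  Training trials supply the fit;
        test trials (averaged across repeats where a repeated-stimulus
        design is present) supply the held-out score.
    config
        Ridge configuration (alpha grid, folds, delay span).
    """

    def __init__(self, trials: TrialSet,
                 config: Optional[RidgeConfig] = None):
        self.trials = trials
        self.config = config or RidgeConfig()
        if not trials.train_trials:
            raise ValueError("trial set has no training trials")

    def fit(self, alpha: Optional[float] = None, seed: int = 0
            ) -> "TRFResults":
        """Fit the mTRF; cross-validate alpha when not given."""
        alpha_scores = None
        if alpha is None:
            alpha, alpha_scores = select_alpha(self.trials, self.config,
                                               seed=seed)
        model = fit_trials(self.trials.train_trials, alpha,
                           self.config.delay_span)
        return TRFResults(self, model, alpha_scores)


class TRFResults:
    """Fitted mTRF with its held-out performance."""

    def __init__(self, parent: TemporalReceptiveField, model: TRFModel,
                 alpha_scores: Optional[np.ndarray] = None):
        self.model = model
        self.config = parent.config
        self.trials = parent.trials
        self.alpha_scores = alpha_scores
        self._test_r: Optional[np.ndarray] = None

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights

    @property
    def alpha(self) -> float:
        return self.model.alpha

    def predict(self, features: FeatureMatrix) -> EEGRecording:
        return predict(self.model, features)

    def test_scores(self) -> Tuple[np.ndarray, float]:
        """Per-channel and channel-mean correlation on the held-out set."""
        pairs = self.trials.test_pairs()
        if not pairs:
            raise ValueError("trial set has no test trials")
        preds, acts = [], []
        for feat, resp in pairs:
            preds.append(predict(self.model, feat).values)
            acts.append(resp)
        r, mean_r = _score_arrays(np.hstack(preds), np.hstack(acts))
        self._test_r = r
        return r, mean_r

    def summary(self) -> str:
        m = self.model
        lines = [
            "Temporal Receptive Field Results",
            "=" * 40,
            f"features:          {len(m.feature_names)}",
            f"delays:            {len(m.delay_grid)} "
            f"(0-{m.delay_grid[-1] * 1000:.0f} ms)",
            f"channels:          {m.n_channels}",
            f"training trials:   {m.n_train_trials}",
            f"training seconds:  {m.training_seconds:.1f}",
            f"alpha:             {m.alpha:.4g}",
        ]
        try:
            _, mean_r = self.test_scores()
            lines.append(f"test mean r:       {mean_r:.4f}")
        except ValueError:
            pass
        return "\n".join(lines)
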