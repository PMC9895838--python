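"""How much training data does an encoding model need?

Bootstrap learning curves over incrementally grown training sets, knee-point
detection by curvature maximization on the (unit-square normalized) curve,
grand-average knees across subjects, and adjacent-weight stability analysis.

The learning-curve protocol starts from ``start_size`` random trials and
grows the training set one step at a time; each of the ``n_boot`` bootstrap
replicates draws its own random ordering of the pool, so the subset at every
size is a uniform random subset of that size while consecutive sizes within
a replicate are nested — which is what makes "weights at size x vs x+1"
stability analysis meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import TrialSet
from .encoding import (RidgeConfig, TRFModel, _gram_pieces, _score_arrays,
                       _solve_ridge, _trial_design, select_alpha)

__all__ = [
    "LearningCurve",
    "KneeResult",
    "GrandAverageKnee",
    "StabilityCurve",
    "learning_curve",
    "knee_point",
    "curvature_knee",
    "grand_average_knee",
    "weight_stability",
    "SufficiencyAnalysis",
    "SufficiencyResults",
]

# keep the cached per-trial Gram blocks under this many bytes; above it the
# blocks are recomputed from cached designs instead
_GRAM_CACHE_BYTES = 2.5e9


@dataclass
class LearningCurve:
    """Bootstrap correlation statistics per training-set size."""

    sizes: np.ndarray  # trials/chunks, strictly ascending
    seconds: np.ndarray  # same grid in seconds of training data
    scores: np.ndarray  # (n_sizes, n_boot) channel-averaged correlations
    n_boot: int
    alpha: float

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly ascending")
        if self.scores.shape != (len(self.sizes), self.n_boot):
            raise ValueError("scores must be (n_sizes, n_boot)")

    @property
    def mean(self) -> np.ndarray:
        return self.scores.mean(axis=1)

    @property
    def se(self) -> np.ndarray:
        if self.n_boot < 2:
            return np.full(len(self.sizes), np.nan)
        return self.scores.std(axis=1, ddof=1) / np.sqrt(self.n_boot)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (size, seconds, replicate, score) rows."""
        rows = []
        for i, s in enumerate(self.sizes):
            for r in range(self.n_boot):
                rows.append((int(s), float(self.seconds[i]), r,
                             float(self.scores[i, r])))
        return pd.DataFrame(rows, columns=["size", "seconds", "replicate",
                                           "score"])


@dataclass
class KneeResult:
    """Curvature series and the size at which |curvature| peaks."""

    knee_size: Optional[float]
    knee_seconds: Optional[float]
    curvature: np.ndarray
    valid: bool
    reason: str = ""


@dataclass
class GrandAverageKnee:
    mean: float
    se: float  # NaN when only one valid subject
    n_valid: int
    n_invalid: int


@dataclass
class StabilityCurve:
    """Correlation between weights fitted at consecutive sizes."""

    sizes: np.ndarray  # from the second size onward
    adjacent_r: np.ndarray
    threshold: float
    stabilization_size: Optional[float]  # None when never stabilized


def learning_curve(
    trials: TrialSet,
    config: Optional[RidgeConfig] = None,
    start_size: int = 10,
    step: int = 1,
    n_boot: int = 10,
    seed: int = 0,
    alpha: Optional[float] = None,
    with_replacement: bool = False,
) -> Tuple[LearningCurve, List[TRFModel]]:
    """Bootstrap learning curve plus the nested model sequence.

    For every size x from ``start_size`` upward in steps of ``step``,
    ``n_boot`` random training subsets of x trials are fitted with the single
    pre-selected alpha (chosen by cross-validation on the full pool when not
    given) and scored against the fixed held-out test response (averaged
    across repeats for repeated-stimulus designs).  Returns the curve and
    the models of the first (designated) replicate at every size, for
    weight-stability analysis.
    """
    config = config or RidgeConfig()
    if start_size < 1:
        raise ValueError("start_size must be >= 1")
    pool = trials.train_trials
    if len(pool) < start_size:
        raise ValueError(f"training pool ({len(pool)}) smaller than "
                         f"start_size ({start_size})")
    pairs = trials.test_pairs()
    if not pairs:
        raise ValueError("test set is empty")
    pool_ids = {t.trial_id for t in pool}
    test_ids = {t.trial_id for t in trials.trials if t.role != "train"}
    if pool_ids & test_ids:
        raise ValueError("test set overlaps the training pool (leakage)")

    rate = trials.sampling_rate
    delay_span = config.delay_span
    n_delays = int(np.floor(delay_span[1] * rate)) + 1
    names = list(pool[0].features.feature_names)
    n_cols = len(names) * n_delays

    if alpha is None:
        alpha, _ = select_alpha(pool, config)
    alpha = float(alpha)

    # fixed test design/response
    from .encoding import build_lagged_design
    x_test = np.vstack([build_lagged_design(feat, delay_span, rate).matrix
                        for feat, _ in pairs])
    y_test = np.hstack([resp for _, resp in pairs])

    cache_grams = len(pool) * n_cols * n_cols * 8 <= _GRAM_CACHE_BYTES
    if cache_grams:
        grams, xtys = _gram_pieces(pool, delay_span)
        designs = None
    else:
        designs = [_trial_design(t, delay_span) for t in pool]
        xtys = [d.T @ (t.eeg.values.T) for d, t in zip(designs, pool)]
        grams = None

    sizes = np.arange(start_size, len(pool) + 1, step)
    scores = np.zeros((len(sizes), n_boot))
    models: List[TRFModel] = []
    durations = np.array([t.features.n_samples for t in pool]) / rate
    eye = np.eye(n_cols)

    children = np.random.SeedSequence(seed).spawn(n_boot)
    for r in range(n_boot):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(len(pool))

        def subset_gram(idx):
            if cache_grams:
                g = np.sum([grams[i] for i in idx], axis=0)
            else:
                g = np.sum([designs[i].T @ designs[i] for i in idx], axis=0)
            b = np.sum([xtys[i] for i in idx], axis=0)
            return g, b

        if with_replacement:
            for si, x in enumerate(sizes):
                idx = rng.choice(len(pool), size=int(x), replace=True)
                g, b = subset_gram(idx)
                w = np.linalg.solve(g + alpha * eye, b)
                _, scores[si, r] = _score_arrays((x_test @ w).T, y_test)
        else:
            g = np.zeros((n_cols, n_cols))
            b = None
            prev = 0
            for si, x in enumerate(sizes):
                add = perm[prev:int(x)]
                ga, ba = subset_gram(add)
                g += ga
                b = ba if b is None else b + ba
                prev = int(x)
                w = np.linalg.solve(g + alpha * eye, b)
                _, scores[si, r] = _score_arrays((x_test @ w).T, y_test)
                if r == 0:
                    sel = perm[:int(x)]
                    models.append(TRFModel(
                        w.reshape(len(names), n_delays, -1),
                        np.arange(n_delays) / rate, alpha, names,
                        training_seconds=float(durations[sel].sum()),
                        n_train_trials=int(x)))

    seconds = sizes * float(durations.mean())
    curve = LearningCurve(sizes, seconds, scores, n_boot, alpha)
    return curve, models


# ---------------------------------------------------------------------------
# knee-point detection
# ---------------------------------------------------------------------------

def _default_window(n: int) -> int:
    """Adaptive smoothing span: ~31% of the series, odd, at least 5."""
    w = max(5, int(round(0.31 * n)))
    return w if w % 2 else w + 1


def curvature_knee(
    x: np.ndarray,
    y: np.ndarray,
    smooth_window: Optional[int] = None,
    boundary_margin: float = 0.05,
) -> KneeResult:
    """Knee of a performance curve by curvature maximization.

    Both axes are rescaled to the unit square (the convention of the
    knee-point literature this implements; without it the curvature of any
    gently sloped saturating curve is maximal at the origin).  First and
    second derivatives come from a Savitzky-Golay quadratic fit over
    ``smooth_window`` points, the curvature is

        K(x) = f''(x) / (1 + f'(x)^2)^1.5,

    and the knee is the size maximizing |K| over the interior of the grid.
    The result is invalid when that argmax hugs the ``boundary_margin``
    exclusion zone at either end, when the curve has no net rise, or when
    the curvature is numerically zero (straight line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 7:
        raise ValueError("need at least 7 sizes for knee detection")
    if smooth_window is None:
        smooth_window = _default_window(n)
    if smooth_window > n:
        raise ValueError(f"smooth_window={smooth_window} exceeds the "
                         f"{n} available sizes")

    u = (x - x[0]) / (x[-1] - x[0])
    y_range = y.max() - y.min()
    v = (y - y.min()) / (y_range if y_range > 0 else 1.0)
    h = np.mean(np.diff(u))

    w = int(smooth_window)
    if w % 2 == 0:
        w -= 1
    polyorder = 2
    if w > polyorder:
        d1 = savgol_filter(v, w, polyorder, deriv=1, delta=h, mode="interp")
        d2 = savgol_filter(v, w, polyorder, deriv=2, delta=h, mode="interp")
        v_s = savgol_filter(v, w, polyorder, mode="interp")
    else:
        d1 = np.gradient(v, u)
        d2 = np.gradient(d1, u)
        v_s = v
    curvature = d2 / (1.0 + d1 ** 2) ** 1.5

    margin = int(np.ceil(boundary_margin * n))
    interior = np.arange(margin, n - margin)
    if len(interior) == 0:
        return KneeResult(None, None, curvature, False,
                          "boundary margin leaves no interior sizes")
    if y_range <= 0 or v_s.max() - v_s.min() <= 0:
        return KneeResult(None, None, curvature, False,
                          "curve is flat (no rise to bend)")
    k_abs = np.abs(curvature[interior])
    if k_abs.max() < 1e-8:
        return KneeResult(None, None, curvature, False,
                          "curvature is numerically zero (straight line)")
    i = int(interior[np.argmax(k_abs)])
    if i <= interior[0] or i >= interior[-1]:
        return KneeResult(float(x[i]), None, curvature, False,
                          "curvature argmax falls at the boundary margin")
    return KneeResult(float(x[i]), None, curvature, True)


def knee_point(curve: Union[LearningCurve, Tuple[np.ndarray, np.ndarray]],
               smooth_window: Optional[int] = None,
               boundary_margin: float = 0.05) -> KneeResult:
    """Knee of a learning curve (bootstrap-mean performance vs size)."""
    if isinstance(curve, LearningCurve):
        result = curvature_knee(curve.sizes.astype(float), curve.mean,
                                smooth_window, boundary_margin)
        if result.knee_size is not None:
            sec_per_trial = curve.seconds[0] / curve.sizes[0]
            result.knee_seconds = float(result.knee_size * sec_per_trial)
        return result
    x, y = curve
    return curvature_knee(np.asarray(x), np.asarray(y), smooth_window,
                          boundary_margin)


def grand_average_knee(per_subject: Sequence[KneeResult]
                       ) -> GrandAverageKnee:
    """Mean and SE of valid per-subject knees; invalid subjects counted."""
    valid = [k.knee_size for k in per_subject if k.valid]
    n_invalid = sum(1 for k in per_subject if not k.valid)
    if not valid:
        raise ValueError("no knee point could be computed for any subject")
    arr = np.asarray(valid, dtype=float)
    se = (arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan
    return GrandAverageKnee(float(arr.mean()), float(se), len(arr),
                            n_invalid)


def weight_stability(models: Sequence[TRFModel],
                     threshold: float = 0.9) -> StabilityCurve:
    """Correlation between flattened weights at consecutive sizes.

    ``stabilization_size`` is the first size after which every subsequent
    adjacent correlation stays at or above ``threshold`` (None if never).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    shapes = {m.weights.shape for m in models}
    if len(shapes) > 1:
        raise ValueError(f"weight shape mismatch across models: {shapes}")
    sizes = np.array([m.n_train_trials for m in models[1:]], dtype=float)
    adjacent = np.empty(len(models) - 1)
    for i in range(len(models) - 1):
        a = models[i].weights.ravel()
        b = models[i + 1].weights.ravel()
        r, _ = _score_arrays(a[None, :], b[None, :])
        adjacent[i] = r[0]
    stabilization: Optional[float] = None
    ok = adjacent >= threshold
    for i in range(len(ok)):
        if ok[i:].all():
            stabilization = float(sizes[i])
            break
    return StabilityCurve(sizes, adjacent, threshold, stabilization)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class SufficiencyAnalysis:
    """Training-data sufficiency analysis for one subject's trial set.

    Runs the full protocol of this package: alpha selection on the complete
    training pool, bootstrap learning curve over incrementally grown
    training sets, curvature knee point, and adjacent-weight stability.
    """

    def __init__(
        self,
        trials: TrialSet,
        config: Optional[RidgeConfig] = None,
        start_size: int = 10,
        step: int = 1,
        n_boot: int = 10,
        smooth_window: Optional[int] = None,
        boundary_margin: float = 0.05,
        stability_threshold: float = 0.9,
        alpha: Optional[float] = None,
    ):
        self.trials = trials
        self.config = config or RidgeConfig()
        self.start_size = start_size
        self.step = step
        self.n_boot = n_boot
        self.smooth_window = smooth_window
        self.boundary_margin = boundary_margin
        self.stability_threshold = stability_threshold
        self.alpha = alpha

    def fit(self, seed: int = 0) -> "SufficiencyResults":
        curve, models = learning_curve(
            self.trials, self.config, self.start_size, self.step,
            self.n_boot, seed=seed, alpha=self.alpha)
        knee = knee_point(curve, self.smooth_window, self.boundary_margin)
        stability = weight_stability(models, self.stability_threshold)
        return SufficiencyResults(self, curve, knee, stability, models,
                                  seed)


class SufficiencyResults:
    """Learning curve, knee point, and weight stability for one run."""

    def __init__(self, parent: SufficiencyAnalysis, curve: LearningCurve,
                 knee: KneeResult, stability: StabilityCurve,
                 models: List[TRFModel], seed: int):
        self.analysis = parent
        self.curve = curve
        self.knee = knee
        self.stability = stability
        self.models = models
        self.seed = seed

    def to_frame(self) -> pd.DataFrame:
        return self.curve.to_frame()

    def summary_dict(self) -> dict:
        k = self.knee
        return {
            "alpha": self.curve.alpha,
            "n_boot": self.curve.n_boot,
            "sizes": [int(s) for s in self.curve.sizes],
            "final_mean_score": float(self.curve.mean[-1]),
            "knee_valid": bool(k.valid),
            "knee_size": None if k.knee_size is None else float(k.knee_size),
            "knee_seconds": (None if k.knee_seconds is None
                             else float(k.knee_seconds)),
            "knee_reason": k.reason,
            "stabilization_size": self.stability.stabilization_size,
            "final_adjacent_r": float(self.stability.adjacent_r[-1]),
            "seed": self.seed,
        }

    def summary(self) -> str:
        d = self.summary_dict()
        lines = [
            "Training-Data Sufficiency Results",
            "=" * 40,
            f"sizes:                {d['sizes'][0]}..{d['sizes'][-1]} "
            f"({len(d['sizes'])} sizes, {d['n_boot']} replicates each)",
            f"alpha:                {d['alpha']:.4g}",
            f"final mean r:         {d['final_mean_score']:.4f}",
        ]
        if d["knee_valid"]:
            lines.append(f"knee point:           {d['knee_size']:.0f} trials "
                         f"({d['knee_seconds']:.1f} s)")
        else:
            lines.append(f"knee point:           invalid "
                         f"({d['knee_reason']})")
        stab = d["stabilization_size"]
        lines.append("weight stabilization: " +
                     (f"{stab:.0f} trials" if stab is not None else "never"))
        lines.append(f"final adjacent r:     {d['final_adjacent_r']:.4f}")
        return "\n".join(lines)
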