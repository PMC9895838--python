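"""Plotting helpers: learning curve with knee, weight heatmaps, stability."""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .encoding import TRFModel  # noqa: E402
from .sufficiency import KneeResult, LearningCurve, StabilityCurve  # noqa: E402

__all__ = ["plot_learning_curve", "plot_weights", "plot_stability"]


def plot_learning_curve(curve: LearningCurve, knee: Optional[KneeResult],
                        path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    m, se = curve.mean, curve.se
    ax.plot(curve.sizes, m, color="tab:blue", lw=1.5)
    ax.fill_between(curve.sizes, m - se, m + se, alpha=0.3,
                    color="tab:blue")
    if knee is not None and knee.valid:
        ax.axvline(knee.knee_size, ls="--", color="gray",
                   label=f"knee = {knee.knee_size:.0f}")
        ax.legend(frameon=False)
    ax.set_xlabel("training-set size (trials)")
    ax.set_ylabel("mean correlation (r)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_weights(models: Sequence[TRFModel], channel: int, path) -> None:
    """Receptive-field heatmaps (feature x delay) at selected fit sizes."""
    fig, axes = plt.subplots(1, len(models),
                             figsize=(3.2 * len(models), 3), squeeze=False)
    for ax, m in zip(axes[0], models):
        w = m.weights[:, :, channel]
        vmax = abs(w).max() or 1.0
        ax.imshow(w, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                  extent=[0, m.delay_grid[-1], len(m.feature_names), 0])
        ax.set_title(f"{m.n_train_trials} trials", fontsize=9)
        ax.set_xlabel("delay (s)")
    axes[0][0].set_ylabel("feature")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_stability(stability: StabilityCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(stability.sizes, stability.adjacent_r, color="tab:green")
    ax.axhline(stability.threshold, ls=":", color="gray")
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("training-set size (trials)")
    ax.set_ylabel("adjacent-weight correlation")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
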