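"""Optional figure generation from the pipeline's CSV-style frames.

CSV tables are the canonical output; these panels are quick-look summaries
in the spirit of the study's figures (error estimates vs resample size per
threshold, the widened null distribution, and bias heat lines per scenario).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _get_axes(n: int):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = min(n, 3)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.4 * nrows))
    return fig, np.atleast_1d(axes).ravel()


def plot_error_sweep(frame: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """One panel per estimator: iteration-averaged value vs resample size."""
    estimators = [e for e in frame["estimator"].unique() if e != "inflation_rate"]
    fig, axes = _get_axes(len(estimators))
    for ax, est in zip(axes, estimators):
        sub = frame[frame["estimator"] == est]
        for alpha, grp in sub.groupby("alpha"):
            grp = grp.sort_values("size")
            ax.plot(grp["size"], grp["value"], marker="o", ms=3,
                    label=f"$\\alpha$={alpha:g}")
        ax.set_xscale("log")
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("resample size")
        ax.set_title(est.replace("_", " "))
    axes[0].legend(fontsize=7)
    for ax in axes[len(estimators):]:
        ax.set_visible(False)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    _close(fig)


def plot_bias(bias: pd.DataFrame, path: str | Path) -> None:
    """Estimated minus analytical power vs resample size, one line per scenario."""
    fig, axes = _get_axes(2)
    for level, grp in bias.groupby("scenario_power_level"):
        grp = grp.sort_values("size")
        axes[0].plot(grp["size"], grp["estimated_power"], marker="o", ms=3,
                     label=f"{100 * level:.0f}%")
        axes[1].plot(grp["size"], grp["bias"], marker="o", ms=3)
    axes[0].set_ylabel("estimated power")
    axes[1].set_ylabel("bias (estimated $-$ analytical)")
    axes[1].axhline(0.0, color="k", lw=0.8)
    for ax in axes[:2]:
        ax.set_xscale("log")
        ax.set_xlabel("resample size")
    axes[0].legend(fontsize=7, title="target power")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    _close(fig)


def plot_variance_diagnostic(diag, path: str | Path) -> None:
    """Tracked-effect histogram with the full-sample value marked."""
    fig, axes = _get_axes(1)
    ax = axes[0]
    ax.hist(diag.tracked_effect_values, bins=20, density=True, alpha=0.7)
    ax.axvline(diag.tracked_effect_r, color="k",
               label=f"full-sample r = {diag.tracked_effect_r:.3f}")
    ax.set_xlabel("resampled correlation of tracked effect")
    ax.set_title(
        f"pooled var {diag.empirical_var:.4f} vs "
        f"$\\sigma_1^2+\\sigma_2^2$ = {diag.predicted_var:.4f}"
    )
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    _close(fig)


def _close(fig) -> None:
    import matplotlib.pyplot as plt

    plt.close(fig)
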