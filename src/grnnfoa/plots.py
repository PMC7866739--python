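"""Basic diagnostic figures: fit scatter, residuals, convergence traces."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_fit_scatter", "plot_residual_hist", "plot_convergence"]


def plot_fit_scatter(y_act, y_est, label: str = "", ax=None):
    """Predicted against actual values with the identity line."""
    ax = ax or plt.figure(figsize=(4, 4)).add_subplot()
    ax.scatter(y_act, y_est, s=12, alpha=0.6, edgecolor="none")
    lims = [min(np.min(y_act), np.min(y_est)), max(np.max(y_act), np.max(y_est))]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel(f"actual {label}")
    ax.set_ylabel(f"predicted {label}")
    return ax


def plot_residual_hist(y_act, y_est, label: str = "", ax=None):
    ax = ax or plt.figure(figsize=(4, 3)).add_subplot()
    ax.hist(np.asarray(y_est) - np.asarray(y_act), bins=30)
    ax.set_xlabel(f"residual {label}")
    ax.set_ylabel("count")
    return ax


def plot_convergence(trace, label: str = "best fitness", ax=None):
    """Incumbent trace of an optimizer run (non-decreasing)."""
    ax = ax or plt.figure(figsize=(4, 3)).add_subplot()
    ax.plot(np.arange(1, len(trace) + 1), trace)
    ax.set_xlabel("generation")
    ax.set_ylabel(label)
    return ax
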