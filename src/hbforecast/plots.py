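"""Diagnostic figures: error histogram and Bland-Altman agreement plot."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import HISTOGRAM_BIN_WIDTH, bland_altman  # noqa: E402

__all__ = ["plot_error_histogram", "plot_bland_altman"]


def plot_error_histogram(errors, path) -> None:
    """Histogram of observed - predicted Hb(t+3), 0.25 g/dL bins."""
    errors = np.asarray(errors, dtype=float)
    lo = np.floor(errors.min() / HISTOGRAM_BIN_WIDTH) * HISTOGRAM_BIN_WIDTH
    hi = np.ceil(errors.max() / HISTOGRAM_BIN_WIDTH) * HISTOGRAM_BIN_WIDTH
    edges = np.arange(lo, hi + HISTOGRAM_BIN_WIDTH / 2, HISTOGRAM_BIN_WIDTH)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(errors, bins=edges, edgecolor="white")
    ax.set_xlabel("observed $-$ predicted Hb(t+3) [g/dL]")
    ax.set_ylabel("records")
    ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(observed, predicted, path) -> None:
    """Difference vs mean with the OLS fit line and +/-1.96 sd limits."""
    ba = bland_altman(observed, predicted)
    mean, diff = ba["mean"], ba["diff"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=6, alpha=0.4)
    xs = np.linspace(mean.min(), mean.max(), 50)
    ax.plot(xs, ba["intercept"] + ba["slope"] * xs, "r-",
            label=f"slope {ba['slope']:.3f} (p={ba['slope_p']:.2g})")
    mu, sd = diff.mean(), diff.std()
    for y, style in ((mu, "k-"), (mu + 1.96 * sd, "k--"), (mu - 1.96 * sd, "k--")):
        ax.axhline(y, lw=0.8, ls=style[1:], color="k")
    ax.set_xlabel("(observed + predicted)/2 Hb(t+3) [g/dL]")
    ax.set_ylabel("observed $-$ predicted [g/dL]")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
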