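"""Histogram plot with the fitted Gaussian overlaid."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diameter import DiameterHistogram, GaussianFit, _gauss  # noqa: E402


def plot_histogram_fit(
    hist: DiameterHistogram, fit: GaussianFit | None = None, path=None, title: str = ""
):
    """Bar histogram of gap distances with the Gaussian fit curve on top.

    Returns the matplotlib figure; writes a PNG when ``path`` is given.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(
        hist.bin_centers, hist.counts, width=hist.bin_size,
        color="0.6", edgecolor="none", label="measured distances",
    )
    if fit is not None:
        x = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 512)
        y = _gauss(x, fit.offset, fit.amplitude, fit.raw_mean, fit.sd)
        ax.plot(x, y, color="tab:blue", lw=1.5, label="Gaussian fit")
        ax.text(
            0.02, 0.98,
            f"mean = {fit.mean:.3g} {hist.units}\nsd = {fit.sd:.3g} {hist.units}",
            transform=ax.transAxes, va="top", ha="left", fontsize=9,
        )
    ax.set_xlabel(f"distance ({hist.units})")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
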