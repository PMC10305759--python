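"""Lightweight figures: topographic map grids, spectra and posteriors."""

from __future__ import annotations

import numpy as np

from .layout import SensorLayout, make_layout


def plot_mapset(mapset, layout: SensorLayout | None = None, axes=None):
    """Grid of interpolated scalp topographies, one panel per class."""
    import matplotlib.pyplot as plt

    layout = layout or make_layout()
    xy = layout.positions_2d
    k = mapset.n_maps
    if axes is None:
        _, axes = plt.subplots(1, k, figsize=(2.2 * k, 2.4))
    axes = np.atleast_1d(axes)
    labels = mapset.class_labels or [str(i) for i in range(k)]
    for ax, m, name in zip(axes, mapset.maps, labels):
        ax.tricontourf(xy[:, 0], xy[:, 1], m, levels=16, cmap="RdBu_r")
        ax.scatter(xy[:, 0], xy[:, 1], s=4, c="k")
        circle = plt.Circle((0, 0), 1.0, fill=False, lw=0.8)
        ax.add_patch(circle)
        ax.set_title(name)
        ax.set_aspect("equal")
        ax.axis("off")
    return axes


def plot_psd_report(report, ax=None):
    """Channel-average PSD with the QC bands shaded."""
    import matplotlib.pyplot as plt

    from .preprocess import BANDS

    if ax is None:
        _, ax = plt.subplots()
    ax.semilogy(report.frequencies, report.power.mean(axis=0), lw=1.2)
    ax.axvspan(*BANDS["alpha"], alpha=0.15, color="tab:orange", label="alpha 8-13 Hz")
    ax.set_xlim(0, 30)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (uV$^2$/Hz)")
    ax.legend(frameon=False)
    return ax


def plot_effect_posterior(results, ax=None):
    """Posterior density of the effect size with ROPE and HDI marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = results.draws["d"]
    ax.hist(d, bins=60, density=True, color="tab:blue", alpha=0.7)
    for edge in results.rope:
        ax.axvline(edge, color="red", ls=":")
    ax.plot([results.hdi_low, results.hdi_high], [0, 0], lw=4, color="k",
            solid_capstyle="butt")
    ax.set_xlabel("effect size d")
    ax.set_title(f"P(outside ROPE) = {results.p_outside_rope:.3f}")
    return ax
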