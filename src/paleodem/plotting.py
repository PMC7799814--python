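"""Thin matplotlib helpers reproducing the standard figure panels:
SPD-vs-envelope plots, zone permutation panels, normalized proxy series and
KDE snapshot maps.  Axes run old → young (cal BP decreasing rightward)."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np


def _bp_axis(ax):
    ax.set_xlabel("cal BP")
    if not ax.xaxis_inverted():
        ax.invert_xaxis()


def plot_envelope_test(result, ax=None, color="black", band_color="0.8"):
    """Observed SPD, simulation envelope and deviation regions."""
    ax = ax or plt.gca()
    ax.fill_between(result.grid, result.lo, result.hi, color=band_color, label="95% envelope")
    ax.plot(result.grid, result.observed, color=color, lw=1.2, label="observed SPD")
    for a, b in result.positive_regions:
        ax.axvspan(a, b, color="red", alpha=0.25, lw=0)
    for a, b in result.negative_regions:
        ax.axvspan(a, b, color="blue", alpha=0.25, lw=0)
    ax.set_ylabel("summed probability")
    ax.set_title(f"global p = {result.global_p:.3g} (nsim = {result.nsim})")
    _bp_axis(ax)
    return ax


def plot_perm_test(result, axes=None):
    """One panel per mark: group SPD against its permutation envelope."""
    labels = result.marks
    if axes is None:
        _, axes = plt.subplots(len(labels), 1, sharex=True, figsize=(7, 2.6 * len(labels)))
        axes = np.atleast_1d(axes)
    for ax, lab in zip(axes, labels):
        g = result.groups[lab]
        ax.fill_between(g.grid, g.lo, g.hi, color="0.85")
        ax.plot(g.grid, g.observed, color="black", lw=1.1)
        for a, b in g.positive_regions:
            ax.axvspan(a, b, color="red", alpha=0.25, lw=0)
        for a, b in g.negative_regions:
            ax.axvspan(a, b, color="blue", alpha=0.25, lw=0)
        ax.set_ylabel(lab)
        ax.set_title(f"{lab}: global p = {g.global_p:.3g}", fontsize=9)
        _bp_axis(ax)
    return axes


def plot_series(series_map, ax=None, normalized=True):
    """Overlay time-slice proxy series (optionally min-max scaled)."""
    from .compare import minmax_normalize

    ax = ax or plt.gca()
    for label, s in series_map.items():
        vals = minmax_normalize(s.values) if normalized else s.values
        ax.plot(s.midpoints, vals, label=label, lw=1.2)
    ax.set_ylabel("normalized proxy" if normalized else "proxy value")
    ax.legend(fontsize=8)
    _bp_axis(ax)
    return ax


def plot_kde_surface(surface, ax=None, cmap="viridis"):
    """Image of a KDE density surface in projected km coordinates."""
    ax = ax or plt.gca()
    im = ax.imshow(
        surface.values,
        origin="lower",
        extent=(surface.x[0], surface.x[-1], surface.y[0], surface.y[-1]),
        cmap=cmap,
        aspect="equal",
    )
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    if surface.interval is not None:
        ax.set_title(f"{surface.interval[0]:.0f}-{surface.interval[1]:.0f} cal BP")
    plt.colorbar(im, ax=ax, shrink=0.8, label="weight / km²")
    return ax
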