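"""Minimal plotting helpers (matplotlib is an optional dependency)."""

from __future__ import annotations

import numpy as np


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_slope_curve(slope_set, ax=None, color="C0", label=None):
    """Slope vs percentile with a +/-1.96 SE band."""
    ax = _get_axes(ax)
    pct = 100.0 * slope_set.taus
    se = slope_set.boot_se
    ax.fill_between(
        pct, slope_set.slopes - 1.96 * se, slope_set.slopes + 1.96 * se,
        alpha=0.25, color=color, linewidth=0,
    )
    ax.plot(pct, slope_set.slopes, color=color, label=label)
    ax.set_xlabel("percentile of the trait distribution")
    ax.set_ylabel("quantile regression slope")
    return ax


def plot_h2_curve(curve, ax=None, color="C1", label=None):
    """Heritability vs percentile with a +/-1.96 SE band."""
    ax = _get_axes(ax)
    pct = 100.0 * curve.taus
    ok = ~np.isnan(curve.h2)
    ax.fill_between(
        pct[ok], (curve.h2 - 1.96 * curve.se)[ok], (curve.h2 + 1.96 * curve.se)[ok],
        alpha=0.25, color=color, linewidth=0,
    )
    ax.plot(pct[ok], curve.h2[ok], color=color, label=label)
    ax.set_xlabel("percentile of the trait distribution")
    ax.set_ylabel("narrow-sense heritability $h^2$")
    return ax


def plot_remapped(remapped_by_group, ax=None):
    """Remapped group curves on the common concentration axis."""
    ax = _get_axes(ax)
    for i, (name, rc) in enumerate(remapped_by_group.items()):
        ok = rc.valid
        ax.plot(rc.concentrations[ok], rc.values[ok], color=f"C{i}", label=name)
        se = rc.se
        if se is not None:
            ax.fill_between(
                rc.concentrations[ok],
                (rc.values - 1.96 * se)[ok],
                (rc.values + 1.96 * se)[ok],
                alpha=0.2, color=f"C{i}", linewidth=0,
            )
    ax.set_xlabel("concentration")
    ax.set_ylabel("slope / heritability")
    ax.legend()
    return ax
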