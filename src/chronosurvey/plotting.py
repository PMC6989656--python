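"""Minimal plotting helpers for chronotype distributions and trends."""

from __future__ import annotations

import numpy as np

from .associations import binned_profile

__all__ = ["plot_binned_profile", "plot_distribution"]


def plot_binned_profile(x, y, n_bins: int = 16, poly_order: int = 4, ax=None,
                        label: str = ""):
    """Scatter of binned means +/- SD with the polynomial trend overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    profile, coeffs = binned_profile(x, y, n_bins=n_bins, poly_order=poly_order)
    ax.errorbar(profile["bin_centre"], profile["mean"], yerr=profile["sd"],
                fmt="o", capsize=2, label=label or None)
    grid = np.linspace(profile["bin_centre"].min(), profile["bin_centre"].max(), 200)
    ax.plot(grid, np.polyval(coeffs, grid), "-")
    return ax


def plot_distribution(values, ax=None, bins: str = "fd", label: str = ""):
    """Histogram with a Gaussian-kernel density overlay."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots()
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    ax.hist(vals, bins=bins, density=True, alpha=0.5, label=label or None)
    kde = stats.gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), 200)
    ax.plot(grid, kde(grid), "-")
    return ax
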