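"""Plots of the fitted familiarity-vs-pulling relationship."""

from __future__ import annotations

import numpy as np


def plot_fit(results, band=None, perf=None, ax=None):
    """Scatter of per-participant (rho, f_c) with the fitted rectified
    exponential-binomial curve and, optionally, its confidence band.

    Parameters
    ----------
    results : REBResults
    band : CIBand, optional
    perf : DataFrame with ``rho`` and ``f_c`` columns, optional
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    grid = band.rho_grid if band is not None else np.linspace(-0.2, 1.0, 121)
    if band is not None:
        ax.fill_between(grid, band.lower, band.upper, color="red", alpha=0.2, lw=0)
    ax.plot(grid, results.predict(grid), color="red", lw=2, label="model fit")
    if perf is not None:
        ax.plot(perf["rho"], perf["f_c"], "ko", ms=5, label="participants")
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    ax.axvline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel(r"haptic pulling performance $\rho$")
    ax.set_ylabel("visual familiarity (fraction correct)")
    ax.set_ylim(0.35, 1.02)
    ax.legend(frameon=False, loc="lower right")
    return ax
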