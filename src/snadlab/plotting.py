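"""Simple diagnostic figures: assay time courses and pH-activity profiles."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_assay_fit", "plot_ph_profile"]

_SPECIES_STYLE = {"TAN": "tab:blue", "TNN": "tab:orange", "NO3N": "tab:green"}


def plot_assay_fit(results, ax=None):
    """Measured concentrations with the fitted OLS lines for one bottle.

    ``results`` is a :class:`~snadlab.assay.BatchAssayResults`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    series = results.series
    for sp, est in sorted(results.rates.items()):
        color = _SPECIES_STYLE.get(sp)
        ax.plot(series.times, series.concentrations[sp], "o", color=color, label=sp)
        t0, t1 = est.window
        tt = np.array([t0, t1])
        c0 = series.concentrations[sp][series.times >= t0][0]
        ax.plot(tt, c0 + est.slope / 60.0 * (tt - t0), "-", color=color, alpha=0.6)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (mg N/L)")
    ax.set_title(series.label or series.assay_type)
    ax.legend()
    return ax


def plot_ph_profile(profile: dict[float, float], ax=None, ylabel: str = "activity"):
    """Activity versus pH, marking the grid optimum."""
    import matplotlib.pyplot as plt

    from .assay import ph_optimum

    if ax is None:
        _, ax = plt.subplots()
    phs = sorted(profile)
    ax.plot(phs, [profile[p] for p in phs], "o-")
    best, flag = ph_optimum(profile)
    ax.axvline(best, ls="--", color="grey", alpha=0.7)
    ax.annotate(f"optimum pH {best} ({flag})", (best, profile[best]),
                textcoords="offset points", xytext=(5, 5))
    ax.set_xlabel("pH")
    ax.set_ylabel(ylabel)
    return ax
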