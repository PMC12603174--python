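"""Diagnostic and reporting figures (matplotlib, non-interactive backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import PSADrawMatrix, ceac as _ceac

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado", "plot_survival_fits"]


def plot_ce_plane(matrix: PSADrawMatrix, wtp: float, ax=None):
    """Incremental cost-effectiveness plane with the WTP threshold line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    de, dc = matrix.delta_effect, matrix.delta_cost
    ax.scatter(de, dc, s=4, alpha=0.3, linewidths=0)
    lim = max(abs(de).max() * 1.1, 1e-6)
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, wtp * xs, "--", color="grey", label=f"WTP NT${wtp:,.0f}/QALY")
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (NT$)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_ceac(matrix: PSADrawMatrix, wtp_grid, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    curve = _ceac(matrix, wtp_grid)
    ax.plot(curve["wtp"], curve["p_cost_effective"])
    ax.set_xlabel("Willingness to pay (NT$/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    return ax


def plot_tornado(dsa_table, top=12, ax=None):
    """Horizontal INMB-range bars, widest at the top."""
    df = dsa_table.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1))
    base = 0.5 * (df["INMB_low"] + df["INMB_high"])
    ax.barh(df["parameter"], df["INMB_high"] - df["INMB_low"], left=df["INMB_low"],
            color="#4878cf", alpha=0.8)
    ax.axvline(float(base.iloc[-1]), color="grey", lw=0.6)
    ax.set_xlabel("INMB (NT$)")
    return ax


def plot_survival_fits(data, fits, t_max=None, ax=None):
    """Kaplan-Meier of one transition dataset with fitted curves overlaid
    (the visual companion to AIC/BIC selection)."""
    from lifelines import KaplanMeierFitter

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    km = KaplanMeierFitter()
    km.fit(data.times, event_observed=data.events)
    km.plot_survival_function(ax=ax, ci_show=True, color="black", label="Kaplan-Meier")
    t_max = t_max or float(data.times.max()) * 1.5
    grid = np.linspace(1e-6, t_max, 200)
    for m in fits:
        ax.plot(grid, m.sf(grid), lw=1.2, label=f"{m.family.name} (AIC {m.aic:.1f})")
    ax.set_xlabel("Years since state entry")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    return ax
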