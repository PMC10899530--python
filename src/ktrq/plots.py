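"""Basic QC plots: trace ensembles, dose-response, Bland-Altman."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .responder import DoseResponseFit
from .tissue import BlandAltmanResult
from .traces import TraceSet

__all__ = ["plot_traces", "plot_dose_response", "plot_bland_altman"]


def plot_traces(traces: TraceSet, max_cells: int = 50, ax=None):
    """Spaghetti plot of per-cell activity with the ensemble mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    _, act, valid = traces.to_matrix()
    t = traces.schedule.times / 60.0
    shown = act[:max_cells]
    for row in shown:
        ax.plot(t, row, color="gray", alpha=0.25, lw=0.6)
    masked = np.where(valid, act, np.nan)
    ax.plot(t, np.nanmean(masked, axis=0), color="crimson", lw=2,
            label="ensemble mean")
    ax.axvline(traces.schedule.treatment_time / 60.0, ls="--", color="k",
               lw=0.8, label="ligand")
    ax.axvline(traces.schedule.meki_time / 60.0, ls=":", color="k",
               lw=0.8, label="MEKi")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("ERK activity (cyt/nuc ratio)")
    ax.legend(frameon=False)
    return ax


def plot_dose_response(fit: DoseResponseFit, ax=None):
    """Observed responder fractions with CIs and the fitted Hill curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    yerr = np.vstack([fit.fractions - fit.ci_low,
                      fit.ci_high - fit.fractions])
    ax.errorbar(fit.doses, fit.fractions, yerr=yerr, fmt="o", color="k",
                capsize=3, label="observed")
    grid = np.geomspace(fit.doses.min(), fit.doses.max(), 100)
    ax.plot(grid, fit.predict(grid), color="crimson",
            label=f"fit: EC50={fit.ec50:.1f} ng/mL")
    ax.set_xscale("log")
    ax.set_xlabel("dose (ng/mL)")
    ax.set_ylabel("responder fraction")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax


def plot_bland_altman(manual, automated, result: BlandAltmanResult, ax=None):
    """Difference-versus-mean plot with bias and limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    mean = (manual + automated) / 2
    diff = automated - manual
    ax.scatter(mean, diff, s=18, color="k")
    for y, style in ((result.bias, "-"), (result.loa_low, "--"),
                     (result.loa_high, "--")):
        ax.axhline(y, ls=style, color="crimson", lw=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("automated - manual")
    return ax
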