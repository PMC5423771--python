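"""Generic diagnostic plots: length-speed scatter, MSD curves, FRAP traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

from .frap import FRAPFit, FRAPRecord
from .motion import MSDCurve

__all__ = ["plot_speed_vs_length", "plot_msd", "plot_frap"]

_CLASS_COLORS = {"S": "tab:blue", "M": "tab:green", "L": "tab:red"}


def plot_speed_vs_length(summaries: pd.DataFrame, ax=None):
    """Scatter of maximum speed against trajectory length, colored by class."""
    if ax is None:
        _, ax = plt.subplots()
    for cls, g in summaries.groupby("length_class"):
        ax.scatter(g["path_length"], g["max_speed"], s=8, alpha=0.6,
                   color=_CLASS_COLORS.get(cls, "gray"), label=cls)
    ax.set_xlabel("trajectory length (µm)")
    ax.set_ylabel("maximum speed (µm/s)")
    ax.legend(title="class", frameon=False)
    return ax


def plot_msd(curve: MSDCurve, fit=None, ax=None):
    """MSD vs lag time, optionally with the fitted diffusion line."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.lags, curve.msd, "o-", ms=4, label="MSD")
    if fit is not None:
        ax.plot(curve.lags, fit.slope * curve.lags + fit.intercept, "--",
                label=f"fit: D = {fit.d_coef:.3g} µm²/s")
        ax.legend(frameon=False)
    ax.set_xlabel("lag τ (s)")
    ax.set_ylabel("MSD (µm²)")
    return ax


def plot_frap(record: FRAPRecord, fit: FRAPFit | None = None, ax=None):
    """Normalized FRAP trace with the bleach point and optional fit overlay."""
    import numpy as np

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(record.times, record.intensity, ".", ms=3, label="ROI intensity")
    ax.axvline(record.times[record.bleach_index], color="k", lw=0.8, ls=":")
    if fit is not None:
        post = record.times[record.bleach_index:]
        t0 = record.times[record.bleach_index]
        model = fit.i0 + (fit.mobile_fraction * (fit.i_pre - fit.i0)) * \
            (1.0 - np.exp(-fit.k * (post - t0)))
        ax.plot(post, model, "r-", lw=1.5,
                label=f"fit: T½ = {fit.t_half:.1f} s, mobile = {fit.mobile_fraction:.2f}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    return ax
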