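"""Simple diagnostic figures for fits and simulations."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .binding import NM, association_curve, dissociation_curve, observed_rate
from .competition import CompetitionTrajectory
from .emsa import TitrationFit, TitrationSeries
from .tracefit import GlobalFitResult, SwitchTrace

__all__ = ["plot_traces", "plot_titration", "plot_competition"]


def plot_traces(
    traces: Sequence[SwitchTrace],
    fit: GlobalFitResult | None = None,
    ax=None,
):
    """Traces as points (hours vs normalized response) with fitted curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, tr in enumerate(traces):
        h = tr.times / 3600.0
        (line,) = ax.plot(
            h, tr.responses, ".", ms=2,
            label=f"{tr.concentration_nM:g} nM ({tr.phase}, spot {tr.spot_id})",
        )
        if fit is not None and i < len(fit.per_trace_curves):
            curve = fit.per_trace_curves[i]
            if tr.phase == "dissociation":
                y = dissociation_curve(tr.times, curve)
            else:
                y = association_curve(tr.times, tr.concentration, fit.rates, curve)
            ax.plot(h, y, "-", color=line.get_color(), lw=1)
    ax.set_xlabel("time [h]")
    ax.set_ylabel("normalized response [%]")
    ax.legend(fontsize="x-small")
    return ax


def plot_titration(series: TitrationSeries, fit: TitrationFit | None = None, ax=None):
    """Semi-log titration: mean fraction bound with replicate SD bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    c_nM = series.concentrations / NM
    ax.errorbar(
        c_nM, series.mean_fractions, yerr=series.sd_fractions, fmt="o", capsize=2
    )
    if fit is not None:
        ax.plot(c_nM, fit.fitted_curve, "-", label=f"K_D = {fit.K_D_nM:.3g} nM")
        ax.legend()
    ax.set_xscale("log")
    ax.set_xlabel("protein concentration [nM]")
    ax.set_ylabel("fraction bound [%]")
    return ax


def plot_competition(traj: CompetitionTrajectory, ax=None):
    """Species concentrations over time plus the visible-complex fraction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h = traj.times / 3600.0
    ax.plot(h, traj.P_free / NM, label="P free")
    for name, pd in traj.PD.items():
        ax.plot(h, pd / NM, label=f"PD ({name})")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("concentration [nM]")
    ax2 = ax.twinx()
    ax2.plot(h, traj.visible_fraction, "k--", lw=1, label="visible complex")
    ax2.set_ylabel("visible complex [% of labeled total]")
    ax.legend(fontsize="x-small")
    return ax
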