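"""Convenience figures: scenario panels and fitted TPCs.

Figures are illustrative outputs; the numeric reports are the tested
artifacts.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .fit import ModelFit
from .translate import figure_scenario

__all__ = ["plot_scenario_panels", "plot_fitted_tpcs"]


def plot_scenario_panels(scenario: dict | None = None, t_range=(0.0, 20.0)):
    """Three panels for the two-population elevation-only scenario:
    absolute growth G(T), proportional growth g(T), population growth r(T)."""
    if scenario is None:
        scenario = figure_scenario()
    T = np.linspace(*t_range, 200)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    styles = {"slow": "-", "fast": "--"}
    for name, pop in scenario.items():
        axes[0].plot(T, pop["G"](T), styles[name], label=f"{name} (alpha={pop['alpha']:g})")
        axes[1].plot(T, pop["g"](T), styles[name])
        axes[2].plot(T, pop["r"](T), styles[name])
    for ax, ylab in zip(axes, ["absolute growth G", "proportional growth g", "population growth r"]):
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel(ylab)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_fitted_tpcs(fit_absolute: ModelFit, fit_proportional: ModelFit,
                     t_range=(12.0, 26.0)):
    """Fitted quadratic TPCs per population on both growth scales."""
    T = np.linspace(*t_range, 200)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, fit, ylab in (
        (axes[0], fit_absolute, "absolute growth (ug/d)"),
        (axes[1], fit_proportional, "proportional growth (1/d)"),
    ):
        effects = fit.to_fixed_effects()
        for pop in effects.populations:
            ax.plot(T, effects.predict(pop, T), label=pop)
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel(ylab)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
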