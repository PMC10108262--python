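"""Serialisation and report rendering for fits and translations."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .fit import FixedStructure, ModelComparison, ModelFit

__all__ = [
    "fit_to_dict",
    "fit_from_dict",
    "comparison_to_dict",
    "render_coefficient_table",
    "write_json",
    "read_json",
]


def fit_to_dict(fit: ModelFit) -> dict:
    """JSON-serialisable view of a single model fit."""
    return {
        "structure": asdict(fit.structure),
        "structure_name": fit.structure.name,
        "method": fit.method,
        "scale": fit.scale,
        "loglik": _num(fit.loglik),
        "k": fit.k,
        "n": fit.n,
        "aicc": _num(fit.aicc),
        "fixed_estimates": {
            name: {"estimate": est, "se": se}
            for name, (est, se) in fit.fixed_estimates.items()
        },
        "random_effects_sd": {
            "clone_intercept": fit.sd_clone_intercept,
            "clone_slope": fit.sd_clone_slope,
            "residual": fit.sd_residual,
        },
        "corr_intercept_slope": fit.corr_intercept_slope,
        "converged": fit.converged,
        "singular": fit.singular,
        "degenerate": fit.degenerate,
        "populations": list(fit.populations),
    }


def fit_from_dict(d: dict) -> ModelFit:
    """Rebuild a :class:`ModelFit` from its JSON form."""
    re_sd = d["random_effects_sd"]
    return ModelFit(
        structure=FixedStructure(**d["structure"]),
        method=d["method"],
        scale=d["scale"],
        loglik=d["loglik"] if d["loglik"] is not None else float("nan"),
        k=d["k"],
        n=d["n"],
        aicc=d["aicc"] if d["aicc"] is not None else float("nan"),
        fixed_estimates={
            name: (v["estimate"], v["se"]) for name, v in d["fixed_estimates"].items()
        },
        sd_clone_intercept=re_sd["clone_intercept"],
        sd_clone_slope=re_sd["clone_slope"],
        corr_intercept_slope=d["corr_intercept_slope"],
        sd_residual=re_sd["residual"],
        converged=d["converged"],
        singular=d["singular"],
        degenerate=d["degenerate"],
        populations=tuple(d["populations"]),
    )


def comparison_to_dict(comparison: ModelComparison) -> dict:
    """JSON-serialisable view of an AICc model comparison."""
    return {
        "candidates": [
            {**fit_to_dict(f), "delta_aicc": _num(delta)}
            for f, delta in zip(comparison.fits, comparison.delta_aicc)
        ],
        "best_structure": comparison.best_ml.structure.name,
        "best_ml": fit_to_dict(comparison.best_ml),
        "best_reml": fit_to_dict(comparison.best_reml),
    }


_TERM_LABELS = {"intercept": "Intercept", "T": "Temperature", "T2": "Temperature^2"}


def render_coefficient_table(
    fit_absolute: ModelFit, fit_proportional: ModelFit
) -> pd.DataFrame:
    """Side-by-side coefficient table for the two growth scales.

    Rows are fixed terms by population (Intercept, Temperature,
    Temperature^2) followed by random-effect SD rows (clone intercept,
    clone temperature slope, residual); columns hold estimate and SE per
    scale.  Per-population direct estimates, not contrasts.
    """
    if set(fit_absolute.populations) != set(fit_proportional.populations):
        raise ValueError(
            "population sets differ between fits: "
            f"{fit_absolute.populations} vs {fit_proportional.populations}"
        )
    rows = []
    for term in ("intercept", "T", "T2"):
        for pop in fit_absolute.populations:
            key_pop, key_common = f"{term}_{pop}", term
            row = {"term": _TERM_LABELS[term], "population": pop}
            for label, fit in (("absolute", fit_absolute), ("proportional", fit_proportional)):
                est_se = fit.fixed_estimates.get(
                    key_pop, fit.fixed_estimates.get(key_common, (0.0, np.nan))
                )
                row[f"{label}_estimate"], row[f"{label}_se"] = est_se
            rows.append(row)
    for label, attr in (
        ("Clone", "sd_clone_intercept"),
        ("Temperature|Clone", "sd_clone_slope"),
        ("Residual", "sd_residual"),
    ):
        rows.append(
            {
                "term": f"Random effect SD: {label}",
                "population": "",
                "absolute_estimate": getattr(fit_absolute, attr),
                "absolute_se": np.nan,
                "proportional_estimate": getattr(fit_proportional, attr),
                "proportional_se": np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_json(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _num(x):
    """NaN/inf-safe number for JSON."""
    x = float(x)
    return None if not np.isfinite(x) else x
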