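"""Per-population quadratic TPC fitting with clone-level random effects.

The statistical model is a Gaussian linear mixed model for a growth rate
(absolute or proportional) observed on individuals nested in clones nested
in populations.  Fixed effects are population-specific quadratic
polynomials in temperature centered at 12 C, so that each population's
intercept is its growth rate at 12 C.  Clone enters as a random intercept
and a random slope on the linear (centered) temperature term.  Candidate
fixed-effect structures are compared by AICc under maximum likelihood and
the winner is refit by REML for parameter reporting — the standard
``lmer`` + AICc workflow for reaction-norm experiments.

Per-population coefficients are reported as direct estimates (not
contrasts): when a population effect is present the design matrix carries
one indicator column per population rather than a reference level plus
contrasts.  This reparameterisation leaves the likelihood, and therefore
AICc comparisons, unchanged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "CENTER_TEMPERATURE",
    "TPCFixedEffects",
    "DEFAULT_ABSOLUTE_EFFECTS",
    "DEFAULT_PROPORTIONAL_EFFECTS",
    "FixedStructure",
    "FULL_STRUCTURE",
    "ModelFit",
    "ModelComparison",
    "build_candidate_set",
    "build_design_matrix",
    "fit_mixed_model",
    "aicc",
    "select_best",
    "predict_tpc",
]

#: Temperature (C) at which the polynomial is centered; intercepts are
#: growth rates at this temperature.
CENTER_TEMPERATURE = 12.0


@dataclass(frozen=True)
class TPCFixedEffects:
    """Per-population quadratic TPC coefficients on a named growth scale.

    ``coefficients`` maps population label -> (intercept, linear, quadratic)
    in centered temperature ``Tc = T - center_temperature``.  The intercept
    is in growth units (ug/d for the absolute scale, 1/d for the
    proportional scale), the linear term in growth units per C, the
    quadratic term per C^2.
    """

    scale: str
    coefficients: Mapping[str, tuple[float, float, float]]
    center_temperature: float = CENTER_TEMPERATURE

    def __post_init__(self) -> None:
        if self.scale not in ("absolute", "proportional"):
            raise ValueError(f"scale must be 'absolute' or 'proportional', got {self.scale!r}")
        for pop, coefs in self.coefficients.items():
            if len(coefs) != 3 or not all(np.isfinite(coefs)):
                raise ValueError(f"population {pop!r} needs three finite coefficients, got {coefs}")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, population: str, temperature) -> float:
        """Evaluate the quadratic TPC at temperature(s) in C."""
        a, b, c = self.coefficients[population]
        tc = np.asarray(temperature, dtype=float) - self.center_temperature
        out = a + b * tc + c * tc ** 2
        return out.item() if np.isscalar(temperature) else out


# REML estimates for the three-population D. magna common-garden study
# (Norway 67.7N, Belgium 51.0N, Spain 40.7N); the default generating
# values for parameter-recovery simulations.
DEFAULT_ABSOLUTE_EFFECTS = TPCFixedEffects(
    scale="absolute",
    coefficients={
        "Norway": (3.803, 0.794, -0.021),
        "Belgium": (1.388, 0.203, 0.011),
        "Spain": (1.627, 0.139, 0.016),
    },
)

DEFAULT_PROPORTIONAL_EFFECTS = TPCFixedEffects(
    scale="proportional",
    coefficients={
        "Norway": (0.1674, 0.0235, -0.0002),
        "Belgium": (0.0830, 0.0120, 0.0006),
        "Spain": (0.0922, 0.0118, 0.0008),
    },
)


@dataclass(frozen=True, order=True)
class FixedStructure:
    """Inclusion flags for the candidate fixed-effect terms.

    Marginality is enforced: the quadratic term requires the linear term,
    each interaction requires both its main effects, and the
    population-by-quadratic interaction additionally requires the
    population-by-linear interaction.
    """

    population: bool = False
    linear: bool = False
    quadratic: bool = False
    pop_by_linear: bool = False
    pop_by_quadratic: bool = False

    def __post_init__(self) -> None:
        if self.quadratic and not self.linear:
            raise ValueError("quadratic term requires the linear term")
        if self.pop_by_linear and not (self.population and self.linear):
            raise ValueError("population x T requires population and T main effects")
        if self.pop_by_quadratic and not (self.pop_by_linear and self.quadratic):
            raise ValueError("population x T^2 requires population x T and T^2")

    @property
    def name(self) -> str:
        parts = ["1"]
        if self.population:
            parts.append("pop")
        if self.linear:
            parts.append("T")
        if self.quadratic:
            parts.append("T2")
        if self.pop_by_linear:
            parts.append("pop:T")
        if self.pop_by_quadratic:
            parts.append("pop:T2")
        return " + ".join(parts)


FULL_STRUCTURE = FixedStructure(True, True, True, True, True)


def build_candidate_set() -> list[FixedStructure]:
    """All marginality-respecting fixed-effect structures.

    Enumerates the 2^5 flag combinations and keeps the valid ones; includes
    the intercept-only model and the full model.
    """
    out = []
    for flags in itertools.product([False, True], repeat=5):
        try:
            out.append(FixedStructure(*flags))
        except ValueError:
            continue
    return out


def build_design_matrix(table: pd.DataFrame, structure: FixedStructure) -> pd.DataFrame:
    """Fixed-effect design matrix with direct per-population coding.

    With a population effect the intercept block is one indicator column
    per population (no global intercept); with a population-by-temperature
    interaction the temperature block is one centered-temperature column
    per population.  Columns are named ``intercept[_pop]``, ``T[_pop]``,
    ``T2[_pop]``.
    """
    pops = sorted(table["population"].unique())
    tc = table["temperature_C"].to_numpy(dtype=float) - CENTER_TEMPERATURE
    cols: dict[str, np.ndarray] = {}
    if structure.population:
        for p in pops:
            cols[f"intercept_{p}"] = (table["population"] == p).to_numpy(dtype=float)
    else:
        cols["intercept"] = np.ones(len(table))
    if structure.pop_by_linear:
        for p in pops:
            cols[f"T_{p}"] = cols[f"intercept_{p}"] * tc
    elif structure.linear:
        cols["T"] = tc
    if structure.pop_by_quadratic:
        for p in pops:
            cols[f"T2_{p}"] = cols[f"intercept_{p}"] * tc ** 2
    elif structure.quadratic:
        cols["T2"] = tc ** 2
    return pd.DataFrame(cols, index=table.index)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike Information Criterion with small-sample correction.

    ``AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelFit:
    """One fitted candidate: structure, likelihood, AICc and estimates.

    ``fixed_estimates`` maps design-column name -> (estimate, SE), with
    per-population direct estimates whenever the structure includes the
    population effect.  ``k`` counts fixed coefficients plus
    variance/covariance parameters (clone intercept variance, clone slope
    variance, their covariance when estimated) plus the residual variance.
    """

    structure: FixedStructure
    method: str
    scale: str
    loglik: float
    k: int
    n: int
    aicc: float
    fixed_estimates: dict[str, tuple[float, float]]
    sd_clone_intercept: float
    sd_clone_slope: float
    corr_intercept_slope: float
    sd_residual: float
    converged: bool
    singular: bool = False
    degenerate: bool = False
    populations: tuple[str, ...] = ()

    def to_fixed_effects(self) -> TPCFixedEffects:
        """Collapse estimates to per-population quadratic coefficients.

        Common (non-interaction) terms are shared across populations;
        absent terms contribute zero.
        """
        est = {name: v[0] for name, v in self.fixed_estimates.items()}
        coefs = {}
        for p in self.populations:
            a = est.get(f"intercept_{p}", est.get("intercept", 0.0))
            b = est.get(f"T_{p}", est.get("T", 0.0))
            c = est.get(f"T2_{p}", est.get("T2", 0.0))
            coefs[p] = (a, b, c)
        return TPCFixedEffects(scale=self.scale, coefficients=coefs)


@dataclass
class ModelComparison:
    """Candidates sorted by AICc, with the best refit by REML."""

    fits: list[ModelFit]
    delta_aicc: list[float]
    best_ml: ModelFit
    best_reml: ModelFit


def _validate_rate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"population", "clone", "temperature_C", "growth_rate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"rate table missing required columns: {sorted(missing)}")
    table = table.dropna(subset=["growth_rate"])
    if table["clone"].nunique() < 2:
        raise ValueError("need at least 2 clones to estimate clone-level variance")
    if table["temperature_C"].nunique() < 2:
        raise ValueError("need at least 2 temperatures to estimate a temperature slope")
    return table


def fit_mixed_model(
    table: pd.DataFrame,
    structure: FixedStructure = FULL_STRUCTURE,
    method: str = "REML",
    estimate_correlation: bool = True,
) -> ModelFit:
    """Fit one candidate structure by ML or REML.

    The random-effect structure is fixed across candidates: a clone random
    intercept and a clone random slope on centered temperature, with their
    correlation estimated by default (set ``estimate_correlation=False``
    to constrain it to zero).  A non-convergent first attempt is retried
    with alternative optimizers before being flagged.

    Data whose residuals are numerically zero (e.g. simulated with all
    noise SDs zero) are handled by ordinary least squares, which is exact
    there; the likelihood is degenerate and reported as NaN.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    table = _validate_rate_table(table)
    scale = str(table["scale"].iloc[0]) if "scale" in table.columns else "unknown"
    pops = tuple(sorted(table["population"].unique()))
    X = build_design_matrix(table, structure)
    y = table["growth_rate"].to_numpy(dtype=float)
    n = len(y)

    beta, ssr, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid_ms = float(np.sum((y - X.to_numpy() @ beta) ** 2) / n)
    if resid_ms < 1e-24 + 1e-16 * float(np.var(y)):
        # exactly-deterministic data: GLS of any weighting reproduces the
        # generating surface, and the Gaussian likelihood is unbounded
        est = {name: (float(b), 0.0) for name, b in zip(X.columns, beta)}
        return ModelFit(
            structure=structure, method=method, scale=scale,
            loglik=float("nan"), k=X.shape[1] + 1, n=n, aicc=float("nan"),
            fixed_estimates=est, sd_clone_intercept=0.0, sd_clone_slope=0.0,
            corr_intercept_slope=0.0, sd_residual=0.0,
            converged=True, degenerate=True, populations=pops,
        )

    tc = table["temperature_C"].to_numpy(dtype=float) - CENTER_TEMPERATURE
    exog_re = np.column_stack([np.ones(n), tc])
    model = sm.MixedLM(y, X.to_numpy(), groups=table["clone"].to_numpy(), exog_re=exog_re)
    free = None
    if not estimate_correlation:
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
        )

    reml = method == "REML"
    result, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for fit_method in ["lbfgs", "cg", "powell", "bfgs"]:
            try:
                kwargs = dict(reml=reml, method=fit_method)
                if free is not None:
                    kwargs["free"] = free
                candidate = model.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            result = candidate
            if candidate.converged:
                converged = True
                break
    if result is None:
        raise RuntimeError(f"mixed model failed to fit for structure {structure.name}")

    k_fe = X.shape[1]
    k_var = 3 if estimate_correlation else 2
    k = k_fe + k_var + 1
    cov_re = np.asarray(result.cov_re)
    v_int, v_slope = cov_re[0, 0], cov_re[1, 1]
    corr = 0.0
    if estimate_correlation and v_int > 0 and v_slope > 0:
        corr = float(cov_re[0, 1] / np.sqrt(v_int * v_slope))
    eigvals = np.linalg.eigvalsh(cov_re)
    singular = bool(eigvals.min() < 1e-10 * max(eigvals.max(), 1e-30))
    fe = np.asarray(result.fe_params, dtype=float)
    se = np.asarray(result.bse[:k_fe], dtype=float)
    return ModelFit(
        structure=structure, method=method, scale=scale,
        loglik=float(result.llf), k=k, n=n,
        aicc=aicc(float(result.llf), k, n),
        fixed_estimates={name: (float(b), float(s)) for name, b, s in zip(X.columns, fe, se)},
        sd_clone_intercept=float(np.sqrt(max(v_int, 0.0))),
        sd_clone_slope=float(np.sqrt(max(v_slope, 0.0))),
        corr_intercept_slope=corr,
        sd_residual=float(np.sqrt(result.scale)),
        converged=converged, singular=singular, populations=pops,
    )


def select_best(table: pd.DataFrame, estimate_correlation: bool = True) -> ModelComparison:
    """Fit every candidate by ML, rank by AICc, refit the winner by REML.

    Non-convergent candidates stay in the comparison table, flagged, but
    are excluded when choosing the best structure.
    """
    fits = [
        fit_mixed_model(table, s, method="ML", estimate_correlation=estimate_correlation)
        for s in build_candidate_set()
    ]
    fits.sort(key=lambda f: (np.inf if np.isnan(f.aicc) else f.aicc))
    usable = [f for f in fits if f.converged and not np.isnan(f.aicc)]
    if not usable:
        raise RuntimeError("no candidate model converged")
    best = usable[0]
    base = best.aicc
    delta = [f.aicc - base for f in fits]
    best_reml = fit_mixed_model(
        table, best.structure, method="REML", estimate_correlation=estimate_correlation
    )
    return ModelComparison(fits=fits, delta_aicc=delta, best_ml=best, best_reml=best_reml)


def predict_tpc(
    fit: "ModelFit | TPCFixedEffects",
    population: str,
    temperature,
    guard: tuple[float, float] = (12.0, 26.0),
):
    """Evaluate a fitted TPC for one population at temperature(s) in C.

    Warns (but does not fail) outside the extrapolation guard, which
    defaults to the experimental range 12-26 C.
    """
    effects = fit.to_fixed_effects() if isinstance(fit, ModelFit) else fit
    if population not in effects.coefficients:
        raise KeyError(f"unknown population {population!r}; have {list(effects.coefficients)}")
    t = np.asarray(temperature, dtype=float)
    if np.any(t < guard[0]) or np.any(t > guard[1]):
        warnings.warn(
            f"temperature outside the fitted range {guard}; extrapolating", stacklevel=2
        )
    return effects.predict(population, temperature)
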