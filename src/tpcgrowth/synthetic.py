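"""Seeded synthetic data with the common-garden experiment's structure.

Emulates a three-population *Daphnia magna* growth assay: 10 clones per
population, 7 temperatures (12-26 C), 8 individuals per clone per
temperature (1680 animals).  Two levels of simulation are provided:

* ``generate_growth_table`` draws growth *rates* directly from the
  hierarchical Gaussian model assumed by the mixed-effects analysis —
  population-specific quadratic fixed effects in centered temperature,
  clone random intercepts and random linear-temperature slopes, and
  i.i.d. Gaussian residuals.  This is the input for parameter-recovery
  studies.

* ``generate_individual_records`` inverts the measurement chain to
  individual *records* (neonate and mature gut lengths, age at maturity):
  a latent proportional growth rate is drawn from the same rate model,
  an age at maturity is drawn from a configurable maturity model, and gut
  lengths are obtained through the dry-mass allometry.  Recomputing the
  growth rate from a record recovers the latent rate exactly, so these
  records exercise the full measurement pipeline end to end.

Only one scale is ever the generating truth: a quadratic TPC cannot hold
exactly on the absolute and the proportional scale at the same time, as
the two are non-linearly linked through mass and time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .fit import (
    DEFAULT_ABSOLUTE_EFFECTS,
    DEFAULT_PROPORTIONAL_EFFECTS,
    TPCFixedEffects,
)
from .growth import AllometryParams, DEFAULT_ALLOMETRY, dry_mass_from_gut_length, gut_length_from_dry_mass

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "GeneratingModel",
    "SchemaError",
    "default_proportional_model",
    "default_absolute_model",
    "default_maturity_model",
    "generate_growth_table",
    "generate_individual_records",
    "compute_rate_table",
    "write_records",
    "read_records",
    "write_rate_table",
    "read_rate_table",
    "RECORD_COLUMNS",
    "RATE_COLUMNS",
]

RECORD_COLUMNS = [
    "population",
    "clone",
    "temperature_C",
    "gut_length_neonate_mm",
    "gut_length_mature_mm",
    "age_at_maturity_days",
    "survived",
]

RATE_COLUMNS = ["population", "clone", "temperature_C", "growth_rate", "scale"]


class SchemaError(ValueError):
    """A delimited-text table is missing a required column."""


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout: populations x clones x temperatures x replicates."""

    populations: tuple[str, ...] = ("Norway", "Belgium", "Spain")
    clones_per_population: int = 10
    temperatures: tuple[float, ...] = (12.0, 15.0, 17.0, 19.0, 22.0, 24.0, 26.0)
    replicates_per_clone_per_temperature: int = 8

    def __post_init__(self) -> None:
        if len(self.populations) < 1 or self.clones_per_population < 1:
            raise ValueError("need at least one population and one clone")
        if self.replicates_per_clone_per_temperature < 1:
            raise ValueError("need at least one replicate")
        temps = np.asarray(self.temperatures, dtype=float)
        if len(temps) < 1 or np.any(np.diff(temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return (
            len(self.populations)
            * self.clones_per_population
            * len(self.temperatures)
            * self.replicates_per_clone_per_temperature
        )

    def clone_labels(self, population: str) -> list[str]:
        return [f"{population}-c{i + 1:02d}" for i in range(self.clones_per_population)]


@dataclass(frozen=True)
class GeneratingModel:
    """Hierarchical Gaussian model that drives the simulation.

    Clone deviations (intercept, linear-temperature slope) are drawn once
    per clone from a bivariate normal with the given SDs and correlation,
    and shared across all of that clone's temperatures and replicates.
    Residuals are i.i.d. Gaussian per individual.
    """

    fixed: TPCFixedEffects
    sd_clone_intercept: float
    sd_clone_slope: float
    sd_residual: float
    corr_intercept_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd_clone_intercept", "sd_clone_slope", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.corr_intercept_slope) > 1:
            raise ValueError("|corr_intercept_slope| must be <= 1")

    @property
    def scale(self) -> str:
        return self.fixed.scale

    def clone_covariance(self) -> np.ndarray:
        cov = self.corr_intercept_slope * self.sd_clone_intercept * self.sd_clone_slope
        return np.array(
            [[self.sd_clone_intercept ** 2, cov], [cov, self.sd_clone_slope ** 2]]
        )


def default_proportional_model() -> GeneratingModel:
    """Generating values on the proportional scale (1/d).

    Fixed effects and clone SDs are the study's REML estimates; the
    residual SD (0.02 1/d) is not reported there and is chosen so that
    simulated fixed-effect SEs match the reported order of magnitude.
    """
    return GeneratingModel(
        fixed=DEFAULT_PROPORTIONAL_EFFECTS,
        sd_clone_intercept=0.0019,
        sd_clone_slope=0.0023,
        sd_residual=0.02,
    )


def default_absolute_model() -> GeneratingModel:
    """Generating values on the absolute scale (ug/d); residual SD 0.5."""
    return GeneratingModel(
        fixed=DEFAULT_ABSOLUTE_EFFECTS,
        sd_clone_intercept=0.072,
        sd_clone_slope=0.055,
        sd_residual=0.5,
    )


def generate_growth_table(
    design: StudyDesign, model: GeneratingModel, seed: int
) -> pd.DataFrame:
    """Simulate growth rates at the individual level.

    Returns one row per individual with columns ``population, clone,
    temperature_C, growth_rate, scale``.  Identical ``(design, model,
    seed)`` produce identical tables.
    """
    missing = [p for p in design.populations if p not in model.fixed.coefficients]
    if missing:
        raise ValueError(f"model.fixed lacks coefficients for populations: {missing}")
    rng = np.random.default_rng(seed)
    cov = model.clone_covariance()
    center = model.fixed.center_temperature
    rows = []
    for pop in design.populations:
        a, b, c = model.fixed.coefficients[pop]
        for clone in design.clone_labels(pop):
            dev_int, dev_slope = rng.multivariate_normal([0.0, 0.0], cov)
            for temp in design.temperatures:
                tc = temp - center
                mu = a + b * tc + c * tc ** 2 + dev_int + dev_slope * tc
                eps = rng.normal(0.0, model.sd_residual,
                                 design.replicates_per_clone_per_temperature)
                for e in eps:
                    rows.append((pop, clone, temp, mu + e, model.scale))
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def default_maturity_model(temperature: float) -> float:
    """Mean age at maturity (d), decreasing linearly from 25 d at 12 C to
    8 d at 26 C.

    An invented, deliberately simple development model: it produces
    plausible record-level fixtures but is not an estimate from data.
    """
    return 25.0 + (8.0 - 25.0) * (temperature - 12.0) / 14.0


def generate_individual_records(
    design: StudyDesign,
    model: GeneratingModel,
    seed: int,
    maturity_model: Callable[[float], float] = default_maturity_model,
    allometry: AllometryParams = DEFAULT_ALLOMETRY,
    neonate_gut_length_mm: float = 0.4,
    age_cv: float = 0.10,
    dropout_probability: float = 0.0,
) -> pd.DataFrame:
    """Simulate individual measurement records.

    For each animal a latent proportional growth rate ``g`` is drawn from
    the rate-level model, an age at maturity from a lognormal around
    ``maturity_model(T)`` (CV ``age_cv``), and the mature gut length is
    back-computed from ``M_mature = M_neonate * exp(g * age)`` through the
    allometry.  Optional dropout marks animals as non-survivors
    (missing-completely-at-random) and blanks their mature measurements.
    """
    if model.scale != "proportional":
        raise ValueError("individual records are generated from a proportional-scale model")
    if not 0 <= dropout_probability < 1:
        raise ValueError("dropout_probability must be in [0, 1)")
    for t in design.temperatures:
        if maturity_model(t) <= 0:
            raise ValueError(f"maturity model returns non-positive mean age at T = {t}")

    table = generate_growth_table(design, model, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n = len(table)
    mean_age = np.array([maturity_model(t) for t in table["temperature_C"]])
    sigma = np.sqrt(np.log1p(age_cv ** 2))
    ages = rng.lognormal(np.log(mean_age) - sigma ** 2 / 2.0, sigma, n)
    m_neonate = dry_mass_from_gut_length(neonate_gut_length_mm, allometry)
    m_mature = m_neonate * np.exp(table["growth_rate"].to_numpy() * ages)
    gl_mature = gut_length_from_dry_mass(m_mature, allometry)
    survived = rng.random(n) >= dropout_probability

    records = pd.DataFrame(
        {
            "population": table["population"],
            "clone": table["clone"],
            "temperature_C": table["temperature_C"],
            "gut_length_neonate_mm": neonate_gut_length_mm,
            "gut_length_mature_mm": gl_mature,
            "age_at_maturity_days": ages,
            "survived": survived,
        }
    )
    records.loc[~survived, ["gut_length_mature_mm", "age_at_maturity_days"]] = np.nan
    return records


def compute_rate_table(
    records: pd.DataFrame,
    scale: str = "proportional",
    allometry: AllometryParams = DEFAULT_ALLOMETRY,
) -> pd.DataFrame:
    """Growth rates from measurement records (survivors only).

    ``scale='proportional'`` gives ``ln(M_mature/M_neonate)/age`` in 1/d;
    ``scale='absolute'`` gives ``(M_mature - M_neonate)/age`` in ug/d.
    """
    if scale not in ("absolute", "proportional"):
        raise ValueError(f"scale must be 'absolute' or 'proportional', got {scale!r}")
    surv = records[records["survived"].astype(bool)].copy()
    m0 = dry_mass_from_gut_length(surv["gut_length_neonate_mm"].to_numpy(), allometry)
    m1 = dry_mass_from_gut_length(surv["gut_length_mature_mm"].to_numpy(), allometry)
    age = surv["age_at_maturity_days"].to_numpy(dtype=float)
    if scale == "proportional":
        rate = np.log(m1 / m0) / age
    else:
        rate = (m1 - m0) / age * 1000.0
    return pd.DataFrame(
        {
            "population": surv["population"].to_numpy(),
            "clone": surv["clone"].to_numpy(),
            "temperature_C": surv["temperature_C"].to_numpy(),
            "growth_rate": rate,
            "scale": scale,
        }
    )


def _check_columns(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.info("%s: ignoring extra column(s) %s", path, extra)
    return df[required]


def write_records(records: pd.DataFrame, path) -> None:
    """Write individual records as UTF-8 CSV with one header row."""
    _check_columns(records, RECORD_COLUMNS, path).to_csv(path, index=False)


def read_records(path, validate: bool = True) -> pd.DataFrame:
    """Read an individual-records CSV.

    Unknown columns (e.g. from a richer archive schema) are ignored with a
    logged notice; missing required columns raise :class:`SchemaError`
    naming them.  ``validate`` checks basic measurement invariants on
    survivors (positive gut lengths and ages, mature > neonate).
    """
    df = pd.read_csv(path)
    df = _check_columns(df, RECORD_COLUMNS, path)
    df["survived"] = df["survived"].astype(bool)
    if validate and len(df):
        if (df["gut_length_neonate_mm"] <= 0).any():
            raise ValueError(f"{path}: non-positive neonate gut length")
        surv = df[df["survived"]]
        if (surv["gut_length_mature_mm"] <= surv["gut_length_neonate_mm"]).any():
            raise ValueError(f"{path}: survivor with mature gut length <= neonate gut length")
        if (surv["age_at_maturity_days"] <= 0).any():
            raise ValueError(f"{path}: non-positive age at maturity")
    return df


def write_rate_table(table: pd.DataFrame, path) -> None:
    """Write a growth-rate table as UTF-8 CSV."""
    _check_columns(table, RATE_COLUMNS, path).to_csv(path, index=False)


def read_rate_table(path) -> pd.DataFrame:
    """Read a growth-rate CSV; extra columns ignored, missing ones fatal."""
    return _check_columns(pd.read_csv(path), RATE_COLUMNS, path)
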