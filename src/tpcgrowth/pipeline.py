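"""End-to-end pipeline: simulate -> rates -> fit -> translate -> report.

Each stage reads and writes plain-text artifacts (CSV for tables, JSON for
fits and translation reports) so any suffix of the pipeline can be run
from files produced earlier, by this package or by hand.  Every run writes
a manifest recording the configuration, the seed and the package version,
so each artifact can be regenerated from its manifest alone.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .fit import ModelFit, select_best
from .report import (
    comparison_to_dict,
    render_coefficient_table,
    write_json,
)
from .synthetic import (
    GeneratingModel,
    StudyDesign,
    compute_rate_table,
    default_proportional_model,
    generate_individual_records,
    read_rate_table,
    read_records,
    write_rate_table,
    write_records,
)
from .translate import LinearConversion, classify_adaptation

logger = logging.getLogger(__name__)

__all__ = ["StageError", "STAGE_EXIT_CODES", "run_pipeline", "translate_fit", "write_manifest"]

STAGE_EXIT_CODES = {
    "simulate": 10,
    "compute-rates": 11,
    "fit": 12,
    "translate": 13,
    "report": 14,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an exit code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


def write_manifest(out_dir: Path, stage: str, config: Mapping, artifacts: list[str]) -> Path:
    path = Path(out_dir) / "manifest.json"
    write_json(
        {
            "package": "tpcgrowth",
            "version": __version__,
            "stage": stage,
            "config": dict(config),
            "artifacts": sorted(artifacts),
        },
        path,
    )
    return path


def translate_fit(
    fit: ModelFit,
    conversion: LinearConversion,
    mortality: Mapping[str, float],
    interval: tuple[float, float],
    n_grid: int = 1000,
) -> dict:
    """Population-growth report from a fitted proportional-scale TPC.

    The affine somatic-to-population conversion is applied pointwise to
    each population's fitted quadratic, an optional per-population
    mortality cost is subtracted, and the resulting curves are scanned for
    pairwise crossings and classified.
    """
    if fit.scale != "proportional":
        raise StageError(
            "translate",
            f"population growth requires a proportional-scale fit, got {fit.scale!r}",
        )
    effects = fit.to_fixed_effects()
    curves = {}
    for pop in effects.populations:
        m = float(mortality.get(pop, 0.0))
        curves[pop] = (
            lambda T, _p=pop, _m=m: conversion(effects.predict(_p, np.asarray(T, dtype=float))) - _m
        )
    classification = classify_adaptation(curves, interval, n_grid=n_grid)
    grid = np.linspace(interval[0], interval[1], 101)
    return {
        "interval_C": list(interval),
        "conversion": {"slope": conversion.slope, "intercept": conversion.intercept},
        "mortality": {p: float(mortality.get(p, 0.0)) for p in effects.populations},
        "classification": classification.label,
        "crossing": classification.crossing,
        "pairwise": {
            f"{a}|{b}": {
                "crossings_C": res.crossings,
                "tangencies_C": res.tangencies,
                "identical": res.identical,
                "superior": [
                    {"from_C": lo, "to_C": hi, "population": who}
                    for lo, hi, who in classification.superior[(a, b)]
                ],
            }
            for (a, b), res in classification.pairwise.items()
        },
        "curves": {
            "temperature_C": grid.tolist(),
            **{p: np.asarray(curves[p](grid)).tolist() for p in effects.populations},
        },
    }


def run_pipeline(config: Mapping, out_dir) -> dict[str, Path]:
    """Run simulate -> compute-rates -> fit -> translate -> report.

    ``config`` keys (all optional except ``seed``): ``design`` and
    ``model`` (field overrides for :class:`StudyDesign` and the default
    proportional :class:`GeneratingModel`), ``records`` / ``rates`` (paths
    to start from existing inputs instead of simulating), ``fit``
    (``estimate_correlation``), ``translate`` (``conversion_slope``,
    ``conversion_intercept``, ``mortality`` per population, ``interval``).
    Deterministic given the seed.  Returns artifact paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    config = dict(config)

    # --- simulate ---------------------------------------------------------
    rates_path = config.get("rates")
    records_path = config.get("records")
    if rates_path is None and records_path is None:
        try:
            seed = int(config["seed"])
            design = StudyDesign(**config.get("design", {}))
            model_cfg = dict(config.get("model", {}))
            base = default_proportional_model()
            model = GeneratingModel(
                fixed=base.fixed,
                sd_clone_intercept=model_cfg.get("sd_clone_intercept", base.sd_clone_intercept),
                sd_clone_slope=model_cfg.get("sd_clone_slope", base.sd_clone_slope),
                sd_residual=model_cfg.get("sd_residual", base.sd_residual),
                corr_intercept_slope=model_cfg.get("corr_intercept_slope", 0.0),
            )
            records = generate_individual_records(
                design, model, seed=seed,
                dropout_probability=float(config.get("dropout_probability", 0.0)),
            )
            records_path = out / "records.csv"
            write_records(records, records_path)
        except KeyError as e:
            raise StageError("simulate", f"missing config key {e}") from e
        except (ValueError, TypeError) as e:
            raise StageError("simulate", str(e)) from e

    # --- compute-rates ----------------------------------------------------
    if rates_path is None:
        artifacts["records"] = Path(records_path)
        logger.info("[simulate] records at %s", records_path)
        try:
            records = read_records(records_path)
        except FileNotFoundError as e:
            raise StageError("compute-rates", f"records file not found: {records_path}") from e
        rates = {
            scale: compute_rate_table(records, scale=scale)
            for scale in ("proportional", "absolute")
        }
        rates_path = out / "rates_proportional.csv"
        write_rate_table(rates["proportional"], rates_path)
        write_rate_table(rates["absolute"], out / "rates_absolute.csv")
        artifacts["rates_absolute"] = out / "rates_absolute.csv"
    artifacts["rates"] = Path(rates_path)
    logger.info("[compute-rates] rate tables at %s", rates_path)

    # --- fit --------------------------------------------------------------
    try:
        rate_table = read_rate_table(rates_path)
    except FileNotFoundError as e:
        raise StageError("fit", f"rate table not found: {rates_path}") from e
    try:
        comparison = select_best(
            rate_table,
            estimate_correlation=bool(config.get("fit", {}).get("estimate_correlation", True)),
        )
    except (ValueError, RuntimeError) as e:
        raise StageError("fit", str(e)) from e
    fit_path = out / "fit_proportional.json"
    write_json(comparison_to_dict(comparison), fit_path)
    artifacts["fit"] = fit_path
    logger.info("[fit] best structure: %s", comparison.best_ml.structure.name)

    # --- translate --------------------------------------------------------
    tcfg = dict(config.get("translate", {}))
    conversion = LinearConversion(
        slope=float(tcfg.get("conversion_slope", 0.967)),
        intercept=float(tcfg.get("conversion_intercept", -0.089)),
    )
    interval = tuple(tcfg.get("interval", (12.0, 26.0)))
    translation = translate_fit(
        comparison.best_reml, conversion, tcfg.get("mortality", {}), interval
    )
    translation_path = out / "translation.json"
    write_json(translation, translation_path)
    artifacts["translation"] = translation_path
    logger.info("[translate] classification: %s", translation["classification"])

    # --- report -----------------------------------------------------------
    try:
        from .fit import fit_mixed_model, FULL_STRUCTURE

        abs_table = read_rate_table(out / "rates_absolute.csv") if (out / "rates_absolute.csv").exists() else None
        if abs_table is not None:
            fit_abs = fit_mixed_model(abs_table, FULL_STRUCTURE, method="REML")
            table = render_coefficient_table(fit_abs, comparison.best_reml)
            table_path = out / "coefficient_table.csv"
            table.to_csv(table_path, index=False)
            artifacts["coefficient_table"] = table_path
    except (ValueError, RuntimeError) as e:
        raise StageError("report", str(e)) from e

    artifacts["manifest"] = write_manifest(
        out, "pipeline", config, [str(p) for p in artifacts.values()]
    )
    logger.info("[report] artifacts in %s", out)
    return artifacts
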