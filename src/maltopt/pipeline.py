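"""End-to-end driver: data -> fitted surfaces -> ANOVA -> optimization.

Reproduces the full malting-optimization workflow on the built-in study, a
user CSV, or a synthetic table: fit/select the five response-surface
models, run the lack-of-fit ANOVA, tabulate actual vs predicted responses,
maximize overall desirability by exhaustive grid search and by the genetic
algorithm, and write a consolidated report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from .data import RunTable, STUDY_FACTORS, builtin_study, load_run_table
from .desirability import (
    STUDY_DIRECTIONS,
    grid_search,
    specs_from_table,
)
from .errors import MaltoptError, ValidationError
from .factors import Factor, code, decode
from .ga import GAConfig, run_ga
from .model import (
    PUBLISHED_TERM_SETS,
    PolynomialSurface,
    default_candidates,
    fit_ols,
    select_model,
)
from .simulate import simulate_responses, study_generator

__all__ = ["PipelineConfig", "run_pipeline", "export_surface_grid", "ROUNDING"]

log = logging.getLogger("maltopt.pipeline")

#: Report rounding by response (decimals); D is reported to 3 and 4 dp.
ROUNDING: dict[str, int] = {
    "extract": 1,
    "kolbach_index": 1,
    "attenuation_limit": 1,
    "viscosity": 2,
    "viscosity_65": 2,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run (YAML/JSON serializable)."""

    source: str = "builtin"  # "builtin" | "synthetic" | path to a CSV
    directions: Mapping[str, str] = field(default_factory=lambda: dict(STUDY_DIRECTIONS))
    term_sets: str = "published"  # "published" | "select"
    force_full: tuple[str, ...] = ("attenuation_limit",)
    grid_steps: tuple[float, ...] = (1.0, 1.0, 1.0)
    d_threshold: float = 0.5
    alpha: float = 0.05
    noise_sd: float = 0.3  # synthetic source only
    seed: int = 0
    outdir: str = "maltopt_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("grid_steps", "force_full"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load(config: PipelineConfig) -> RunTable:
    if config.source == "builtin":
        return builtin_study()
    if config.source == "synthetic":
        return simulate_responses(study_generator(config.seed, config.noise_sd))
    return load_run_table(config.source)


def _table_hash(table: RunTable) -> str:
    payload = table.to_frame().to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage failures are re-raised with the stage name; outputs of completed
    stages are left on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        table = _load(config)
        missing = set(config.directions) - set(table.response_names)
        if missing:
            raise ValidationError(
                f"desirability directions reference unknown responses: {sorted(missing)}"
            )
        log.info("stage=load hash=%s seed=%d n_runs=%d complete=%d",
                 _table_hash(table), config.seed, table.n_runs, table.n_complete())
        table.to_csv(out / "run_table.csv")
        factors = table.design.factors

        stage = "fit"
        results = {}
        for name in table.response_names:
            if config.term_sets == "published" and name in PUBLISHED_TERM_SETS:
                res = fit_ols(table, name, PUBLISHED_TERM_SETS[name])
            else:
                cands = default_candidates(table.design.factor_names)
                force = cands[0] if name in config.force_full else None
                res, report = select_model(table, name, cands, force=force)
                report.to_csv(out / f"model_selection_{name}.csv", index=False)
            results[name] = res
            res.to_json(out / f"model_{name}.json")
            res.coef_table().to_csv(out / f"coefficients_{name}.csv")
        log.info("stage=fit models=%d", len(results))

        stage = "anova"
        anova_rows = {}
        for name, res in results.items():
            tab = res.anova()
            tab.to_csv(out / f"anova_{name}.csv")
            anova_rows[name] = tab
        log.info("stage=anova tables=%d", len(anova_rows))

        stage = "actual_vs_predicted"
        avp = table.design.to_frame()[["run_id"]].copy()
        coded = table.design.coded()
        for name, res in results.items():
            nd = ROUNDING.get(name, 3)
            actual = table.responses.loc[avp["run_id"].to_numpy(), name].to_numpy()
            pred = res.predict(coded)
            pred = np.where(np.isnan(actual), np.nan, pred)
            avp[f"{name}_actual"] = actual
            avp[f"{name}_predicted"] = np.round(pred, nd)
            avp[f"{name}_predicted_full"] = pred
        avp.to_csv(out / "actual_vs_predicted.csv", index=False, na_rep="na")

        stage = "grid"
        specs = specs_from_table(table, config.directions)
        surfaces = {name: res.surface for name, res in results.items()}
        best, feasible = grid_search(
            surfaces, specs, factors, config.grid_steps,
            report_threshold=config.d_threshold,
        )
        feasible.to_csv(out / "desirability_grid.csv", index=False)
        best.to_json(out / "grid_optimum.json")
        log.info("stage=grid D=%.4f", best.overall_D)

        stage = "ga"
        ga_config = GAConfig(
            bounds=tuple((-1.0, 1.0) for _ in factors), seed=config.seed
        )

        def fitness(points):
            from .desirability import _evaluate

            return _evaluate(surfaces, specs, points)[2]

        ga_res = run_ga(fitness, ga_config)
        ga_res.trace.to_csv(out / "ga_trace.csv")
        from .desirability import evaluate_point

        ga_best = evaluate_point(surfaces, specs, ga_res.best_point, factors)
        ga_best.to_json(out / "ga_optimum.json")
        log.info("stage=ga D=%.4f", ga_res.best_fitness)

        stage = "summary"
        summary = {
            "source": config.source,
            "seed": config.seed,
            "n_runs": table.n_runs,
            "n_complete": table.n_complete(),
            "models": {n: r.to_dict() for n, r in results.items()},
            "grid_optimum": best.to_dict(),
            "ga_optimum": ga_best.to_dict(),
            "ga_best_fitness": ga_res.best_fitness,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _write_summary_md(out / "summary.md", table, results, anova_rows, best, ga_best)
        return summary
    except MaltoptError as exc:
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc


def _fmt_point(natural, factors) -> str:
    return ", ".join(
        f"{v:.1f} {f.unit}" for v, f in zip(natural, factors)
    )


def _write_summary_md(path, table, results, anova_rows, grid_best, ga_best) -> None:
    factors = table.design.factors
    lines = ["# Malting optimization summary", ""]
    lines.append(f"Runs: {table.n_runs} ({table.n_complete()} complete)")
    lines.append("")
    lines.append("## Fitted models")
    for name, res in results.items():
        lof = anova_rows[name].frame
        lof_p = lof.loc["lack_of_fit", "p"] if "lack_of_fit" in lof.index else float("nan")
        lines.append(
            f"- {name}: adj R2 = {res.rsquared_adj:.3f}, AIC = {res.aic:.2f}, "
            f"lack-of-fit p = {lof_p:.3f}"
        )
    lines.append("")
    lines.append("## Optima")
    lines.append(
        f"- Grid search: D = {grid_best.overall_D:.3f} at "
        f"({_fmt_point(grid_best.natural_point, factors)})"
    )
    lines.append(
        f"- Genetic algorithm: D = {ga_best.overall_D:.4f} at "
        f"({_fmt_point(ga_best.natural_point, factors)})"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def export_surface_grid(
    surface: PolynomialSurface,
    factors: Sequence[Factor],
    fixed: Mapping[str, float],
    n_points: int = 41,
) -> pd.DataFrame:
    """Regular prediction grid over the two factors not held fixed.

    ``fixed`` maps factor names to natural-unit values and must pin all but
    two factors; values must lie inside the design box.  Output columns:
    the two free factors (natural units) and ``prediction``.
    """
    free = [f for f in factors if f.name not in fixed]
    if len(free) != 2:
        raise ValidationError("slice must fix all but two factors")
    for name, val in fixed.items():
        f = next((x for x in factors if x.name == name), None)
        if f is None:
            raise ValidationError(f"unknown factor {name!r}")
        if not f.low <= val <= f.high:
            raise ValidationError(f"slice value {val} outside box for {name!r}")
    ax1 = np.linspace(free[0].low, free[0].high, n_points)
    ax2 = np.linspace(free[1].low, free[1].high, n_points)
    g1, g2 = np.meshgrid(ax1, ax2, indexing="ij")
    natural = np.zeros((g1.size, len(factors)))
    for i, f in enumerate(factors):
        if f.name == free[0].name:
            natural[:, i] = g1.ravel()
        elif f.name == free[1].name:
            natural[:, i] = g2.ravel()
        else:
            natural[:, i] = fixed[f.name]
    preds = surface.predict(code(natural, factors))
    out = pd.DataFrame({free[0].name: g1.ravel(), free[1].name: g2.ravel()})
    out["prediction"] = preds
    return out
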