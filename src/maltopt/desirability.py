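"""Derringer–Suich desirability aggregation and grid optimization.

Each predicted response y is mapped to an individual desirability
d in [0, 1].  With acceptability bounds L < U and scaling exponent s > 0:

    larger-is-better:   d = 0 for y <= L, ((y-L)/(U-L))^s inside, 1 for y >= U
    smaller-is-better:  d = 1 for y <= L, ((U-y)/(U-L))^s inside, 0 for y >= U

The overall desirability D is the geometric mean of the individual d's, so
any fully unacceptable response (d = 0) zeroes the whole product.  Bounds
default to the observed response extrema of the run table being optimized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import RunTable
from .errors import ValidationError
from .factors import Factor, code, decode

__all__ = [
    "DesirabilitySpec",
    "d_larger",
    "d_smaller",
    "desirability",
    "overall_desirability",
    "OptimizationResult",
    "evaluate_point",
    "desirability_grid",
    "grid_search",
    "STUDY_DIRECTIONS",
    "specs_from_table",
]

#: Optimization direction per response in the malting study: maximize malt
#: yield (extract) and fermentability (attenuation limit), minimize
#: over-modification (Kolbach index) and both wort viscosities.
STUDY_DIRECTIONS: dict[str, str] = {
    "extract": "maximize",
    "attenuation_limit": "maximize",
    "kolbach_index": "minimize",
    "viscosity": "minimize",
    "viscosity_65": "minimize",
}


@dataclass(frozen=True)
class DesirabilitySpec:
    response: str
    direction: str  # "maximize" | "minimize"
    low: float
    high: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not self.low < self.high:
            raise ValidationError("desirability bounds need low < high")
        if self.s <= 0:
            raise ValidationError("scaling exponent s must be > 0")


def d_larger(y, low: float, high: float, s: float = 1.0) -> np.ndarray:
    """Larger-is-better transform; clamps to 0 below L and 1 above U."""
    y = np.asarray(y, dtype=float)
    frac = np.clip((y - low) / (high - low), 0.0, 1.0)
    return frac**s


def d_smaller(y, low: float, high: float, s: float = 1.0) -> np.ndarray:
    """Smaller-is-better transform; 1 below L, 0 above U."""
    y = np.asarray(y, dtype=float)
    frac = np.clip((high - y) / (high - low), 0.0, 1.0)
    return frac**s


def desirability(y, spec: DesirabilitySpec) -> np.ndarray:
    fn = d_larger if spec.direction == "maximize" else d_smaller
    return fn(y, spec.low, spec.high, spec.s)


def overall_desirability(d_values) -> np.ndarray:
    """Geometric mean across responses; rows = points, columns = responses.

    Exactly 0 whenever any individual desirability is 0.
    """
    arr = np.atleast_2d(np.asarray(d_values, dtype=float))
    if arr.size == 0:
        raise ValidationError("overall desirability of an empty set is undefined")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("individual desirabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    out = np.exp(logs.mean(axis=1))
    out[np.any(arr == 0.0, axis=1)] = 0.0
    return out


def specs_from_table(
    table: RunTable,
    directions: Mapping[str, str] = STUDY_DIRECTIONS,
    s: float = 1.0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> list[DesirabilitySpec]:
    """One spec per response; bounds default to the observed extrema."""
    specs = []
    for name in table.response_names:
        if name not in directions:
            raise ValidationError(f"no optimization direction for response {name!r}")
        lo, hi = (bounds or {}).get(name) or table.bounds(name)
        specs.append(DesirabilitySpec(name, directions[name], lo, hi, s))
    return specs


@dataclass(frozen=True)
class OptimizationResult:
    """A factor combination with its predictions and desirability breakdown."""

    coded_point: np.ndarray
    natural_point: np.ndarray
    predicted: dict[str, float]
    individual_d: dict[str, float]
    overall_D: float

    def to_dict(self) -> dict:
        return {
            "coded_point": list(map(float, self.coded_point)),
            "natural_point": list(map(float, self.natural_point)),
            "predicted": self.predicted,
            "individual_d": self.individual_d,
            "overall_D": self.overall_D,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _evaluate(models, specs, coded_pts) -> tuple[dict, np.ndarray, np.ndarray]:
    """Predictions, d-matrix and D for a batch of coded points."""
    preds = {sp.response: np.asarray(models[sp.response].predict(coded_pts))
             for sp in specs}
    d_mat = np.column_stack([desirability(preds[sp.response], sp) for sp in specs])
    return preds, d_mat, overall_desirability(d_mat)


def evaluate_point(
    models: Mapping[str, object],
    specs: Sequence[DesirabilitySpec],
    coded_point,
    factors: Sequence[Factor],
    *,
    warn_outside: bool = True,
) -> OptimizationResult:
    """Predict every response at one coded point and aggregate to D.

    Points outside the coded box [-1, 1]^k are evaluated anyway (the models
    extrapolate) with a warning.
    """
    pt = np.asarray(coded_point, dtype=float).reshape(1, -1)
    if warn_outside and np.any(np.abs(pt) > 1.0 + 1e-9):
        import warnings

        warnings.warn("evaluating desirability outside the design box")
    preds, d_mat, D = _evaluate(models, specs, pt)
    natural = decode(pt, factors)[0]
    return OptimizationResult(
        coded_point=pt[0],
        natural_point=natural,
        predicted={sp.response: float(preds[sp.response][0]) for sp in specs},
        individual_d={sp.response: float(d) for sp, d in zip(specs, d_mat[0])},
        overall_D=float(D[0]),
    )


def desirability_grid(
    models: Mapping[str, object],
    specs: Sequence[DesirabilitySpec],
    factors: Sequence[Factor],
    steps: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Long-format evaluation grid over the design box in natural units.

    ``steps`` are the natural-unit increments per factor (default 1 unit
    each: 1 d x 1 °C x 1 g/100 g for the study factors).  Rows are emitted
    in lexicographic order of the natural coordinates, so first-argmax
    lookups break ties lexicographically.
    """
    if steps is None:
        steps = [1.0] * len(factors)
    if len(steps) != len(factors):
        raise ValidationError("one grid step per factor required")
    axes = []
    for f, st in zip(factors, steps):
        if st <= 0:
            raise ValidationError("grid steps must be positive")
        axes.append(np.arange(f.low, f.high + 1e-9, st))
    mesh = np.meshgrid(*axes, indexing="ij")
    natural = np.column_stack([m.ravel() for m in mesh])
    if natural.size == 0:
        raise ValidationError("empty grid")
    coded = code(natural, factors)
    preds, d_mat, D = _evaluate(models, specs, coded)
    out = pd.DataFrame(natural, columns=[f.name for f in factors])
    for i, f in enumerate(factors):
        out[f"{f.name}_coded"] = coded[:, i]
    for sp in specs:
        out[f"pred_{sp.response}"] = preds[sp.response]
    for j, sp in enumerate(specs):
        out[f"d_{sp.response}"] = d_mat[:, j]
    out["D"] = D
    return out


def grid_search(
    models: Mapping[str, object],
    specs: Sequence[DesirabilitySpec],
    factors: Sequence[Factor],
    steps: Sequence[float] | None = None,
    *,
    report_threshold: float | None = None,
) -> tuple[OptimizationResult, pd.DataFrame]:
    """Exhaustive grid maximization of D.

    Returns the argmax (first in lexicographic natural order on ties) and
    the full grid; if ``report_threshold`` is given the returned frame is
    restricted to points with D >= threshold (exposing *all* feasible
    regions, not just the winner's neighbourhood).
    """
    grid = desirability_grid(models, specs, factors, steps)
    best_idx = int(np.argmax(grid["D"].to_numpy()))
    coded_cols = [f"{f.name}_coded" for f in factors]
    best = evaluate_point(
        models, specs, grid.loc[best_idx, coded_cols].to_numpy(dtype=float), factors
    )
    if report_threshold is not None:
        grid = grid[grid["D"] >= report_threshold].reset_index(drop=True)
    return best, grid
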