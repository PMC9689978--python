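"""Synthetic FCCD run tables from known second-order models plus noise.

The generator reproduces the data-generating structure the OLS/ANOVA
machinery assumes: each response mean is a second-order polynomial in the
coded factors, observed with iid homoscedastic Gaussian noise, independent
across responses.  Per-response noise streams are spawned deterministically
from one master seed, so a table is fully reproducible from its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import RunTable, STUDY_FACTORS
from .errors import ValidationError
from .factors import Design, fccd
from .model import PUBLISHED_MODELS, PolynomialSurface, TermSet

__all__ = ["ResponseModel", "GeneratorSpec", "simulate_responses", "mask_runs",
           "study_generator"]


@dataclass(frozen=True)
class ResponseModel:
    """True mean surface and noise level for one simulated response."""

    surface: PolynomialSurface
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Design + per-response true models + master seed."""

    design: Design
    models: dict[str, ResponseModel]
    seed: int
    units: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "factors": [
                {"name": f.name, "unit": f.unit, "low": f.low, "high": f.high}
                for f in self.design.factors
            ],
            "responses": {
                name: {
                    "terms": list(m.surface.term_set.labels),
                    "coefficients": m.surface.coefficients.tolist(),
                    "noise_sd": m.noise_sd,
                }
                for name, m in self.models.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def simulate_responses(spec: GeneratorSpec) -> RunTable:
    """Draw one run table: mean surface at each design point + N(0, sd^2).

    Identical spec (including seed) gives an identical table.  Response
    order follows the spec's insertion order; each response consumes its
    own spawned substream, so adding a response does not perturb the draws
    of the others.
    """
    coded = spec.design.coded()
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.models))
    data = {}
    for (name, rm), ss in zip(spec.models.items(), streams):
        rng = np.random.default_rng(ss)
        mean = rm.surface.predict(coded)
        data[name] = mean + rng.normal(0.0, rm.noise_sd, size=len(mean))
    resp = pd.DataFrame(data, index=pd.Index(spec.design.run_ids, name="run_id"))
    return RunTable(spec.design, resp, dict(spec.units))


def mask_runs(table: RunTable, run_ids) -> RunTable:
    """Set all responses of the listed runs to missing (emulates failed runs)."""
    return table.mask_runs(run_ids)


def study_generator(seed: int, noise_sd: float = 0.3,
                    responses: tuple[str, ...] | None = None) -> GeneratorSpec:
    """Generator emulating the rye-malting study: its 18-run FCCD with the
    published surfaces as truth.

    ``noise_sd`` defaults to 0.3, the order of the residual standard
    deviation of the study's extract model (~0.27 % d.m. on a 1-decimal
    response); pass a mapping-by-position via ``responses`` to restrict to
    a subset of the five responses.
    """
    design = fccd(STUDY_FACTORS, n_center=4)
    names = responses if responses is not None else tuple(PUBLISHED_MODELS)
    models = {name: ResponseModel(PUBLISHED_MODELS[name], noise_sd) for name in names}
    return GeneratorSpec(design, models, seed)
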