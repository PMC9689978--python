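"""Run tables: design points paired with measured responses.

The package ships the rye micro-malting study that motivates it: an 18-run
face-centred central composite design in germination time (4-6 d),
germination temperature (12-18 °C) and degree of steeping (40-46 g/100 g),
with five malt-quality responses measured per run — Congress-wort extract
(% d.m.), Kolbach index (%), apparent attenuation limit (%), and wort
viscosity in the Congress and isothermal 65 °C mashes (mPa·s).  One run
(6 d, 15 °C, 43 g/100 g) failed for technical reasons and is missing for
all responses; analyses are complete-case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .factors import Design, Factor

__all__ = [
    "RunTable",
    "STUDY_FACTORS",
    "RESPONSES",
    "RESPONSE_UNITS",
    "study_design",
    "builtin_study",
    "load_run_table",
]

STUDY_FACTORS: tuple[Factor, ...] = (
    Factor("time", "d", 4.0, 6.0),
    Factor("temp", "°C", 12.0, 18.0),
    Factor("steep", "g/100 g", 40.0, 46.0),
)

RESPONSES: tuple[str, ...] = (
    "extract",
    "kolbach_index",
    "attenuation_limit",
    "viscosity",
    "viscosity_65",
)

RESPONSE_UNITS: dict[str, str] = {
    "extract": "% d.m.",
    "kolbach_index": "%",
    "attenuation_limit": "%",
    "viscosity": "mPa·s",
    "viscosity_65": "mPa·s",
}

# validation class per response: percentages live in (0, 100), viscosities
# must be strictly positive; synthetic responses default to unconstrained
_RESPONSE_KIND: dict[str, str] = {
    "extract": "percent",
    "kolbach_index": "percent",
    "attenuation_limit": "percent",
    "viscosity": "positive",
    "viscosity_65": "positive",
}

_MISSING_TOKEN = "na"


@dataclass(frozen=True)
class RunTable:
    """A design plus per-run response measurements (missing-aware).

    ``responses`` is indexed by run_id with one float column per response;
    missing measurements are NaN.  Invariant: a failed run is missing for
    *all* responses (partial rows are rejected).
    """

    design: Design
    responses: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.design.table["run_id"].to_numpy()
        if not np.array_equal(np.sort(self.responses.index.to_numpy()), np.sort(ids)):
            raise ValidationError("response run_ids do not match the design")
        miss = self.responses.isna()
        partial = miss.any(axis=1) & ~miss.all(axis=1)
        if partial.any():
            bad = list(self.responses.index[partial])
            raise ValidationError(f"runs {bad} are missing for some but not all responses")
        for name in self.response_names:
            vals = self.responses[name].dropna()
            kind = _RESPONSE_KIND.get(name)
            if kind == "percent" and not ((vals > 0) & (vals < 100)).all():
                raise ValidationError(f"response {name!r} must lie in (0, 100)")
            if kind == "positive" and not (vals > 0).all():
                raise ValidationError(f"response {name!r} must be positive")

    @property
    def response_names(self) -> tuple[str, ...]:
        return tuple(self.responses.columns)

    @property
    def n_runs(self) -> int:
        return len(self.responses)

    def complete_mask(self) -> pd.Series:
        """Boolean mask (indexed by run_id) of fully observed runs."""
        return ~self.responses.isna().any(axis=1)

    def n_complete(self) -> int:
        return int(self.complete_mask().sum())

    def complete_cases(self, response: str) -> tuple[np.ndarray, np.ndarray]:
        """(coded design points, observed values) for one response."""
        if response not in self.response_names:
            raise ValidationError(f"unknown response {response!r}")
        obs = self.responses[response]
        keep = obs.notna().to_numpy()
        coded = self.design.coded()[keep]
        return coded, obs.to_numpy(dtype=float)[keep]

    def bounds(self, response: str) -> tuple[float, float]:
        """(min, max) of the observed values — the desirability bounds."""
        vals = self.responses[response].dropna() if response in self.response_names else None
        if vals is None:
            raise ValidationError(f"unknown response {response!r}")
        if vals.empty:
            raise ValidationError(f"response {response!r} has no observed values")
        return float(vals.min()), float(vals.max())

    def mask_runs(self, run_ids) -> "RunTable":
        """Return a copy with all responses of the listed runs set missing."""
        ids = list(run_ids)
        unknown = set(ids) - set(self.responses.index)
        if unknown:
            raise ValidationError(f"unknown run_ids: {sorted(unknown)}")
        resp = self.responses.copy()
        resp.loc[ids, :] = math.nan
        return replace(self, responses=resp)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: design columns plus one column per response."""
        out = self.design.to_frame()
        resp = self.responses.loc[out["run_id"].to_numpy()]
        for name in self.response_names:
            out[name] = resp[name].to_numpy()
        return out

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame.to_csv(path, index=False, na_rep=_MISSING_TOKEN)


def study_design() -> Design:
    """The 18-run FCCD in the randomized order the study was executed."""
    rows = [
        (-1, 1, 1), (0, 0, 0), (-1, 1, -1), (0, 0, -1), (1, 1, -1),
        (0, 0, 0), (0, 0, 0), (-1, 0, 0), (1, -1, -1), (1, 0, 0),
        (0, 1, 0), (1, 1, 1), (0, -1, 0), (0, 0, 1), (-1, -1, -1),
        (-1, -1, 1), (0, 0, 0), (1, -1, 1),
    ]
    roles = [
        "corner", "center", "corner", "axial", "corner",
        "center", "center", "axial", "corner", "axial",
        "axial", "corner", "axial", "axial", "corner",
        "corner", "center", "corner",
    ]
    return Design.from_coded(STUDY_FACTORS, np.array(rows, dtype=float), roles)


# Measured responses per run (run 10 failed -> all missing).  Columns:
# extract, kolbach_index, attenuation_limit, viscosity, viscosity_65.
_STUDY_ACTUAL: dict[int, tuple[float, ...] | None] = {
    1: (83.2, 60.6, 73.5, 4.99, 6.93),
    2: (83.4, 60.3, 73.0, 4.67, 6.36),
    3: (83.5, 59.6, 74.7, 4.92, 7.13),
    4: (83.3, 57.3, 72.7, 5.04, 6.88),
    5: (83.5, 60.6, 71.8, 4.29, 5.99),
    6: (83.3, 60.4, 72.9, 4.69, 6.12),
    7: (83.1, 59.3, 72.9, 4.71, 6.54),
    8: (82.3, 53.2, 73.1, 5.82, 7.42),
    9: (82.5, 51.8, 73.3, 5.56, 7.77),
    10: None,
    11: (83.9, 60.4, 73.3, 4.55, 5.94),
    12: (82.7, 61.7, 71.5, 4.19, 5.42),
    13: (82.1, 52.4, 73.0, 6.00, 8.14),
    14: (83.8, 62.0, 73.2, 4.63, 6.17),
    15: (80.3, 43.3, 71.8, 7.89, 8.93),
    16: (80.1, 44.6, 71.6, 7.29, 7.89),
    17: (83.2, 58.8, 73.2, 4.82, 6.38),
    18: (83.0, 58.0, 73.5, 5.25, 6.70),
}


def builtin_study() -> RunTable:
    """The full rye-malting study: 18 runs, run 10 missing, 5 responses."""
    design = study_design()
    records = {
        rid: (vals if vals is not None else (math.nan,) * len(RESPONSES))
        for rid, vals in _STUDY_ACTUAL.items()
    }
    resp = pd.DataFrame.from_dict(records, orient="index", columns=list(RESPONSES))
    resp = resp.loc[design.table["run_id"].to_numpy()]
    resp.index.name = "run_id"
    return RunTable(design, resp, dict(RESPONSE_UNITS))


def response_bounds(table: RunTable, response: str) -> tuple[float, float]:
    """Observed (min, max) of one response over non-missing runs."""
    return table.bounds(response)


def load_run_table(
    path,
    factors=STUDY_FACTORS,
    responses=RESPONSES,
    units: dict[str, str] | None = None,
) -> RunTable:
    """Read a run table written by :meth:`RunTable.to_csv`.

    Comma separated, ``.`` decimal; empty cells or ``na`` mark missing
    values.  Column set must be exactly run_id, role, natural and coded
    factor columns, and the named responses; anything else is an error.
    """
    frame = pd.read_csv(path, na_values=[_MISSING_TOKEN], keep_default_na=True)
    expected = (
        ["run_id", "role"]
        + [f.name for f in factors]
        + [f"{f.name}_coded" for f in factors]
        + list(responses)
    )
    unknown = set(frame.columns) - set(expected)
    if unknown:
        raise ValidationError(f"unknown columns in run table: {sorted(unknown)}")
    missing = set(expected) - set(frame.columns)
    if missing:
        raise ValidationError(f"run table missing columns: {sorted(missing)}")
    for col in expected:
        if col == "role":
            continue
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.loc[pd.to_numeric(frame[col], errors="coerce").isna()
                            & frame[col].notna(), col]
            raise ValidationError(
                f"unparseable numeric cell(s) in column {col!r}: {list(bad)[:3]}"
            )
    if frame["run_id"].duplicated().any():
        raise ValidationError("duplicate run_id in run table")
    design = Design.from_coded(
        factors,
        frame[[f"{f.name}_coded" for f in factors]].to_numpy(dtype=float),
        frame["role"].tolist(),
        run_ids=frame["run_id"].to_numpy(),
    )
    resp = frame[list(responses)].copy()
    resp.index = pd.Index(frame["run_id"].to_numpy(), name="run_id")
    return RunTable(design, resp, dict(units or RESPONSE_UNITS))
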