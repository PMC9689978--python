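"""Process factors, coded units and face-centred central composite designs.

A process factor varies over a natural-unit interval ``[low, high]``.  For
response-surface work it is rescaled to a dimensionless *coded* unit

    x = (natural - center) / half_range,

so that ``low`` maps to -1, ``high`` to +1 and the midpoint to 0.  Designs
are generated in coded units; the face-centred central composite design
(FCCD) places its axial points on the cube faces (alpha = 1), so every
design point lies in ``[-1, 1]^k`` and each factor takes three levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Factor", "Design", "code", "decode", "fccd"]


@dataclass(frozen=True)
class Factor:
    """One controllable process variable.

    Parameters
    ----------
    name : str
        Short identifier used for design/model columns (e.g. ``"time"``).
    unit : str
        Natural unit, metadata only (e.g. ``"d"``, ``"°C"``).
    low, high : float
        Bounds of the experimental region in natural units; ``low < high``.
    """

    name: str
    unit: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def to_coded(self, natural):
        return (np.asarray(natural, dtype=float) - self.center) / self.half_range

    def to_natural(self, coded):
        return self.center + self.half_range * np.asarray(coded, dtype=float)


def _as_2d(points, k: int, what: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[1] != k:
        raise ValidationError(
            f"{what}: expected {k} values per point, got {arr.shape[1]}"
        )
    return arr


def code(natural_points, factors: Sequence[Factor]) -> np.ndarray:
    """Convert natural-unit levels to coded units, one row per point."""
    pts = _as_2d(natural_points, len(factors), "code")
    return np.column_stack([f.to_coded(pts[:, i]) for i, f in enumerate(factors)])


def decode(coded_points, factors: Sequence[Factor]) -> np.ndarray:
    """Convert coded levels back to natural units (inverse of :func:`code`)."""
    pts = _as_2d(coded_points, len(factors), "decode")
    return np.column_stack([f.to_natural(pts[:, i]) for i, f in enumerate(factors)])


@dataclass(frozen=True)
class Design:
    """A coded experimental design: factors plus a run table.

    ``table`` has columns ``run_id`` (unique int), ``role`` (one of
    ``corner``/``axial``/``center``) and one coded-unit column per factor,
    named after the factor.
    """

    factors: tuple[Factor, ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"run_id", "role"} | {f.name for f in self.factors}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        if self.table["run_id"].duplicated().any():
            raise ValidationError("design run_ids must be unique")
        coded = self.coded()
        roles = self.table["role"].to_numpy()
        for row, role in zip(coded, roles):
            if role == "corner" and not np.all(np.abs(row) == 1.0):
                raise ValidationError("corner rows must have all |coded| = 1")
            if role == "center" and not np.all(row == 0.0):
                raise ValidationError("center rows must be all zero")
            if role == "axial" and np.count_nonzero(row) != 1:
                raise ValidationError("axial rows must have exactly one nonzero level")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.table)

    @property
    def run_ids(self) -> np.ndarray:
        return self.table["run_id"].to_numpy()

    def coded(self) -> np.ndarray:
        """Coded levels as an (n_runs, k) array in factor order."""
        return self.table[list(self.factor_names)].to_numpy(dtype=float)

    def natural(self) -> np.ndarray:
        """Natural-unit levels as an (n_runs, k) array."""
        return decode(self.coded(), self.factors)

    def to_frame(self) -> pd.DataFrame:
        """Export frame: run_id, role, natural and coded columns per factor."""
        out = self.table[["run_id", "role"]].copy()
        nat = self.natural()
        for i, f in enumerate(self.factors):
            out[f.name] = nat[:, i]
        for i, f in enumerate(self.factors):
            out[f"{f.name}_coded"] = self.coded()[:, i]
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: Sequence[Factor]) -> "Design":
        frame = pd.read_csv(path)
        cols = ["run_id", "role"] + [f"{f.name}_coded" for f in factors]
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValidationError(f"design CSV missing columns: {sorted(missing)}")
        table = frame[cols].rename(
            columns={f"{f.name}_coded": f.name for f in factors}
        )
        return cls(tuple(factors), table.reset_index(drop=True))

    @classmethod
    def from_coded(
        cls,
        factors: Sequence[Factor],
        coded_rows: Iterable[Sequence[float]],
        roles: Sequence[str],
        run_ids: Sequence[int] | None = None,
    ) -> "Design":
        coded = _as_2d(list(coded_rows), len(factors), "design rows")
        n = coded.shape[0]
        ids = np.arange(1, n + 1) if run_ids is None else np.asarray(run_ids)
        table = pd.DataFrame({"run_id": ids, "role": list(roles)})
        for i, f in enumerate(factors):
            table[f.name] = coded[:, i]
        return cls(tuple(factors), table)


def fccd(
    factors: Sequence[Factor],
    n_center: int,
    *,
    run_order: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> Design:
    """Generate a face-centred central composite design (alpha = 1).

    The canonical row order is: 2^k cube corners (last factor varying
    fastest, -1 before +1), 2k axial points (per factor, -1 then +1 on that
    axis), then ``n_center`` centre points.  ``run_order`` permutes rows
    explicitly; alternatively pass ``rng`` to randomize.  Run ids are
    assigned 1..n after any permutation.
    """
    k = len(factors)
    if k < 2:
        raise ValidationError("an FCCD needs at least 2 factors")
    if n_center < 1:
        raise ValidationError("n_center must be >= 1")
    rows: list[np.ndarray] = []
    roles: list[str] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(np.array(corner))
        roles.append("corner")
    for axis in range(k):
        for level in (-1.0, 1.0):
            row = np.zeros(k)
            row[axis] = level
            rows.append(row)
            roles.append("axial")
    for _ in range(n_center):
        rows.append(np.zeros(k))
        roles.append("center")
    order = np.arange(len(rows))
    if run_order is not None:
        order = np.asarray(run_order)
        if sorted(order) != list(range(len(rows))):
            raise ValidationError("run_order must be a permutation of all rows")
    elif rng is not None:
        order = rng.permutation(len(rows))
    coded = np.array(rows)[order]
    roles_arr = [roles[i] for i in order]
    return Design.from_coded(factors, coded, roles_arr)
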