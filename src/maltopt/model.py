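"""Second-order (quadratic) response-surface models fit by OLS.

The mean of each response is modelled as a polynomial in the *coded*
factors x_i in [-1, 1]:

    E[y] = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

over a selectable subset of terms (intercept always included).  Fitting is
ordinary least squares on complete cases; inference (SEs, t, two-sided p)
is the standard Gaussian-error machinery.  AIC/BIC use the full Gaussian
log-likelihood with k = p + 1 parameters (mean coefficients plus the
residual variance — the convention of R's ``AIC``), so values are directly
comparable across term sets on the same data.

The five response-surface equations published for the rye-malting study
ship as :data:`PUBLISHED_MODELS`, so predictions can be made from the
printed coefficients without refitting.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import RunTable
from .errors import InsufficientDataError, RankDeficiencyError, ValidationError

__all__ = [
    "TermSet",
    "build_design_matrix",
    "PolynomialSurface",
    "ResponseSurface",
    "ResponseSurfaceResults",
    "fit_ols",
    "select_model",
    "default_candidates",
    "significance_labels",
    "PUBLISHED_MODELS",
]


@dataclass(frozen=True)
class TermSet:
    """An ordered subset of second-order polynomial terms.

    Each term is a tuple of factor indices with multiplicity: ``()`` is the
    intercept, ``(0,)`` a linear term, ``(0, 1)`` an interaction, ``(0, 0)``
    a square.  Canonical order is intercept, linear terms in factor order,
    interactions in lexicographic pair order, then squares — fixed so
    coefficient vectors are reported reproducibly.
    """

    factor_names: tuple[str, ...]
    terms: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if () not in self.terms:
            raise ValidationError("a term set must contain the intercept")
        if self.terms != _canonical_order(self.terms):
            raise ValidationError("terms must be in canonical order")

    @classmethod
    def full_quadratic(cls, factor_names: Sequence[str]) -> "TermSet":
        k = len(factor_names)
        terms: list[tuple[int, ...]] = [()]
        terms += [(i,) for i in range(k)]
        terms += list(itertools.combinations(range(k), 2))
        terms += [(i, i) for i in range(k)]
        return cls(tuple(factor_names), tuple(terms))

    @classmethod
    def from_labels(cls, factor_names: Sequence[str], labels: Iterable[str]) -> "TermSet":
        idx = {n: i for i, n in enumerate(factor_names)}
        terms = [()]
        for lab in labels:
            if lab == "1":
                continue
            terms.append(_parse_label(lab, idx))
        return cls(tuple(factor_names), _canonical_order(tuple(terms)))

    def drop(self, *what: str) -> "TermSet":
        """Remove terms by label (``"time:temp"``, ``"temp^2"``) or drop
        every term involving a factor by giving the factor name."""
        idx = {n: i for i, n in enumerate(self.factor_names)}
        remove: set[tuple[int, ...]] = set()
        for w in what:
            if w in idx:
                remove |= {t for t in self.terms if idx[w] in t}
            else:
                remove.add(_parse_label(w, idx))
        kept = tuple(t for t in self.terms if t not in remove)
        return TermSet(self.factor_names, kept)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._label(t) for t in self.terms)

    def _label(self, term: tuple[int, ...]) -> str:
        if term == ():
            return "1"
        if len(term) == 1:
            return self.factor_names[term[0]]
        if term[0] == term[1]:
            return f"{self.factor_names[term[0]]}^2"
        return f"{self.factor_names[term[0]]}:{self.factor_names[term[1]]}"

    @property
    def factors_used(self) -> tuple[int, ...]:
        """Indices of factors appearing in any non-intercept term."""
        used = sorted({i for t in self.terms for i in t})
        return tuple(used)

    def __len__(self) -> int:
        return len(self.terms)


def _parse_label(lab: str, idx: Mapping[str, int]) -> tuple[int, ...]:
    if lab.endswith("^2"):
        return (idx[lab[:-2]],) * 2
    if ":" in lab:
        a, b = lab.split(":")
        return tuple(sorted((idx[a], idx[b])))
    return (idx[lab],)


def _term_rank(term: tuple[int, ...]) -> tuple:
    if term == ():
        return (0,)
    if len(term) == 1:
        return (1, term[0])
    if term[0] == term[1]:
        return (3, term[0])
    return (2, term)


def _canonical_order(terms: tuple[tuple[int, ...], ...]) -> tuple[tuple[int, ...], ...]:
    return tuple(sorted(set(terms), key=_term_rank))


def build_design_matrix(coded_points, term_set: TermSet) -> np.ndarray:
    """Model matrix: one column per term, evaluated at coded points."""
    pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
    cols = []
    for term in term_set.terms:
        col = np.ones(pts.shape[0])
        for i in term:
            col = col * pts[:, i]
        cols.append(col)
    return np.column_stack(cols)


@dataclass(frozen=True)
class PolynomialSurface:
    """A polynomial mean surface with known coefficients (coded units)."""

    term_set: TermSet
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (len(self.term_set),):
            raise ValidationError(
                f"coefficient vector length {coef.shape} does not match "
                f"{len(self.term_set)} terms"
            )
        object.__setattr__(self, "coefficients", coef)

    def predict(self, coded_points) -> np.ndarray:
        return build_design_matrix(coded_points, self.term_set) @ self.coefficients

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=list(self.term_set.labels))


class ResponseSurface:
    """Model object: one response regressed on a term set over a run table.

    Statsmodels-style usage::

        model = ResponseSurface(table, "extract", term_set)
        res = model.fit()
        res.summary()
    """

    def __init__(self, table: RunTable, response: str, term_set: TermSet):
        if term_set.factor_names != table.design.factor_names:
            raise ValidationError("term set factors do not match the design")
        coded, y = table.complete_cases(response)
        p = len(term_set)
        if len(y) < p + 1:
            raise InsufficientDataError(
                f"{len(y)} complete cases for {p} parameters (need >= {p + 1})"
            )
        X = build_design_matrix(coded, term_set)
        if np.linalg.matrix_rank(X) < p:
            raise RankDeficiencyError(
                f"model matrix rank deficient for terms {term_set.labels}"
            )
        self.table = table
        self.response = response
        self.term_set = term_set
        self.coded = coded
        self.endog = y
        self.exog = pd.DataFrame(X, columns=list(term_set.labels))

    def fit(self) -> "ResponseSurfaceResults":
        sm_res = sm.OLS(self.endog, self.exog).fit()
        return ResponseSurfaceResults(self, sm_res)


class ResponseSurfaceResults:
    """Fitted response surface: estimates, inference and fit indices."""

    def __init__(self, model: ResponseSurface, sm_results):
        self.model = model
        self._sm = sm_results
        self.response = model.response
        self.term_set = model.term_set
        self.params = pd.Series(sm_results.params.to_numpy(), index=list(model.term_set.labels))
        self.bse = pd.Series(sm_results.bse.to_numpy(), index=self.params.index)
        self.tvalues = pd.Series(sm_results.tvalues.to_numpy(), index=self.params.index)
        self.pvalues = pd.Series(sm_results.pvalues.to_numpy(), index=self.params.index)
        self.nobs = int(sm_results.nobs)
        self.df_resid = int(sm_results.df_resid)
        self.resid = np.asarray(sm_results.resid)
        self.fittedvalues = np.asarray(sm_results.fittedvalues)
        self.ssr = float(sm_results.ssr)
        self.rsquared = float(sm_results.rsquared)
        self.rsquared_adj = float(sm_results.rsquared_adj)
        # full Gaussian log-likelihood; k counts the residual variance too
        k = len(self.params) + 1
        self.aic = float(-2.0 * sm_results.llf + 2.0 * k)
        self.bic = float(-2.0 * sm_results.llf + np.log(self.nobs) * k)
        self.scale = float(sm_results.scale) if self.df_resid > 0 else 0.0

    @property
    def surface(self) -> PolynomialSurface:
        return PolynomialSurface(self.term_set, self.params.to_numpy())

    def predict(self, coded_points) -> np.ndarray:
        return self.surface.predict(coded_points)

    def fit_indices(self) -> tuple[float, float, float]:
        return self.aic, self.bic, self.rsquared_adj

    def significance(self, alpha: float = 0.05) -> pd.Series:
        return significance_labels(self, alpha)

    def anova(self):
        """Lack-of-fit ANOVA against the pure-error estimate (see
        :mod:`maltopt.anova`)."""
        from .anova import anova

        return anova(self, self.model.table)

    def studentized_residuals(self) -> np.ndarray:
        from .anova import studentized_residuals

        return studentized_residuals(self)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "t_value": self.tvalues,
                "p_value": self.pvalues,
                "significant": self.significance(),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Response surface fit: {self.response}",
            f"  n_obs = {self.nobs}, terms = {len(self.params)}, "
            f"df_resid = {self.df_resid}",
            f"  R2 = {self.rsquared:.4f}, adj R2 = {self.rsquared_adj:.4f}, "
            f"AIC = {self.aic:.2f}, BIC = {self.bic:.2f}",
            "",
            self.coef_table().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": list(self.term_set.labels),
            "coefficients": self.params.tolist(),
            "std_errors": self.bse.tolist(),
            "t_values": self.tvalues.tolist(),
            "p_values": self.pvalues.tolist(),
            "n_obs": self.nobs,
            "df_resid": self.df_resid,
            "residual_variance": self.scale,
            "rsquared_adj": self.rsquared_adj,
            "aic": self.aic,
            "bic": self.bic,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_ols(table: RunTable, response: str, term_set: TermSet) -> ResponseSurfaceResults:
    """Convenience wrapper: build the model and fit in one call."""
    return ResponseSurface(table, response, term_set).fit()


def significance_labels(results: ResponseSurfaceResults, alpha: float = 0.05) -> pd.Series:
    """Per-term significance flags: two-sided p-value < alpha."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return results.pvalues < alpha


def default_candidates(factor_names: Sequence[str]) -> list[TermSet]:
    """Candidate term sets: the full quadratic, the full set with each whole
    factor removed, and the full set with each single interaction or square
    removed."""
    full = TermSet.full_quadratic(factor_names)
    cands = [full]
    for name in factor_names:
        cands.append(full.drop(name))
    for term, label in zip(full.terms, full.labels):
        if len(term) == 2:
            cands.append(full.drop(label))
    return cands


def select_model(
    table: RunTable,
    response: str,
    candidates: Sequence[TermSet],
    *,
    force: TermSet | None = None,
) -> tuple[ResponseSurfaceResults, pd.DataFrame]:
    """Fit every candidate and pick the best by (AIC, BIC, -adj R2).

    Selection is lexicographic: lowest AIC wins; BIC then adjusted R2 break
    ties.  ``force`` overrides the ranking with an explicitly retained term
    set (still fitted and reported in the comparison table) — used where a
    response is kept at the full quadratic on substantive grounds even if
    the indices prefer a reduction.

    Returns (best results, comparison table of all candidates).
    """
    if not candidates:
        raise ValidationError("need at least one candidate term set")
    fits = [fit_ols(table, response, ts) for ts in candidates]
    report = pd.DataFrame(
        {
            "terms": [" + ".join(ts.labels[1:]) or "1" for ts in candidates],
            "n_terms": [len(ts) for ts in candidates],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "rsquared_adj": [f.rsquared_adj for f in fits],
        }
    )
    order = sorted(
        range(len(fits)),
        key=lambda i: (fits[i].aic, fits[i].bic, -fits[i].rsquared_adj),
    )
    report["rank"] = 0
    for rank, i in enumerate(order, start=1):
        report.loc[i, "rank"] = rank
    if force is not None:
        matches = [i for i, ts in enumerate(candidates) if ts == force]
        if not matches:
            fits.append(fit_ols(table, response, force))
            return fits[-1], report
        return fits[matches[0]], report
    return fits[order[0]], report


def _surface(labels: Sequence[str], coefs: Sequence[float]) -> PolynomialSurface:
    names = ("time", "temp", "steep")
    return PolynomialSurface(TermSet.from_labels(names, labels), np.asarray(coefs))


#: Published coefficient vectors of the five rye-malt response surfaces
#: (coded-unit scale), packaged so predictions do not depend on refit
#: rounding.  Factor order: time, temp, steep.
PUBLISHED_MODELS: dict[str, PolynomialSurface] = {
    "extract": _surface(
        ["time", "temp", "time:temp", "time^2", "temp^2"],
        [83.3652, 0.5636, 0.8800, -0.7000, -0.5929, -0.4109],
    ),
    "kolbach_index": _surface(
        ["time", "temp", "steep", "time:temp", "time:steep", "temp:steep",
         "time^2", "temp^2", "steep^2"],
        [59.3654, 3.0837, 5.2800, 1.4300, -2.4750, 0.6250, -0.6750,
         -2.4125, -2.6308, 0.6192],
    ),
    "attenuation_limit": _surface(
        ["time", "temp", "steep", "time:temp", "time:steep", "temp:steep",
         "time^2", "temp^2", "steep^2"],
        [73.0460, -0.1990, 0.1600, -0.1000, -1.0375, 0.1625, -0.1875,
         -0.2375, 0.0577, -0.1423],
    ),
    "viscosity": _surface(
        ["time", "temp", "steep", "time:temp", "time:steep", "temp:steep",
         "time^2", "temp^2"],
        [4.7654, -0.7291, -0.9050, -0.1350, 0.3675, 0.0150, 0.1100,
         0.2929, 0.4933],
    ),
    "viscosity_65": _surface(
        ["time", "temp", "steep", "time:temp", "time:steep", "temp:steep",
         "temp^2"],
        [6.4582, -0.6624, -0.8020, -0.3590, -0.0375, -0.0500, 0.1675,
         0.6258],
    ),
}

#: The term sets of the published models, for refitting on new data.
PUBLISHED_TERM_SETS: dict[str, TermSet] = {
    name: surf.term_set for name, surf in PUBLISHED_MODELS.items()
}
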