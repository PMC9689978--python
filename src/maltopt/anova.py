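"""ANOVA with lack-of-fit / pure-error decomposition and residual diagnostics.

Replicated design points allow the residual sum of squares to be split into
*pure error* (within-replicate variation, independent of the model form)
and *lack of fit* (systematic departure of the fitted surface from the
replicate means).  A significant lack-of-fit F = MS_lof / MS_pe indicates
the surface is inadequate for prediction.

Replicate grouping convention: runs are replicates when they share the
coded level of every factor *appearing in the fitted term set* — factors
the model ignores are projected out.  For a three-factor FCCD fitted with a
two-factor model this pools the centre points with the axial points of the
dropped factor (six pseudo-replicates at the projected centre plus the
four projected corner pairs, pure-error df = 9); full three-factor models
group only the true centre replicates (df = 3).  Grouping uses exact
equality of coded levels, which are exact by design construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .data import RunTable
from .errors import ValidationError
from .model import ResponseSurfaceResults, TermSet

__all__ = ["pure_error", "anova", "AnovaTable", "studentized_residuals", "stars"]


def stars(p: float | None) -> str:
    """Significance bands: *** <0.001, ** <0.01, * <0.05, else ns."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pure_error(table: RunTable, response: str, term_set: TermSet) -> tuple[float, int]:
    """Pure-error sum of squares and df under reduced-space replicate grouping.

    Returns ``(0.0, 0)`` when no factor-level combination is replicated.
    """
    coded, y = table.complete_cases(response)
    used = term_set.factors_used
    keys = [tuple(row[list(used)]) for row in coded] if used else [() for _ in y]
    groups: dict[tuple, list[float]] = {}
    for key, val in zip(keys, y):
        groups.setdefault(key, []).append(val)
    ss = 0.0
    df = 0
    for vals in groups.values():
        if len(vals) > 1:
            arr = np.asarray(vals)
            ss += float(np.sum((arr - arr.mean()) ** 2))
            df += len(vals) - 1
    return ss, df


@dataclass(frozen=True)
class AnovaTable:
    """Model / residual / lack-of-fit / pure-error decomposition."""

    response: str
    frame: pd.DataFrame  # index: model, residuals, lack_of_fit, pure_error

    def __str__(self) -> str:
        return f"ANOVA: {self.response}\n" + self.frame.to_string(
            float_format=lambda v: f"{v: .4f}"
        )

    def row(self, name: str) -> pd.Series:
        return self.frame.loc[name]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    def to_json(self, path) -> None:
        payload = {"response": self.response, "rows": self.frame.reset_index()
                   .rename(columns={"index": "source"}).to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def anova(results: ResponseSurfaceResults, table: RunTable) -> AnovaTable:
    """ANOVA table for a fitted surface, with the lack-of-fit test.

    Model SS is the corrected total SS minus the residual SS; F(model) uses
    the overall residual mean square, F(lack of fit) the pure-error mean
    square.  With no replicated points the lack-of-fit rows are dropped and
    a warning is issued.
    """
    y = results.model.endog
    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = results.ssr
    df_model = len(results.params) - 1
    df_resid = results.df_resid
    ss_model = ss_total - ss_resid

    ss_pe, df_pe = pure_error(table, results.response, results.term_set)
    rows: dict[str, dict] = {}
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    f_model = (ss_model / df_model) / ms_resid if df_resid > 0 else np.nan
    p_model = float(stats.f.sf(f_model, df_model, df_resid)) if df_resid > 0 else np.nan
    rows["model"] = dict(df=df_model, sum_sq=ss_model, mean_sq=ss_model / df_model,
                         F=f_model, p=p_model)
    rows["residuals"] = dict(df=df_resid, sum_sq=ss_resid, mean_sq=ms_resid,
                             F=np.nan, p=np.nan)
    if df_pe == 0:
        warnings.warn(
            "no replicated design points under the model's factors; "
            "pure error undefined, lack-of-fit test skipped"
        )
    else:
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        if df_lof < 0 or ss_lof < -1e-8:
            raise ValidationError("inconsistent lack-of-fit decomposition")
        ss_lof = max(ss_lof, 0.0)
        ms_pe = ss_pe / df_pe
        if df_lof == 0:
            f_lof = np.nan
            p_lof = np.nan
            ms_lof = np.nan
        else:
            ms_lof = ss_lof / df_lof
            f_lof = ms_lof / ms_pe if ms_pe > 0 else np.inf
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        rows["lack_of_fit"] = dict(df=df_lof, sum_sq=ss_lof, mean_sq=ms_lof,
                                   F=f_lof, p=p_lof)
        rows["pure_error"] = dict(df=df_pe, sum_sq=ss_pe, mean_sq=ms_pe,
                                  F=np.nan, p=np.nan)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame["signif"] = [stars(p) if not np.isnan(f) else ""
                       for f, p in zip(frame["F"], frame["p"])]
    assert n - 1 == frame.loc["model", "df"] + frame.loc["residuals", "df"]
    return AnovaTable(results.response, frame)


def studentized_residuals(results: ResponseSurfaceResults) -> np.ndarray:
    """Externally studentized residuals (leave-one-out scaled).

    Each residual is divided by its standard error estimated from a fit
    excluding that observation, so one gross outlier cannot mask itself.
    """
    if results.df_resid < 2:
        raise ValidationError("need residual df >= 2 for external studentization")
    infl = OLSInfluence(results._sm)
    lev = np.asarray(infl.hat_matrix_diag)
    if np.any(lev >= 1.0 - 1e-12):
        raise ValidationError("leverage of 1: point is exactly interpolated")
    vals = np.asarray(infl.resid_studentized_external)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite studentized residual")
    return vals
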