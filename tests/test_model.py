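"""Quadratic response-surface fitting, indices, selection, significance."""

import numpy as np
import pandas as pd
import pytest

import maltopt as m
from maltopt.errors import (
    InsufficientDataError,
    RankDeficiencyError,
    ValidationError,
)
from maltopt.model import build_design_matrix


class TestTermSet:
    def test_full_quadratic_order(self):
        ts = m.TermSet.full_quadratic(("time", "temp", "steep"))
        assert ts.labels == (
            "1", "time", "temp", "steep", "time:temp", "time:steep",
            "temp:steep", "time^2", "temp^2", "steep^2",
        )

    def test_drop_factor_removes_all_its_terms(self):
        ts = m.TermSet.full_quadratic(("time", "temp", "steep")).drop("steep")
        assert ts.labels == ("1", "time", "temp", "time:temp", "time^2", "temp^2")

    def test_published_term_sets_match_equations(self):
        assert m.PUBLISHED_TERM_SETS["extract"].labels == (
            "1", "time", "temp", "time:temp", "time^2", "temp^2")
        assert len(m.PUBLISHED_TERM_SETS["kolbach_index"]) == 10
        assert "steep^2" not in m.PUBLISHED_TERM_SETS["viscosity"].labels
        assert "time^2" not in m.PUBLISHED_TERM_SETS["viscosity_65"].labels

    def test_intercept_required(self):
        with pytest.raises(ValidationError):
            m.TermSet(("a", "b"), ((0,), (1,)))


class TestDesignMatrix:
    def test_center_row(self):
        ts = m.TermSet.full_quadratic(("a", "b", "c"))
        row = build_design_matrix([[0, 0, 0]], ts)[0]
        assert row[0] == 1 and np.all(row[1:] == 0)

    def test_mixed_point_full_quadratic(self):
        ts = m.TermSet.full_quadratic(("a", "b", "c"))
        row = build_design_matrix([[1, -1, 1 / 3]], ts)[0]
        expected = [1, 1, -1, 1 / 3, -1, 1 / 3, -1 / 3, 1, 1, 1 / 9]
        assert np.allclose(row, expected)

    def test_corner_quadratic_columns_are_one(self):
        ts = m.TermSet.full_quadratic(("a", "b", "c"))
        rows = build_design_matrix([[-1, 1, -1], [1, 1, 1]], ts)
        assert np.all(rows[:, -3:] == 1)


class TestFit:
    def test_ols_matches_normal_equation_oracle(self, study):
        for name in m.RESPONSES:
            ts = m.PUBLISHED_TERM_SETS[name]
            res = m.fit_ols(study, name, ts)
            coded, y = study.complete_cases(name)
            X = build_design_matrix(coded, ts)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(res.params.to_numpy(), oracle, rtol=1e-8)

    def test_refit_reproduces_published_coefficients(self, study):
        for name, surf in m.PUBLISHED_MODELS.items():
            res = m.fit_ols(study, name, surf.term_set)
            assert np.allclose(
                res.params.to_numpy(), surf.coefficients, atol=0.02
            ), name

    def test_extract_headline_coefficients(self, study):
        res = m.fit_ols(study, "extract", m.PUBLISHED_TERM_SETS["extract"])
        assert res.params["1"] == pytest.approx(83.3652, abs=0.02)
        assert res.params["time"] == pytest.approx(0.5636, abs=0.02)
        assert res.params["temp"] == pytest.approx(0.8800, abs=0.02)

    @pytest.mark.parametrize(
        "response, adj_r2",
        [("extract", 0.937), ("kolbach_index", 0.946), ("attenuation_limit", 0.909)],
    )
    def test_adjusted_r2(self, study, response, adj_r2):
        # agreement to the printed 3-decimal precision (half-unit ties allowed)
        res = m.fit_ols(study, response, m.PUBLISHED_TERM_SETS[response])
        assert res.rsquared_adj == pytest.approx(adj_r2, abs=6e-4)

    def test_insufficient_complete_cases(self, study):
        crippled = study.mask_runs(list(study.responses.index)[:12])
        with pytest.raises(InsufficientDataError):
            m.fit_ols(crippled, "kolbach_index",
                      m.PUBLISHED_TERM_SETS["kolbach_index"])

    def test_rank_deficient_design(self):
        # responses observed only at the centre points: squares collinear
        table = m.builtin_study()
        keep = [2, 6, 7, 17, 1, 3, 5, 9, 12, 15, 16, 18]
        drop = [r for r in table.responses.index if r not in keep]
        crippled = table.mask_runs(drop)
        ts = m.TermSet.full_quadratic(table.design.factor_names)
        with pytest.raises((RankDeficiencyError, InsufficientDataError)):
            m.fit_ols(crippled, "extract", ts)


class TestPredict:
    def test_published_extract_predictions(self):
        surf = m.PUBLISHED_MODELS["extract"]
        assert round(float(surf.predict([[-1, -1, -1]])[0]), 1) == 80.2
        assert round(float(surf.predict([[0, 0, 0]])[0]), 1) == 83.4

    def test_published_ki_at_grid_optimum(self):
        val = float(m.PUBLISHED_MODELS["kolbach_index"].predict([[1, -1, 1 / 3]])[0])
        assert round(val, 1) == 55.6


class TestSelection:
    def test_single_candidate_returned(self, study):
        ts = m.PUBLISHED_TERM_SETS["extract"]
        best, report = m.select_model(study, "extract", [ts])
        assert best.term_set == ts and len(report) == 1

    def test_reduced_extract_model_wins_on_aic(self, study):
        full = m.TermSet.full_quadratic(study.design.factor_names)
        reduced = m.PUBLISHED_TERM_SETS["extract"]
        best, report = m.select_model(study, "extract", [full, reduced])
        assert best.term_set == reduced
        assert report.loc[1, "aic"] < report.loc[0, "aic"]

    def test_force_retains_full_quadratic(self, study):
        full = m.TermSet.full_quadratic(study.design.factor_names)
        reduced = m.PUBLISHED_TERM_SETS["extract"]
        best, _ = m.select_model(
            study, "attenuation_limit", [full, reduced], force=full
        )
        assert best.term_set == full

    def test_empty_candidates_error(self, study):
        with pytest.raises(ValidationError):
            m.select_model(study, "extract", [])

    def test_default_candidates_contain_published_reductions(self, study):
        cands = m.default_candidates(study.design.factor_names)
        assert m.TermSet.full_quadratic(study.design.factor_names) in cands
        assert m.PUBLISHED_TERM_SETS["extract"] in cands  # whole steep block out


class TestSignificance:
    def test_extract_time_and_temp_significant(self, study):
        res = m.fit_ols(study, "extract", m.PUBLISHED_TERM_SETS["extract"])
        sig = res.significance()
        assert sig["time"] and sig["temp"]

    def test_aal_only_interaction_significant(self, study):
        res = m.fit_ols(
            study, "attenuation_limit", m.PUBLISHED_TERM_SETS["attenuation_limit"]
        )
        sig = res.significance().drop("1")
        assert sig["time:temp"]
        assert not sig.drop("time:temp").any()

    def test_type_one_error_rate_per_term(self):
        """A pure-noise response should flag each term ~5% of the time."""
        design = m.fccd(m.STUDY_FACTORS, n_center=4)
        ts = m.TermSet.full_quadratic(design.factor_names)
        n_seeds = 200
        flags = np.zeros(len(ts))
        null = m.PolynomialSurface(ts, np.zeros(len(ts)))
        for seed in range(n_seeds):
            spec = m.GeneratorSpec(
                design, {"y": m.ResponseModel(null, 1.0)}, seed=seed
            )
            table = m.simulate_responses(spec)
            res = m.fit_ols(table, "y", ts)
            flags += res.significance().to_numpy()
        rates = flags / n_seeds
        assert np.all(rates <= 0.10)
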