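"""Pure error, lack-of-fit decomposition and studentized residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

import maltopt as m
from maltopt.anova import pure_error, studentized_residuals
from maltopt.errors import ValidationError
from maltopt.factors import Design
from maltopt.model import build_design_matrix


class TestPureError:
    def test_reduced_extract_model_projects_to_df9(self, study):
        """Dropping the steeping factor pools its axials with the centres."""
        ss, df = pure_error(study, "extract", m.PUBLISHED_TERM_SETS["extract"])
        assert df == 9
        assert ss == pytest.approx(0.8050, abs=1e-10)

    def test_full_ki_model_uses_centre_replicates_only(self, study):
        ss, df = pure_error(
            study, "kolbach_index", m.PUBLISHED_TERM_SETS["kolbach_index"]
        )
        assert df == 3
        assert ss == pytest.approx(1.82, abs=1e-10)

    def test_no_replicates_gives_zero(self, study):
        # corner runs only: all distinct under the full three-factor model
        corners = study.design.table.loc[
            study.design.table["role"] == "corner", "run_id"
        ]
        others = [r for r in study.responses.index if r not in set(corners)]
        table = study.mask_runs(others)
        ss, df = pure_error(
            table, "extract", m.TermSet.full_quadratic(study.design.factor_names)
        )
        assert (ss, df) == (0.0, 0)


class TestAnovaTable:
    def test_extract_lack_of_fit_matches_study(self, study):
        res = m.fit_ols(study, "extract", m.PUBLISHED_TERM_SETS["extract"])
        tab = res.anova().frame
        assert tab.loc["lack_of_fit", "df"] == 2
        assert tab.loc["lack_of_fit", "F"] == pytest.approx(0.0949, abs=0.0005)
        assert tab.loc["lack_of_fit", "signif"] == "ns"
        assert tab.loc["lack_of_fit", "p"] == pytest.approx(0.9103533, abs=1e-4)

    def test_ki_model_f_and_df(self, study):
        res = m.fit_ols(study, "kolbach_index", m.PUBLISHED_TERM_SETS["kolbach_index"])
        tab = res.anova().frame
        assert tab.loc["model", "df"] == 9 and tab.loc["residuals", "df"] == 7
        assert tab.loc["model", "sum_sq"] == pytest.approx(513.82, rel=0.002)
        assert tab.loc["model", "F"] == pytest.approx(32.31, rel=0.002)

    def test_ss_and_df_additivity_all_models(self, study):
        for name in m.RESPONSES:
            res = m.fit_ols(study, name, m.PUBLISHED_TERM_SETS[name])
            tab = res.anova().frame
            assert tab.loc["residuals", "df"] == (
                tab.loc["lack_of_fit", "df"] + tab.loc["pure_error", "df"]
            )
            assert tab.loc["residuals", "sum_sq"] == pytest.approx(
                tab.loc["lack_of_fit", "sum_sq"] + tab.loc["pure_error", "sum_sq"],
                abs=1e-8,
            )
            assert tab["mean_sq"].dropna().to_numpy() == pytest.approx(
                (tab["sum_sq"] / tab["df"]).dropna().to_numpy()
            )

    def test_all_lack_of_fit_nonsignificant(self, study):
        for name in m.RESPONSES:
            res = m.fit_ols(study, name, m.PUBLISHED_TERM_SETS[name])
            assert res.anova().frame.loc["lack_of_fit", "p"] > 0.05, name

    def test_noise_free_truth_has_zero_lack_of_fit(self):
        table = m.simulate_responses(m.study_generator(seed=2, noise_sd=0.0))
        masked = m.mask_runs(table, [10])
        res = m.fit_ols(masked, "kolbach_index",
                        m.PUBLISHED_TERM_SETS["kolbach_index"])
        tab = res.anova().frame
        assert tab.loc["residuals", "sum_sq"] == pytest.approx(0.0, abs=1e-16)

    def test_no_replicates_warns_and_skips_lof(self, study):
        corners = study.design.table.loc[
            study.design.table["role"] == "corner", "run_id"
        ]
        others = [r for r in study.responses.index if r not in set(corners)]
        table = study.mask_runs(others)
        ts = m.TermSet.full_quadratic(study.design.factor_names).drop(
            "time^2", "temp^2", "steep^2"
        )
        res = m.fit_ols(table, "extract", ts)
        with pytest.warns(UserWarning, match="lack-of-fit"):
            tab = m.anova(res, table).frame
        assert "lack_of_fit" not in tab.index


def _line_fixture(x, y):
    """One-factor run table (straight-line term set) for residual checks."""
    factors = (m.Factor("x", "", -1.0, 1.0), m.Factor("z", "", -1.0, 1.0))
    coded = np.column_stack([x, np.zeros(len(x))])
    design = Design.from_coded(factors, coded, ["point"] * len(x))
    resp = pd.DataFrame({"y": y}, index=pd.Index(design.run_ids, name="run_id"))
    table = m.RunTable(design, resp)
    ts = m.TermSet.full_quadratic(("x", "z")).drop("z", "x^2")
    return m.fit_ols(table, "y", ts)


class TestStudentizedResiduals:
    def test_symmetric_duplicated_fixture_sums_to_zero(self):
        res = _line_fixture([-1, -1, 1, 1], [0.0, 2.0, 0.0, 2.0])
        vals = studentized_residuals(res)
        assert vals.sum() == pytest.approx(0.0, abs=1e-10)

    def test_outlier_has_largest_magnitude_with_loo_oracle(self):
        x = np.array([-1.0, -1 / 3, 1 / 3, 1.0])
        # last point far off the trend; the others jittered so no
        # leave-one-out fit is exactly interpolating
        y = np.array([-1.05, -0.30, 0.25, 3.0])
        res = _line_fixture(x, y)
        vals = studentized_residuals(res)
        assert np.argmax(np.abs(vals)) == 3

        # independent leave-one-out oracle via the prediction-error form
        X = np.column_stack([np.ones(4), x])
        oracle = []
        for i in range(4):
            keep = [j for j in range(4) if j != i]
            Xi, yi = X[keep], y[keep]
            beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ yi)
            resid = yi - Xi @ beta
            s2 = resid @ resid / (len(keep) - 2)
            var = s2 * (1 + X[i] @ np.linalg.inv(Xi.T @ Xi) @ X[i])
            oracle.append((y[i] - X[i] @ beta) / np.sqrt(var))
        assert np.allclose(vals, oracle, atol=1e-10)

    def test_builtin_extract_has_no_gross_outlier(self, study):
        res = m.fit_ols(study, "extract", m.PUBLISHED_TERM_SETS["extract"])
        assert np.all(np.abs(studentized_residuals(res)) < 4.0)

    def test_requires_enough_residual_df(self):
        res = _line_fixture([-1.0, 0.0, 1.0], [0.0, 0.1, 0.3])
        with pytest.raises(ValidationError):
            studentized_residuals(res)
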