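"""Cohort statistics: descriptives, exact tests, Spearman, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wristpa import analysis, simulate
from wristpa.types import SimulationConfig

from conftest import fisher_oracle_2x3, ols_oracle


@pytest.fixture(scope="module")
def cohort500():
    return simulate.generate_cohort(500, config=SimulationConfig(seed=3), noise_sd=5.0)


class TestFisher:
    @pytest.mark.parametrize(
        "table",
        [
            [[5, 2, 3], [1, 7, 4]],
            [[10, 0, 0], [0, 10, 10]],
            [[3, 3, 3], [3, 3, 3]],
            [[1, 1, 1], [9, 9, 9]],
        ],
    )
    def test_matches_enumeration_oracle_2x3(self, table):
        got = analysis.fisher_exact_2xc(np.array(table))
        assert got == pytest.approx(fisher_oracle_2x3(np.array(table)), rel=1e-9)

    def test_matches_scipy_2x2(self):
        table = np.array([[8, 2], [1, 5]])
        _, p = stats.fisher_exact(table)
        assert analysis.fisher_exact_2xc(table) == pytest.approx(p, rel=1e-9)

    def test_rejects_wrong_shape_and_negative(self):
        with pytest.raises(ValueError):
            analysis.fisher_exact_2xc(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError):
            analysis.fisher_exact_2xc(np.array([[1, -1], [2, 2]]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=6, max_size=6))
    def test_is_a_probability(self, flat):
        table = np.array(flat).reshape(2, 3)
        if table.sum() == 0 or (table.sum(axis=0) == 0).any():
            return
        p = analysis.fisher_exact_2xc(table)
        assert 0.0 < p <= 1.0


class TestDescriptives:
    def test_kruskal_groups_and_pvalue(self, cohort500):
        comp = analysis.describe_by_group(cohort500, "aee_kj_day_kg")
        assert comp.test_name == "kruskal_wallis"
        assert set(comp.groups) == {1, 2, 3}
        assert comp.p_value < 0.001  # levels differ by construction
        meds = [comp.groups[l]["median"] for l in (1, 2, 3)]
        assert meds[0] < meds[1] < meds[2]

    def test_categorical_uses_fisher(self, cohort500):
        df = cohort500.copy()
        df["sex2"] = df["sex"]
        comp = analysis.describe_by_group(df, "sex2", categorical=True)
        assert comp.test_name == "fisher_exact"
        assert 0 < comp.p_value <= 1

    def test_constant_variable_yields_nan_not_crash(self, cohort500):
        df = cohort500.copy()
        df["flat"] = 1.0
        comp = analysis.describe_by_group(df, "flat")
        assert np.isnan(comp.p_value)

    def test_unknown_variable_rejected(self, cohort500):
        with pytest.raises(ValueError, match="unknown"):
            analysis.describe_by_group(cohort500, "nope")


class TestSpearman:
    def test_perfect_monotone_pair(self):
        df = pd.DataFrame({"a": np.arange(20.0), "b": np.arange(20.0) ** 3, "c": 1.0})
        m = analysis.spearman_matrix(df, ["a", "b", "c"])
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(m.loc["a", "c"])
        assert (np.diag(m) == 1.0).all()

    def test_acc_tracks_aee_in_cohort(self, cohort500):
        m = analysis.spearman_matrix(cohort500, ["acc_mg", "aee_kj_day_kg", "age"])
        assert m.loc["acc_mg", "aee_kj_day_kg"] > 0.9
        assert m.equals(m.T)


class TestRegression:
    def test_matches_normal_equation_oracle(self, cohort500):
        res = analysis.fit_aee_model(cohort500, "partial")
        X = np.column_stack(
            [
                np.ones(len(cohort500)),
                (cohort500["inchianti"] == 2).astype(float),
                (cohort500["inchianti"] == 3).astype(float),
                cohort500["age"],
                (cohort500["sex"] == "female").astype(float),
                cohort500["bmi"],
            ]
        )
        beta, se = ols_oracle(X, cohort500["aee_kj_day_kg"].to_numpy())
        order = ["const", "inchianti2", "inchianti3", "age", "female", "bmi"]
        assert np.allclose(res.terms.loc[order, "beta"], beta, atol=1e-8)
        assert np.allclose(res.terms.loc[order, "se"], se, atol=1e-8)

    def test_recovers_generating_coefficients(self, cohort500):
        res = analysis.fit_aee_model(cohort500, "partial")
        for term in ("inchianti2", "inchianti3", "female"):
            true = simulate.DEFAULT_TRUE_BETAS[term]
            z = (res.beta(term) - true) / res.terms.loc[term, "se"]
            assert abs(z) < 3.0

    def test_full_model_adds_mmse_gds(self, cohort500):
        res = analysis.fit_aee_model(cohort500, "full")
        assert {"mmse", "gds"} <= set(res.terms.index)
        assert res.n_obs == len(cohort500.dropna(subset=["mmse", "gds"]))

    def test_ci_width_matches_quantile(self, cohort500):
        res = analysis.fit_aee_model(cohort500, "partial", ci_quantile=2.5)
        t = res.terms.loc["inchianti2"]
        assert t["ci_high"] - t["ci_low"] == pytest.approx(2 * 2.5 * t["se"])

    def test_collinear_design_names_term(self, cohort500):
        df = cohort500.copy()
        df["sex"] = "male"  # female dummy becomes all-zero
        with pytest.raises(ValueError, match="female"):
            analysis.fit_aee_model(df, "partial")

    def test_single_level_rejected(self, cohort500):
        df = cohort500[cohort500["inchianti"] == 2]
        with pytest.raises(ValueError, match="two distinct"):
            analysis.fit_aee_model(df, "partial")


class TestContrasts:
    @pytest.fixture()
    def printed(self):
        return analysis.regression_from_coefficients(
            {"inchianti2": 17.434, "inchianti3": 23.449, "female": 7.142},
            ses={"inchianti2": 4.192, "inchianti3": 6.014, "female": 3.717},
        )

    def test_reported_convention(self, printed):
        assert analysis.reported_style_contrast(printed, 1, 2, "male") == pytest.approx(17.434)
        assert analysis.reported_style_contrast(printed, 1, 2, "female") == pytest.approx(24.576)
        assert analysis.reported_style_contrast(printed, 2, 3, "female") == pytest.approx(30.591)

    def test_standard_convention_differs(self, printed):
        assert analysis.standard_contrast(printed, 2, 3) == pytest.approx(23.449 - 17.434)

    def test_bad_levels_and_sex_rejected(self, printed):
        with pytest.raises(ValueError):
            analysis.reported_style_contrast(printed, 1, 5, "male")
        with pytest.raises(ValueError):
            analysis.reported_style_contrast(printed, 1, 2, "other")
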