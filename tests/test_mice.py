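"""Chained-equations imputation: fits, draws, convergence diagnostics."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import riskuq as rq
from riskuq.schema import VariableSpec
from riskuq.toys import gaussian_toy

from conftest import toy_exact_summary


class TestFitConditionalModels:
    def test_zero_part_intercept_recovers_zero_fraction(self, schema, pop):
        """40% structural zeros with uninformative predictors: the fitted
        zero-part intercept must equal logit(0.6) within 3 standard errors
        (the zero part models P(value > 0))."""
        margins = dict(rq.cohort.DEFAULT_MARGINS)
        margins["alcohol"] = (
            "zero-inflated-lognormal",
            {"p_zero": 0.4, "mu": math.log(6.0), "sigma": 0.9},
        )
        coh = rq.simulate_cohort(
            schema, pop, n=4000, seed=31, margins=margins,
            dependence=pd.DataFrame(
                np.eye(9),
                index=[v.name for v in schema if v.group != "FH"],
                columns=[v.name for v in schema if v.group != "FH"],
            ),
        )
        models = rq.fit_conditional_models(coh, schema)
        intercept = models.models["alcohol"].zero_part.beta[0]
        # analytic MLE of an intercept-only logistic: logit(p); SE ~ 1/sqrt(n p q)
        se = 1.0 / math.sqrt(4000 * 0.4 * 0.6)
        # predictors are uninformative but estimated; allow a margin on top
        assert abs(intercept - logit(0.6)) < 3 * se + 0.35

    def test_linear_slope_recovers_correlation(self):
        """Bivariate normal (X, Y), corr 0.8: fitted slope of Y on X within
        3 closed-form standard errors of 0.8."""
        toy = gaussian_toy(n=5000, seed=41, rho=0.8)
        sub_schema = rq.RiskFactorSchema(variables=toy.schema.variables[:2])
        rec = toy.cohort.records[["x1", "x2"]]
        coh = rq.ReferenceCohort(records=rec, schema=sub_schema)
        models = rq.fit_conditional_models(coh, sub_schema)
        beta = models.models["x2"].beta  # [intercept, slope on x1]
        se = math.sqrt((1 - 0.64) / 5000)
        assert abs(beta[1] - 0.8) < 3 * se

    def test_pv_multinomial_has_eight_equations(self, models, schema):
        pv_model = models.models[schema.pv_variable]
        assert pv_model.n_classes == 9
        p = rq.mice._m.n_predictors(schema, schema.pv_variable)
        assert pv_model.theta.shape == (8 * p,)

    def test_absent_level_raises(self, schema, pop):
        coh = rq.simulate_cohort(schema, pop, n=1500, seed=32)
        coh.records.loc[coh.records["pv"] != "none", "pv"] = "none"
        coh.records.iloc[0, coh.records.columns.get_loc("pv")] = "CHEK2"
        with pytest.raises(ValueError, match="absent"):
            rq.fit_conditional_models(coh, schema)

    def test_small_cohort_rejected(self, schema, pop):
        coh = rq.simulate_cohort(schema, pop, n=60, seed=33)
        with pytest.raises(ValueError, match="training rows"):
            rq.fit_conditional_models(coh, schema)


class TestChainedImpute:
    def test_fully_observed_profile_unchanged(self, models, schema, cohort):
        row = cohort.records.iloc[3]
        prof = rq.IndividualProfile(age=40, values={v.name: row[v.name] for v in schema})
        cps = rq.chained_impute(prof, models, M=20, seed=1)
        assert cps.data.drop_duplicates().shape[0] == 1
        for v in schema:
            assert (cps.data[v.name] == row[v.name]).all()

    def test_gaussian_conditional_recovery(self):
        """Two-variable Gaussian check: Y | X=x is N(rho*x, 1-rho^2)."""
        toy = gaussian_toy(n=5000, seed=42, rho=0.8)
        sub_schema = rq.RiskFactorSchema(variables=toy.schema.variables[:2])
        coh = rq.ReferenceCohort(records=toy.cohort.records[["x1", "x2"]], schema=sub_schema)
        models = rq.fit_conditional_models(coh, sub_schema)
        x = 1.5
        prof = rq.IndividualProfile(age=40, values={"x1": x, "x2": None})
        cps = rq.chained_impute(prof, models, M=10_000, seed=2)
        y = cps.data["x2"].to_numpy()
        cond_var = 1 - 0.64
        se_mc = math.sqrt(cond_var / 10_000)
        se_fit = math.sqrt(cond_var / 5000 * (1 + x * x))
        assert abs(y.mean() - 0.8 * x) < 3 * math.sqrt(se_mc**2 + se_fit**2)
        assert abs(y.var(ddof=1) - cond_var) < 0.1 * cond_var

    def test_discrete_conditionals_match_enumeration(self, toy, toy_models):
        """With factor_a observed, the joint frequencies of the imputed
        (factor_b, factor_c) must match the exact conditional table."""
        cps = rq.chained_impute(toy.profile, toy_models, M=10_000, seed=3)
        cond = toy.conditional(a=0)
        for r in cond.itertuples():
            emp = float(
                ((cps.data["factor_b"] == r.b) & (cps.data["factor_c"] == r.c)).mean()
            )
            se = math.sqrt(r.prob * (1 - r.prob) / 10_000)
            assert abs(emp - r.prob) <= 3 * se + 0.005

    def test_observed_entries_immutable_and_seed_deterministic(
        self, models, schema, fh_profile
    ):
        a = rq.chained_impute(fh_profile, models, M=200, seed=7)
        b = rq.chained_impute(fh_profile, models, M=200, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert (a.data["family_history"] == "2+").all()
        c = rq.chained_impute(fh_profile, models, M=200, seed=8)
        assert not a.data.equals(c.data)

    def test_bad_arguments(self, models, fh_profile):
        with pytest.raises(ValueError, match="M must be"):
            rq.chained_impute(fh_profile, models, M=0, seed=1)
        with pytest.raises(ValueError, match="fitted"):
            rq.chained_impute(fh_profile, None, M=10, seed=1)


class TestGelmanRubin:
    def test_identical_chains_floor(self):
        """Zero between-chain variance attains the floor sqrt((n-1)/n)."""
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(100)
        chains = np.vstack([trace, trace])
        assert rq.gelman_rubin(chains) == pytest.approx(math.sqrt(99 / 100))

    def test_formula_oracle(self):
        """Direct spreadsheet-style evaluation on shifted chains."""
        rng = np.random.default_rng(1)
        n = 100
        c1 = rng.standard_normal(n)
        c2 = rng.standard_normal(n) + 10.0
        chains = np.vstack([c1, c2])
        W = (c1.var(ddof=1) + c2.var(ddof=1)) / 2
        B = n * np.var([c1.mean(), c2.mean()], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert rq.gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_conventions(self):
        assert rq.gelman_rubin([[1.0, 1.0], [1.0, 1.0]]) == 1.0
        assert rq.gelman_rubin([[1.0, 1.0], [2.0, 2.0]]) == math.inf
        with pytest.raises(ValueError):
            rq.gelman_rubin([[1.0, 2.0]])

    def test_well_mixed_chains_converge(self, gauss, gauss_models):
        prof = rq.IndividualProfile(
            age=40, values={"x1": 0.5, "x2": None, "x3": None, "x4": None}
        )
        cps = rq.chained_impute(prof, gauss_models, M=8000, n_iter=10, n_chains=4, seed=5)
        rep = rq.ConvergenceReport.from_completed(cps)
        assert rep.max_rhat < 1.1


class TestCompareObservedImputed:
    def test_mcar_distributions_agree(self, schema, pop):
        """Under MCAR the observed and imputed distributions share a law: the
        KS statistic stays below the 1% critical value."""
        coh = rq.simulate_cohort(schema, pop, n=10_000, seed=51)
        models = rq.fit_conditional_models(coh, schema)
        holed = rq.apply_missingness(coh, "MCAR", rates={"pgs": 0.5}, seed=52)
        report = rq.compare_observed_imputed(holed, models, ["pgs"], seed=53)
        n1 = report["pgs"]["n_observed"]
        n2 = report["pgs"]["n_imputed"]
        crit = 1.63 * math.sqrt((n1 + n2) / (n1 * n2))
        assert report["pgs"]["ks_statistic"] < crit

    def test_fully_observed_variable_skipped(self, cohort, models):
        holed = rq.apply_missingness(cohort, "MCAR", rates={"bmi": 0.3}, seed=55)
        with pytest.warns(UserWarning, match="no missing"):
            report = rq.compare_observed_imputed(holed, models, ["bmi", "pgs"], seed=56)
        assert report["pgs"]["skipped"] is True
        assert report["bmi"]["skipped"] is False

    def test_mar_imputation_recovers_conditional_truth(self, schema, pop):
        """MAR on MD driven by BMI: observed and imputed means differ, but the
        imputed values match the suppressed truth (truth-holdout oracle)."""
        n = 10_000
        coh = rq.simulate_cohort(schema, pop, n=n, seed=57)
        models = rq.fit_conditional_models(coh, schema)
        truth = coh.records["mammographic_density"].to_numpy().copy()
        # higher BMI -> more likely missing MD
        b = 0.25
        a = -b * 26.0
        holed = rq.apply_missingness(
            coh, "MAR", mar_params={"mammographic_density": (a, {"bmi": b})}, seed=58
        )
        report = rq.compare_observed_imputed(
            holed, models, ["mammographic_density"], seed=59
        )
        r = report["mammographic_density"]
        mask = holed.records["mammographic_density"].isna().to_numpy()
        true_mean = truth[mask].mean()
        se = truth[mask].std(ddof=1) / math.sqrt(mask.sum()) * math.sqrt(2)
        assert abs(r["imputed_mean"] - true_mean) < 3 * se
        # MAR signature: the observed mean is a biased estimate of the truth
        assert abs(r["observed_mean"] - true_mean) > abs(r["imputed_mean"] - true_mean)
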