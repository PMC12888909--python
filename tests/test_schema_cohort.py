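"""Schema declarations and the Gaussian-copula cohort generator."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, ndtr
from scipy.stats import kendalltau, ks_2samp, spearmanr

import riskuq as rq
from riskuq.cohort import DEFAULT_MARGINS
from riskuq.schema import PV_LEVELS, VariableSpec


class TestSchema:
    def test_default_schema_structure(self, schema):
        qrfs = schema.group_members("QRF")
        assert len(qrfs) >= 6
        for name in ("bmi", "alcohol", "menarche_age", "parity", "hrt_use", "oc_use"):
            assert name in qrfs
        assert schema["alcohol"].kind == "semicontinuous-zero-inflated"
        md = schema.group_members("MD")
        assert len(md) == 1
        assert schema[md[0]].kind == "continuous-positive"
        assert schema[md[0]].transform == "log"
        pv = schema[schema.pv_variable]
        assert pv.kind == "categorical" and len(pv.levels) == 9
        assert pv.risk_effect[pv.reference] == 0.0
        pgs = schema[schema.pgs_variable]
        assert pgs.kind == "continuous" and pgs.center == 0.0 and pgs.scale == 1.0
        fh = schema.group_members("FH")
        assert schema[fh[0]].levels == ("0", "1", "2+")

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="log transform"):
            VariableSpec(name="x", kind="binary", group="QRF", transform="log")
        with pytest.raises(ValueError, match="reference"):
            VariableSpec(
                name="x", kind="categorical", group="QRF",
                levels=("a", "b"), risk_effect={"a": 0.5, "b": 0.0},
            )
        with pytest.raises(ValueError, match="unknown group"):
            VariableSpec(name="x", kind="binary", group="XX")

    def test_pv_schema_invariant(self, schema):
        with pytest.raises(ValueError, match="9 levels"):
            rq.RiskFactorSchema(
                variables=(schema["pgs"], schema["family_history"]),
                pv_variable="family_history",
            )


class TestSimulateCohort:
    def test_pgs_marginally_standard_normal(self, schema, pop):
        n = 10_000
        coh = rq.simulate_cohort(schema, pop, n=n, seed=3)
        pgs = coh.records["pgs"]
        assert abs(pgs.mean()) < 4 / np.sqrt(n)
        assert abs(pgs.std(ddof=1) - 1.0) < 0.05

    def test_pv_carrier_frequency_binomial(self, schema, pop):
        n = 100_000
        freqs = dict(pop.pv_frequencies)
        freqs["BRCA1"] = 0.001
        freqs["none"] += pop.pv_frequencies["BRCA1"] - 0.001
        pop2 = rq.PopulationModel(
            age_grid=pop.age_grid, incidence=pop.incidence,
            mortality=pop.mortality, pv_frequencies=freqs,
        )
        coh = rq.simulate_cohort(schema, pop2, n=n, seed=4)
        count = int((coh.records["pv"] == "BRCA1").sum())
        sd = np.sqrt(n * 0.001 * 0.999)
        assert abs(count - n * 0.001) <= 3 * sd

    def test_copula_rank_correlation_matches_oracle(self, schema, pop):
        """Latent correlation 0.5 between the BMI and MD scores must give the
        same Spearman correlation as a brute-force draw from the copula."""
        dep = rq.default_dependence(schema)
        dep.loc["bmi", "mammographic_density"] = 0.5
        dep.loc["mammographic_density", "bmi"] = 0.5
        coh = rq.simulate_cohort(schema, pop, n=10_000, dependence=dep, seed=5)
        got = spearmanr(coh.records["bmi"], coh.records["mammographic_density"]).statistic

        # oracle: 10^6 bivariate-normal draws mapped through the two margins
        rng = np.random.default_rng(99)
        z = rng.standard_normal((1_000_000, 2))
        z[:, 1] = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        bmi = np.exp(DEFAULT_MARGINS["bmi"][1]["mu"] + DEFAULT_MARGINS["bmi"][1]["sigma"] * z[:, 0])
        md = np.exp(
            DEFAULT_MARGINS["mammographic_density"][1]["mu"]
            + DEFAULT_MARGINS["mammographic_density"][1]["sigma"] * z[:, 1]
        )
        expected = spearmanr(bmi, md).statistic
        assert abs(got - expected) < 0.05

    def test_margins_invariant_to_dependence(self, schema, pop):
        """Copula property: each margin is unchanged by the latent correlation
        (KS distance below the 1% two-sample critical value at n=10,000)."""
        dep = rq.default_dependence(schema)
        dep.loc["bmi", "mammographic_density"] = 0.5
        dep.loc["mammographic_density", "bmi"] = 0.5
        indep = rq.default_dependence(schema) * 0 + np.eye(len(dep))
        indep.index, indep.columns = dep.index, dep.columns
        a = rq.simulate_cohort(schema, pop, n=10_000, dependence=dep, seed=6)
        b = rq.simulate_cohort(schema, pop, n=10_000, dependence=indep, seed=7)
        n = 10_000
        crit = 1.63 * np.sqrt(2 * n / (n * n))  # 1% KS critical value
        for col in ("bmi", "mammographic_density", "pgs"):
            d = ks_2samp(a.records[col], b.records[col]).statistic
            assert d < crit, col

    def test_domains_and_determinism(self, schema, pop, cohort):
        rec = cohort.records
        assert (rec["bmi"] > 0).all()
        assert (rec["mammographic_density"] > 0).all()
        assert (rec["alcohol"] >= 0).all()
        assert set(rec["pv"].unique()) <= set(PV_LEVELS)
        again = rq.simulate_cohort(schema, pop, n=4000, seed=21)
        pd.testing.assert_frame_equal(rec, again.records)

    def test_family_history_positively_associated_with_genetics(self, cohort):
        rec = cohort.records
        fh_num = rec["family_history"].map({"0": 0, "1": 1, "2+": 2})
        tau = kendalltau(rec["pgs"], fh_num).statistic
        assert tau > 0.02

    def test_non_positive_definite_dependence_rejected(self, schema, pop):
        dep = rq.default_dependence(schema)
        dep.iloc[:, :] = 0.99
        np.fill_diagonal(dep.values, 1.0)
        dep.iloc[0, 1] = dep.iloc[1, 0] = -0.99
        with pytest.raises(ValueError, match="positive definite"):
            rq.simulate_cohort(schema, pop, n=10, dependence=dep, seed=0)


class TestApplyMissingness:
    def test_zero_rates_identity(self, cohort, schema):
        out = rq.apply_missingness(
            cohort, "MCAR", rates={v.name: 0.0 for v in schema}, seed=1
        )
        pd.testing.assert_frame_equal(out.records, cohort.records)

    def test_mcar_rate_binomial(self, schema, pop):
        n = 10_000
        coh = rq.simulate_cohort(schema, pop, n=n, seed=8)
        out = rq.apply_missingness(coh, "MCAR", rates={"bmi": 0.3}, seed=9)
        miss = int(out.records["bmi"].isna().sum())
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(miss - 0.3 * n) <= 3 * sd
        assert len(out.records) == n  # rows never removed

    def test_mar_logistic_matches_direct_model(self, schema, pop):
        """P(missing)=0.1 at age 40 and 0.5 at age 70 pins down the logistic
        intercept/slope; empirical missingness at those ages must agree."""
        n = 40_000
        coh = rq.simulate_cohort(schema, pop, n=n, seed=10)
        # logit(0.1) = a + 40 b ; logit(0.5) = a + 70 b
        b = (0.0 - np.log(1 / 9)) / 30.0
        a = np.log(1 / 9) - 40.0 * b
        out = rq.apply_missingness(
            coh, "MAR", mar_params={"mammographic_density": (a, {"age": b})}, seed=11
        )
        for age, p in ((40, 0.1), (70, 0.5)):
            sel = out.records["age"] == age
            n_age = int(sel.sum())
            emp = out.records.loc[sel, "mammographic_density"].isna().mean()
            assert abs(emp - p) <= 3 * np.sqrt(p * (1 - p) / n_age)

    def test_mar_driver_with_missing_rejected(self, schema, pop):
        coh = rq.simulate_cohort(schema, pop, n=200, seed=12)
        holed = rq.apply_missingness(coh, "MCAR", rates={"bmi": 0.5}, seed=13)
        with pytest.raises(ValueError, match="driver"):
            rq.apply_missingness(
                holed, "MAR", mar_params={"alcohol": (0.0, {"bmi": 0.1})}, seed=14
            )
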