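"""Relative risk, baseline calibration, absolute risk, classification."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskuq as rq


def _reference_values(schema):
    vals = {}
    for v in schema:
        if v.is_categorical:
            vals[v.name] = v.reference
        elif v.kind == "binary":
            vals[v.name] = 0
        elif v.kind == "semicontinuous-zero-inflated":
            vals[v.name] = 0.0
        elif v.transform == "log":
            vals[v.name] = math.exp(v.center)
        else:
            vals[v.name] = v.center
    return vals


class TestRelativeRisk:
    def test_all_reference_profile_is_one(self, schema):
        prof = rq.IndividualProfile(age=40, values=_reference_values(schema))
        assert rq.relative_risk(prof, schema) == pytest.approx(1.0)

    def test_single_pgs_deviation(self, schema):
        vals = _reference_values(schema)
        vals["pgs"] = 1.0  # +1 SD, per-SD RR 1.6
        prof = rq.IndividualProfile(age=40, values=vals)
        assert rq.relative_risk(prof, schema) == pytest.approx(1.6)

    def test_term_by_term_oracle(self, schema, cohort):
        """Product of per-variable factors, each computed independently."""
        row = cohort.records.iloc[7]
        vals = {v.name: row[v.name] for v in schema}
        prof = rq.IndividualProfile(age=40, values=vals)
        expected = 1.0
        for v in schema:
            expected *= math.exp(v.log_rr(vals[v.name]))
        assert rq.relative_risk(prof, schema) == pytest.approx(expected, rel=1e-12)

    def test_log_additivity(self, schema):
        """RR of a multi-deviation profile equals the product of RRs of the
        single-deviation profiles."""
        ref = _reference_values(schema)
        deviations = {"pgs": 1.3, "bmi": 31.0, "pv": "CHEK2", "hrt_use": 1}
        product = 1.0
        for name, val in deviations.items():
            product *= rq.relative_risk(
                rq.IndividualProfile(age=40, values={**ref, name: val}), schema
            )
        combined = rq.relative_risk(
            rq.IndividualProfile(age=40, values={**ref, **deviations}), schema
        )
        assert combined == pytest.approx(product, rel=1e-12)

    def test_missing_entry_directs_to_uncertainty_module(self, schema):
        vals = _reference_values(schema)
        vals["pgs"] = None
        with pytest.raises(ValueError, match="uncertainty"):
            rq.relative_risk(rq.IndividualProfile(age=40, values=vals), schema)


class TestCalibration:
    def test_all_reference_cohort_gives_unit_calibration(self, schema, pop):
        rec = pd.DataFrame([_reference_values(schema)] * 50)
        cal = rq.calibrate_baseline(pop, schema, rec)
        assert np.allclose(cal.calibration, 1.0)

    def test_mean_rr_two_gives_calibration_two(self, schema, pop):
        ref = _reference_values(schema)
        low, high = dict(ref), dict(ref)
        # symmetric pair with mean RR 2: RRs 0.5 and 3.5
        low["pgs"] = math.log(0.5) / math.log(1.6)
        high["pgs"] = math.log(3.5) / math.log(1.6)
        rec = pd.DataFrame([low, high])
        cal = rq.calibrate_baseline(pop, schema, rec)
        assert np.allclose(cal.calibration, 2.0, rtol=1e-12)

    def test_conservation_on_synthetic_cohort(self, schema, pop, cohort, pop_cal):
        """Direct-averaging oracle: post-calibration cohort-mean hazard equals
        the population incidence at every age to 1e-6 relative."""
        rr = rq.relative_risk_frame(cohort.records, schema)
        for idx in (0, 20, 40, 60):
            lam = rr * pop_cal.incidence[idx] / pop_cal.calibration[idx]
            assert lam.mean() == pytest.approx(pop.incidence[idx], rel=1e-6)

    def test_empty_cohort_rejected(self, schema, pop):
        with pytest.raises(ValueError, match="empty"):
            rq.calibrate_baseline(pop, schema, pd.DataFrame(columns=[v.name for v in schema]))


def _constant_pop(lam, mu):
    ages = np.arange(20, 81)
    pop = rq.PopulationModel(
        age_grid=ages,
        incidence=np.full(ages.shape, lam),
        mortality=np.full(ages.shape, mu),
        pv_frequencies={},
    )
    pop.calibrated = True
    return pop


class TestAbsoluteRisk:
    def test_closed_form_no_competing_mortality(self):
        pop = _constant_pop(0.001, 0.0)
        risk = rq.absolute_risk_from_rr(1.0, pop, age=40, horizon=10)
        assert risk == pytest.approx(1 - math.exp(-0.01), rel=1e-4)

    def test_closed_form_competing_risk(self):
        lam, mu, T = 0.002, 0.010, 10
        pop = _constant_pop(lam, mu)
        risk = rq.absolute_risk_from_rr(1.0, pop, age=40, horizon=T)
        expected = lam / (lam + mu) * (1 - math.exp(-(lam + mu) * T))
        assert risk == pytest.approx(expected, rel=0.01)

    def test_age_varying_hazards_match_month_grid_oracle(self, pop):
        """Fine-discretization oracle: month grid with hazards held constant
        within each year."""
        rr = 2.3
        age, horizon = 45, 10
        lam = rr * pop.incidence[pop.age_index(age):][:horizon]
        mu = pop.mortality[pop.age_index(age):][:horizon]
        dt = 1.0 / 12.0
        surv, cum = 1.0, 0.0
        for t in range(horizon):
            for _ in range(12):
                cum += surv * lam[t] / (lam[t] + mu[t]) * (1 - math.exp(-(lam[t] + mu[t]) * dt))
                surv *= math.exp(-(lam[t] + mu[t]) * dt)
        pop_u = _constant_pop(0, 0)
        pop_u.incidence = pop.incidence
        pop_u.mortality = pop.mortality
        got = rq.absolute_risk_from_rr(rr, pop_u, age=age, horizon=horizon)
        assert got == pytest.approx(cum, rel=0.005)

    def test_zero_horizon_and_grid_errors(self, schema, pop_cal, cohort):
        row = cohort.records.iloc[0]
        vals = {v.name: row[v.name] for v in schema}
        prof = rq.IndividualProfile(age=40, horizon=0, values=vals)
        assert rq.absolute_risk(prof, pop_cal, schema) == 0.0
        with pytest.raises(ValueError, match="grid"):
            rq.absolute_risk(
                rq.IndividualProfile(age=15, values=vals), pop_cal, schema
            )
        with pytest.raises(ValueError, match="grid"):
            rq.absolute_risk(
                rq.IndividualProfile(age=75, horizon=10, values=vals), pop_cal, schema
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        log_rr=st.floats(-2.0, 3.0),
        horizon=st.integers(1, 30),
    )
    def test_monotone_in_rr_and_horizon(self, log_rr, horizon):
        pop = _constant_pop(0.002, 0.008)
        r = rq.absolute_risk_from_rr(math.exp(log_rr), pop, 40, horizon)
        r_more_rr = rq.absolute_risk_from_rr(math.exp(log_rr + 0.1), pop, 40, horizon)
        r_longer = rq.absolute_risk_from_rr(math.exp(log_rr), pop, 40, horizon + 1)
        assert 0.0 <= r < 1.0
        assert r_more_rr > r
        assert r_longer > r


class TestClassify:
    @pytest.mark.parametrize(
        "risk,label",
        [
            (0.025, "near-population"),
            (0.03, "moderate"),
            (0.05, "moderate"),
            (0.08, "moderate"),
            (0.09, "high"),
            (0.0, "near-population"),
            (1.0, "high"),
        ],
    )
    def test_nice_boundaries(self, risk, label):
        assert rq.classify(risk) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rq.classify(1.2)
        with pytest.raises(ValueError):
            rq.classify(-0.1)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            rq.CategoryScheme(thresholds=(0.08, 0.03))
        with pytest.raises(ValueError):
            rq.CategoryScheme(thresholds=(0.03,), labels=("a", "b", "c"))
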