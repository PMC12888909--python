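import numpy as np
import pytest

import riskuq as rq
from riskuq.toys import discrete_toy, gaussian_toy


@pytest.fixture(scope="session")
def schema():
    return rq.default_schema()


@pytest.fixture(scope="session")
def pop():
    return rq.default_population()


@pytest.fixture(scope="session")
def cohort(schema, pop):
    return rq.simulate_cohort(schema, pop, n=4000, seed=21)


@pytest.fixture(scope="session")
def models(cohort, schema):
    return rq.fit_conditional_models(cohort, schema)


@pytest.fixture(scope="session")
def pop_cal(pop, schema, cohort):
    return rq.calibrate_baseline(pop, schema, cohort)


@pytest.fixture(scope="session")
def fh_profile(schema):
    """Index woman, age 40: two affected first-degree relatives, all other
    risk factors unmeasured."""
    values = {v.name: None for v in schema}
    values["family_history"] = "2+"
    return rq.IndividualProfile(age=40, horizon=10, values=values)


@pytest.fixture(scope="session")
def toy():
    return discrete_toy()


@pytest.fixture(scope="session")
def toy_models(toy):
    # plain MLE: fitted conditionals equal the empirical table exactly
    return rq.fit_conditional_models(toy.cohort, toy.schema, ridge_alpha=None)


@pytest.fixture(scope="session")
def gauss():
    return gaussian_toy(n=5000, seed=11, rho=0.5)


@pytest.fixture(scope="session")
def gauss_models(gauss):
    return rq.fit_conditional_models(gauss.cohort, gauss.schema)


def toy_exact_summary(toy, scheme=None, **observed):
    """Enumeration oracle: exact point estimate and category probabilities
    of the toy risk distribution given the observed factors."""
    scheme = scheme or rq.CategoryScheme()
    risks, probs = toy.enumerate_distribution(**observed)
    idx = rq.classify_array(risks, scheme)
    cats = {lab: float(probs[idx == i].sum()) for i, lab in enumerate(scheme.labels)}
    return float((risks * probs).sum()), cats
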