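"""Small exactly-solvable systems for validating the Monte Carlo pipeline.

Two fixtures are provided:

* a **discrete toy**: three binary risk factors with a known joint law
  (tabulated over 8 cells) and a tabulated risk function, where every
  quantity the pipeline estimates — category probabilities, point
  estimates, reclassification flows — can be computed exactly by
  enumeration;
* a **Gaussian toy**: a 4-variable multivariate-normal system where the
  conditional distribution of the missing variables given the observed one
  has a closed form.

The discrete cohort is built with *exact* cell counts chosen so that the
third factor is exactly independent of the first two in the sample. The
maximum-likelihood main-effects logistic conditionals then coincide
exactly with the empirical conditionals of the 8-cell table, so the
chained sampler's target law is the empirical joint itself and the
enumeration oracle is exact (no model-fit approximation enters).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ReferenceCohort
from .population import PopulationModel
from .risk import IndividualProfile, absolute_risk_from_rr, calibrate_baseline
from .schema import RiskFactorSchema, VariableSpec

__all__ = ["DiscreteToy", "discrete_toy", "GaussianToy", "gaussian_toy"]


@dataclass
class DiscreteToy:
    """Three-binary-factor system with enumerable joint law and risks."""

    schema: RiskFactorSchema
    cohort: ReferenceCohort
    pop: PopulationModel  # calibrated
    profile: IndividualProfile  # factor_a observed = 0, b and c missing
    joint: pd.DataFrame  # columns a, b, c, prob
    age: int = 40
    horizon: int = 10

    def cell_risk(self, a: int, b: int, c: int) -> float:
        """Deterministic absolute risk of a fully specified cell."""
        rr = math.exp(
            a * self.schema["factor_a"].risk_effect
            + b * self.schema["factor_b"].risk_effect
            + c * self.schema["factor_c"].risk_effect
        )
        return float(absolute_risk_from_rr(rr, self.pop, self.age, self.horizon))

    def conditional(self, **observed) -> pd.DataFrame:
        """Exact conditional law of the cells given observed factors."""
        sub = self.joint
        for k, v in observed.items():
            sub = sub[sub[k.replace("factor_", "") if k.startswith("factor_") else k] == v]
        sub = sub.copy()
        sub["prob"] = sub["prob"] / sub["prob"].sum()
        return sub

    def enumerate_distribution(self, **observed):
        """Exact (risk, probability) pairs given observed factors."""
        sub = self.conditional(**observed)
        risks = np.array([self.cell_risk(r.a, r.b, r.c) for r in sub.itertuples()])
        return risks, sub["prob"].to_numpy()


def discrete_toy(
    incidence: float = 0.011,
    mortality: float = 0.005,
    effects=(math.log(3.0), math.log(2.2), math.log(1.5)),
) -> DiscreteToy:
    """Build the discrete validation toy.

    Factors: ``factor_a`` (questionnaire group, observed in the index
    profile), ``factor_b`` (genetic group) and ``factor_c`` (density
    group), all binary. The cohort holds 800 records with exact counts:
    the (a, b) margin is [[320, 160], [80, 240]] (odds ratio 6) and c is
    exactly independent with P(c=1) = 3/8. The population model has
    constant hazards and is calibrated on the cohort.
    """
    schema = RiskFactorSchema(
        variables=(
            VariableSpec(name="factor_a", kind="binary", group="QRF", risk_effect=effects[0]),
            VariableSpec(name="factor_b", kind="binary", group="GF", risk_effect=effects[1]),
            VariableSpec(name="factor_c", kind="binary", group="MD", risk_effect=effects[2]),
        )
    )
    n_ab = {(0, 0): 320, (0, 1): 160, (1, 0): 80, (1, 1): 240}
    n_c1, n_total = 300, 800
    rows = []
    cells = []
    for (a, b), nab in n_ab.items():
        for c, w in ((0, n_total - n_c1), (1, n_c1)):
            count = nab * w // n_total  # exact by construction
            rows.extend([(a, b, c)] * count)
            cells.append({"a": a, "b": b, "c": c, "prob": count / n_total})
    records = pd.DataFrame(rows, columns=["factor_a", "factor_b", "factor_c"]).astype(float)
    cohort = ReferenceCohort(
        records=records, schema=schema, provenance={"generator": "exact-counts"}
    )
    ages = np.arange(20, 81)
    pop = PopulationModel(
        age_grid=ages,
        incidence=np.full(ages.shape, incidence),
        mortality=np.full(ages.shape, mortality),
        pv_frequencies={},
    )
    pop = calibrate_baseline(pop, schema, cohort)
    profile = IndividualProfile(
        age=40, horizon=10, values={"factor_a": 0.0, "factor_b": None, "factor_c": None}
    )
    joint = pd.DataFrame(cells)
    return DiscreteToy(schema=schema, cohort=cohort, pop=pop, profile=profile, joint=joint)


@dataclass
class GaussianToy:
    """4-variable multivariate-normal system with closed-form conditionals."""

    schema: RiskFactorSchema
    cohort: ReferenceCohort
    mean: np.ndarray
    cov: np.ndarray
    names: list

    def conditional(self, observed: dict):
        """Exact conditional mean vector and covariance of the missing
        variables given the observed ones (multivariate-normal formula)."""
        obs_idx = [self.names.index(k) for k in observed]
        mis_idx = [i for i in range(len(self.names)) if i not in obs_idx]
        S = self.cov
        S11 = S[np.ix_(mis_idx, mis_idx)]
        S12 = S[np.ix_(mis_idx, obs_idx)]
        S22 = S[np.ix_(obs_idx, obs_idx)]
        x_obs = np.array([observed[self.names[i]] for i in obs_idx])
        mu_mis = self.mean[mis_idx]
        mu_obs = self.mean[obs_idx]
        K = S12 @ np.linalg.inv(S22)
        cond_mean = mu_mis + K @ (x_obs - mu_obs)
        cond_cov = S11 - K @ S12.T
        return [self.names[i] for i in mis_idx], cond_mean, cond_cov


def gaussian_toy(n: int = 5000, seed: int = 0, rho: float = 0.5) -> GaussianToy:
    """4 jointly normal covariates with exchangeable correlation ``rho``."""
    names = [f"x{i + 1}" for i in range(4)]
    schema = RiskFactorSchema(
        variables=tuple(
            VariableSpec(name=nm, kind="continuous", group="QRF", risk_effect=0.1)
            for nm in names
        )
    )
    mean = np.zeros(4)
    cov = np.full((4, 4), rho)
    np.fill_diagonal(cov, 1.0)
    rng = np.random.default_rng(seed)
    data = rng.multivariate_normal(mean, cov, size=n)
    cohort = ReferenceCohort(
        records=pd.DataFrame(data, columns=names),
        schema=schema,
        provenance={"generator": "mvn", "rho": rho, "n": n, "seed": seed},
    )
    return GaussianToy(schema=schema, cohort=cohort, mean=mean, cov=cov, names=names)
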