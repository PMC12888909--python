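"""Synthetic reference-cohort generation.

A Gaussian copula over latent normal scores drives the dependence between
covariates; each margin is then mapped to its declared distribution
(log-normal mammographic density and BMI, zero-inflated log-normal alcohol
intake, standard-normal polygenic score, multinomial rare-variant status).
Family history is *not* part of the copula: the count of affected
first-degree relatives is drawn conditionally on the polygenic score and
pathogenic-variant status through a continuation-ratio logistic link, so
that family history is positively associated with the genetic factors and
measuring genetics changes the conditional family-history/risk relationship.

Missingness can then be imposed completely at random (MCAR) or at random
given observed drivers (MAR, logistic model).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .population import PopulationModel
from .schema import RiskFactorSchema

__all__ = [
    "ReferenceCohort",
    "simulate_cohort",
    "apply_missingness",
    "default_dependence",
    "DEFAULT_MARGINS",
    "DEFAULT_FH_PARAMS",
]


@dataclass
class ReferenceCohort:
    """Tabular reference records keyed by schema variable names.

    Missing entries are encoded as NaN (continuous/binary) or None/NaN
    (categorical). ``provenance`` records generator parameters and seed.
    """

    records: pd.DataFrame
    schema: RiskFactorSchema
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.records) < 1:
            raise ValueError("cohort must contain at least one record")
        for v in self.schema:
            if v.name not in self.records.columns:
                raise ValueError(f"cohort missing schema column {v.name!r}")
            col = self.records[v.name]
            if col.isna().all():
                raise ValueError(f"column {v.name!r} is entirely missing")
            obs = col.dropna()
            if v.is_categorical:
                bad = set(obs.unique()) - set(v.levels)
                if bad:
                    raise ValueError(f"column {v.name!r} has undeclared levels {bad}")
            elif v.kind == "continuous-positive":
                if (obs.astype(float) <= 0).any():
                    raise ValueError(f"column {v.name!r} must be positive")
            elif v.kind == "semicontinuous-zero-inflated":
                if (obs.astype(float) < 0).any():
                    raise ValueError(f"column {v.name!r} must be non-negative")

    def __len__(self):
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def is_complete(self) -> bool:
        return not self.records[self.schema.names].isna().any().any()


#: Default marginal distributions for the default schema's covariates.
#: Types: normal(mean, sd); lognormal(mu, sigma) of the log;
#: zero-inflated-lognormal(p_zero, mu, sigma); bernoulli(p);
#: categorical(probs aligned with the declared levels).
DEFAULT_MARGINS = {
    "bmi": ("lognormal", {"mu": np.log(26.0), "sigma": 0.18}),
    "alcohol": ("zero-inflated-lognormal", {"p_zero": 0.25, "mu": np.log(6.0), "sigma": 0.9}),
    "menarche_age": ("normal", {"mean": 13.0, "sd": 1.6}),
    "parity": ("categorical", {"probs": (0.20, 0.25, 0.35, 0.20)}),
    "hrt_use": ("bernoulli", {"p": 0.25}),
    "oc_use": ("bernoulli", {"p": 0.60}),
    "mammographic_density": ("lognormal", {"mu": np.log(20.0), "sigma": 0.55}),
    "pgs": ("normal", {"mean": 0.0, "sd": 1.0}),
    # "pv" margin comes from PopulationModel.pv_frequencies
}

#: Continuation-ratio logistic parameters linking family history to genetics:
#: P(>=1 affected relative) and P(2+ | >=1) both rise with the polygenic
#: score and with carrying any pathogenic variant.
DEFAULT_FH_PARAMS = {
    "intercept1": -1.99,  # ~12% with >=1 affected relative at PGS=0, no PV
    "intercept2": -1.73,  # ~15% of those have 2+
    "slope_pgs": 0.35,
    "slope_pv": 1.2,
}


def default_dependence(schema: RiskFactorSchema) -> pd.DataFrame:
    """Default latent correlation matrix for the copula covariates.

    Modest, plausible correlations: BMI is negatively correlated with
    percent mammographic density and weakly positively with alcohol intake;
    everything else is independent at the latent level.
    """
    names = [v.name for v in schema if v.group != "FH"]
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pairs = [("bmi", "mammographic_density", -0.25), ("bmi", "alcohol", 0.10)]
    for a, b, r in pairs:
        if a in names and b in names:
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def _margin_from_latent(kind, params, z, u, rng):
    """Map latent normal scores z (and their uniforms u) to a margin."""
    if kind == "normal":
        return params["mean"] + params["sd"] * z
    if kind == "lognormal":
        return np.exp(params["mu"] + params["sigma"] * z)
    if kind == "zero-inflated-lognormal":
        p0 = params["p_zero"]
        out = np.zeros_like(z)
        pos = u >= p0
        # conditional quantile of the positive part
        v = (u[pos] - p0) / (1.0 - p0)
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        out[pos] = np.exp(params["mu"] + params["sigma"] * ndtri(v))
        return out
    if kind == "bernoulli":
        return (u >= 1.0 - params["p"]).astype(int)
    if kind == "categorical":
        cum = np.cumsum(params["probs"])
        if abs(cum[-1] - 1.0) > 1e-9:
            raise ValueError("categorical margin probabilities must sum to 1")
        return np.searchsorted(cum, u, side="right").clip(0, len(cum) - 1)
    raise ValueError(f"unknown margin kind {kind!r}")


def simulate_cohort(
    schema: RiskFactorSchema,
    pop: PopulationModel,
    n: int,
    dependence: pd.DataFrame | None = None,
    seed: int = 0,
    margins: dict | None = None,
    fh_params: dict | None = None,
    age_range: tuple = (40, 70),
) -> ReferenceCohort:
    """Draw a synthetic reference cohort of ``n`` complete records.

    Covariates other than family history are generated through a Gaussian
    copula (latent scores ``z ~ N(0, dependence)``, margins mapped by
    inverse CDF); family history is drawn conditionally on the polygenic
    score and pathogenic-variant status. An auxiliary uniform ``age`` column
    (useful as a MAR driver) is included; it is not a schema covariate.

    Raises ``ValueError`` if ``dependence`` is not positive definite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    margins = dict(DEFAULT_MARGINS if margins is None else margins)
    fh_params = dict(DEFAULT_FH_PARAMS if fh_params is None else fh_params)
    if dependence is None:
        dependence = default_dependence(schema)
    copula_names = [v.name for v in schema if v.group != "FH"]
    dep = dependence.loc[copula_names, copula_names].to_numpy(dtype=float)
    if not np.allclose(dep, dep.T):
        raise ValueError("dependence matrix must be symmetric")
    try:
        chol = np.linalg.cholesky(dep)
    except np.linalg.LinAlgError as err:
        raise ValueError("dependence matrix is not positive definite") from err

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(copula_names))) @ chol.T
    u = ndtr(z)

    data = {}
    for j, name in enumerate(copula_names):
        spec = schema[name]
        if name == schema.pv_variable:
            probs = [pop.pv_frequencies[lvl] for lvl in spec.levels]
            codes = _margin_from_latent("categorical", {"probs": probs}, z[:, j], u[:, j], rng)
            data[name] = np.asarray(spec.levels, dtype=object)[codes]
            continue
        if name not in margins:
            raise ValueError(f"no margin declared for variable {name!r}")
        kind, params = margins[name]
        vals = _margin_from_latent(kind, params, z[:, j], u[:, j], rng)
        if spec.is_categorical:
            data[name] = np.asarray(spec.levels, dtype=object)[np.asarray(vals, dtype=int)]
        else:
            data[name] = vals

    # family history conditional on genetics (continuation-ratio logistic)
    fh_vars = [v for v in schema if v.group == "FH"]
    if fh_vars:
        (fh_spec,) = fh_vars
        pgs = np.asarray(data[schema.pgs_variable], dtype=float)
        has_pv = (data[schema.pv_variable] != schema[schema.pv_variable].reference).astype(float)
        eta = fh_params["slope_pgs"] * pgs + fh_params["slope_pv"] * has_pv
        p_ge1 = expit(fh_params["intercept1"] + eta)
        p_2plus = expit(fh_params["intercept2"] + eta)
        u1 = rng.random(n)
        u2 = rng.random(n)
        count = (u1 < p_ge1).astype(int) + ((u1 < p_ge1) & (u2 < p_2plus)).astype(int)
        data[fh_spec.name] = np.asarray(fh_spec.levels, dtype=object)[count]

    data["age"] = rng.integers(age_range[0], age_range[1] + 1, size=n)
    records = pd.DataFrame(data, columns=schema.names + ["age"])
    provenance = {
        "generator": "gaussian-copula",
        "n": int(n),
        "seed": int(seed),
        "margins": {k: [v[0], {kk: float(vv) if np.isscalar(vv) else list(map(float, vv)) for kk, vv in v[1].items()}] for k, v in margins.items()},
        "fh_params": {k: float(v) for k, v in fh_params.items()},
        "dependence": dependence.loc[copula_names, copula_names].to_numpy().tolist(),
        "age_range": list(age_range),
    }
    return ReferenceCohort(records=records, schema=schema, provenance=provenance)


def apply_missingness(
    cohort: ReferenceCohort,
    mechanism: str,
    rates: dict | None = None,
    drivers: list | None = None,
    mar_params: dict | None = None,
    seed: int = 0,
) -> ReferenceCohort:
    """Flag entries of a cohort as missing under MCAR or MAR.

    MCAR: each entry of variable ``v`` is masked with probability
    ``rates[v]``. MAR: ``mar_params[v] = (intercept, {driver: slope})``
    defines a per-row logistic missingness probability on fully observed
    driver columns. Rows are never removed.
    """
    records = cohort.records.copy()
    rng = np.random.default_rng(seed)
    n = len(records)
    if mechanism == "MCAR":
        if not rates:
            raise ValueError("MCAR requires per-variable rates")
        for name, rate in rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate for {name!r} must be in [0, 1]")
            if rate == 0.0:
                continue
            mask = rng.random(n) < rate
            records.loc[mask, name] = np.nan
    elif mechanism == "MAR":
        if not mar_params:
            raise ValueError("MAR requires mar_params: {var: (intercept, {driver: slope})}")
        drivers = drivers or sorted(
            {d for _, slopes in mar_params.values() for d in slopes}
        )
        for d in drivers:
            if records[d].isna().any():
                raise ValueError(f"MAR driver {d!r} has missing entries")
        for name, (intercept, slopes) in mar_params.items():
            eta = np.full(n, float(intercept))
            for d, slope in slopes.items():
                eta = eta + float(slope) * records[d].to_numpy(dtype=float)
            mask = rng.random(n) < expit(eta)
            records.loc[mask, name] = np.nan
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}; use 'MCAR' or 'MAR'")

    for name in cohort.schema.names:
        if records[name].isna().all():
            raise ValueError(f"missingness left column {name!r} entirely missing")
    provenance = dict(cohort.provenance)
    provenance["missingness"] = {
        "mechanism": mechanism,
        "rates": {k: float(v) for k, v in (rates or {}).items()},
        "mar_params": {
            k: [float(i), {d: float(s) for d, s in sl.items()}]
            for k, (i, sl) in (mar_params or {}).items()
        },
        "seed": int(seed),
    }
    return ReferenceCohort(records=records, schema=cohort.schema, provenance=provenance)
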