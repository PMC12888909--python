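"""Multivariate imputation by chained equations (fully conditional specification).

Each variable with missing entries gets a conditional regression model on
all other covariates (family chosen by variable type, see
:mod:`riskuq.models`). Imputation initializes missing entries by draws from
the observed marginals and then cycles through the variables, each time
drawing model parameters from their asymptotic sampling distribution
("proper" imputation) and the missing value from the resulting conditional
model. Convergence is monitored with per-chain traces of the mean and SD
across iterations and the Gelman-Rubin potential scale reduction factor.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from . import models as _m
from .cohort import ReferenceCohort
from .risk import IndividualProfile
from .schema import RiskFactorSchema

__all__ = [
    "ImputationModelSet",
    "CompletedProfileSet",
    "ConvergenceReport",
    "fit_conditional_models",
    "chained_impute",
    "impute_cohort",
    "gelman_rubin",
    "compare_observed_imputed",
]

_POOL_MAX = 5000  # marginal-draw pool size stored per variable


@dataclass
class ImputationModelSet:
    """Fitted conditional models, visit order and marginal-draw pools."""

    schema: RiskFactorSchema
    models: dict
    visit_order: list
    marginal_pools: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in self.schema:
            if v.name not in self.models:
                raise ValueError(f"no fitted model for variable {v.name!r}")


@dataclass
class CompletedProfileSet:
    """M completed covariate vectors for one index profile.

    Every vector agrees with the profile on all observed entries; traces
    hold per-chain, per-iteration means and SDs of each imputed variable
    (on the numeric/code scale) for convergence diagnostics.
    """

    profile: IndividualProfile
    data: pd.DataFrame
    chain_ids: np.ndarray
    traces: dict
    M: int
    n_iter: int
    n_chains: int
    seed: int


def _encode_value(spec, value):
    if spec.is_categorical or (spec.kind == "binary" and spec.levels):
        return float(spec.levels.index(value))
    return float(value)


def _cohort_hash(frame: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(str(pd.util.hash_pandas_object(frame).sum()).encode())
    return h.hexdigest()[:16]


def fit_conditional_models(
    cohort: ReferenceCohort,
    schema: RiskFactorSchema | None = None,
    ridge_alpha: float | None = _m._RIDGE_ALPHA,
    visit_order: list | None = None,
) -> ImputationModelSet:
    """Fit one conditional model per schema variable on a reference cohort.

    Each model is fit on the rows where its target (and every predictor) is
    observed; all other schema variables are predictors. Raises if a
    declared categorical level is absent from the training data, or if the
    cohort is too small relative to the number of predictors (fewer than 10
    observations per design column).
    """
    schema = schema or cohort.schema
    codes = _m.encode_frame(cohort.records, schema)
    observed = {name: ~np.isnan(arr) for name, arr in codes.items()}
    visit_order = list(visit_order or schema.names)
    if set(visit_order) != set(schema.names):
        raise ValueError("visit_order must cover exactly the schema variables")

    fitted, pools = {}, {}
    for spec in schema:
        name = spec.name
        rows = observed[name].copy()
        for other in schema.names:
            if other != name:
                rows &= observed[other]
        n_rows = int(rows.sum())
        p = _m.n_predictors(schema, name)
        if n_rows < 10 * p:
            raise ValueError(
                f"{name}: only {n_rows} complete training rows for {p} "
                f"predictors; need at least {10 * p}"
            )
        y = codes[name][rows]
        if spec.is_categorical:
            present = set(np.unique(y.astype(int)))
            absent = [lvl for i, lvl in enumerate(spec.levels) if i not in present]
            if absent:
                raise ValueError(
                    f"{name}: level(s) {absent} absent from the training data; "
                    "enlarge the cohort or merge categories"
                )
        X = _m.predictor_matrix(codes, schema, name, rows=np.where(rows)[0])
        fitted[name] = _m.fit_variable_model(spec, X, y, ridge_alpha)
        pool = codes[name][observed[name]]
        if len(pool) > _POOL_MAX:
            step = len(pool) / _POOL_MAX
            pool = pool[(np.arange(_POOL_MAX) * step).astype(int)]
        pools[name] = pool.copy()

    provenance = {
        "n": len(cohort),
        "cohort_hash": _cohort_hash(cohort.records[schema.names]),
        "ridge_alpha": ridge_alpha,
        "ridged_variables": [k for k, m in fitted.items() if getattr(m, "ridged", False)
                             or getattr(getattr(m, "zero_part", None), "ridged", False)],
    }
    return ImputationModelSet(
        schema=schema,
        models=fitted,
        visit_order=visit_order,
        marginal_pools=pools,
        provenance=provenance,
    )


def chained_impute(
    profile: IndividualProfile,
    models: ImputationModelSet,
    M: int,
    n_iter: int = 10,
    n_chains: int = 4,
    seed: int = 0,
    proper: bool = True,
) -> CompletedProfileSet:
    """Draw M completed covariate vectors for one profile.

    The M samples run as parallel chains grouped into ``n_chains`` blocks
    for diagnostics. Missing entries are initialized by draws from the
    observed marginals, then each variable in the visit order is redrawn
    from its conditional model for ``n_iter`` sweeps; observed entries are
    never altered.
    """
    if models is None:
        raise ValueError("models must be a fitted ImputationModelSet")
    if M < 1:
        raise ValueError("M must be >= 1")
    schema = models.schema
    profile.validate(schema)
    missing = [v for v in models.visit_order if v in profile.missing_variables(schema)]
    rng = np.random.default_rng(seed)

    codes = {}
    for spec in schema:
        if spec.name in missing:
            pool = models.marginal_pools[spec.name]
            codes[spec.name] = rng.choice(pool, size=M, replace=True)
        else:
            codes[spec.name] = np.full(M, _encode_value(spec, profile.values[spec.name]))

    n_chains = max(1, min(n_chains, M))
    chain_ids = np.minimum((np.arange(M) * n_chains) // M, n_chains - 1)
    traces = {
        v: {"mean": np.zeros((n_chains, n_iter)), "sd": np.zeros((n_chains, n_iter))}
        for v in missing
    }
    if missing:
        for it in range(n_iter):
            for name in missing:
                X = _m.predictor_matrix(codes, schema, name)
                codes[name] = models.models[name].draw(X, rng, proper=proper)
            for name in missing:
                for c in range(n_chains):
                    vals = codes[name][chain_ids == c]
                    traces[name]["mean"][c, it] = vals.mean()
                    traces[name]["sd"][c, it] = vals.std(ddof=1) if len(vals) > 1 else 0.0

    data = _m.decode_codes(codes, schema)
    return CompletedProfileSet(
        profile=profile,
        data=data,
        chain_ids=chain_ids,
        traces=traces,
        M=M,
        n_iter=n_iter,
        n_chains=n_chains,
        seed=seed,
    )


def gelman_rubin(chains) -> float:
    """Gelman-Rubin potential scale reduction factor (PSRF, R-hat).

    ``chains`` is an (m, n) array: m >= 2 chains of n >= 2 iterations of a
    scalar quantity. Returns sqrt(((n-1)/n * W + B/n) / W) with W the mean
    within-chain variance and B = n * variance of the chain means. If the
    within-chain variance is zero: returns 1.0 when the chains are also
    identical in mean, +inf otherwise.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of >= 2 iterations each")
    m, n = arr.shape
    W = float(arr.var(axis=1, ddof=1).mean())
    B = float(n * arr.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


@dataclass
class ConvergenceReport:
    """Per-variable R-hat of the mean and SD traces of a chained imputation."""

    rhat: dict
    traces: dict
    n_iter: int
    n_chains: int

    @classmethod
    def from_completed(cls, completed: CompletedProfileSet) -> "ConvergenceReport":
        rhat = {}
        for name, tr in completed.traces.items():
            rhat[name] = {
                "mean": gelman_rubin(tr["mean"]) if completed.n_chains >= 2 else float("nan"),
                "sd": gelman_rubin(tr["sd"]) if completed.n_chains >= 2 else float("nan"),
            }
        return cls(
            rhat=rhat,
            traces=completed.traces,
            n_iter=completed.n_iter,
            n_chains=completed.n_chains,
        )

    @property
    def max_rhat(self) -> float:
        vals = [v for d in self.rhat.values() for v in d.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, tr in self.traces.items():
            for c in range(tr["mean"].shape[0]):
                for it in range(tr["mean"].shape[1]):
                    rows.append(
                        {
                            "variable": name,
                            "chain": c,
                            "iteration": it,
                            "mean": tr["mean"][c, it],
                            "sd": tr["sd"][c, it],
                        }
                    )
        return pd.DataFrame(rows)


def impute_cohort(
    cohort: ReferenceCohort,
    models: ImputationModelSet,
    n_iter: int = 10,
    seed: int = 0,
    proper: bool = True,
) -> pd.DataFrame:
    """Single imputation of a cohort's missing entries (one completed copy).

    One parameter draw per variable per sweep is shared across the cohort
    (a dataset-level imputation, as opposed to the per-sample draws used
    for an individual's Monte Carlo risk distribution).
    """
    schema = models.schema
    codes = _m.encode_frame(cohort.records, schema)
    miss_rows = {name: np.where(np.isnan(arr))[0] for name, arr in codes.items()}
    rng = np.random.default_rng(seed)
    for name, rows in miss_rows.items():
        if len(rows):
            pool = models.marginal_pools[name]
            codes[name][rows] = rng.choice(pool, size=len(rows), replace=True)
    targets = [v for v in models.visit_order if len(miss_rows[v])]
    for _ in range(n_iter):
        for name in targets:
            rows = miss_rows[name]
            X = _m.predictor_matrix(codes, schema, name, rows=rows)
            codes[name][rows] = models.models[name].draw(
                X, rng, proper=proper, common_params=True
            )
    out = _m.decode_codes(codes, schema)
    for col in cohort.records.columns:
        if col not in out.columns:
            out[col] = cohort.records[col].to_numpy()
    return out


def compare_observed_imputed(
    cohort: ReferenceCohort,
    models: ImputationModelSet,
    variables: list | None = None,
    seed: int = 0,
    n_iter: int = 10,
) -> dict:
    """Compare observed vs imputed value distributions per variable.

    Imputes the cohort's missing entries once and reports, per selected
    variable, summary statistics of the observed and the imputed values
    plus a two-sample KS statistic (continuous) or total-variation distance
    (categorical/binary). Fully observed variables are skipped with a
    warning and flagged in the report.
    """
    schema = models.schema
    completed = impute_cohort(cohort, models, n_iter=n_iter, seed=seed)
    if variables is None:
        variables = [
            v.name for v in schema if cohort.records[v.name].isna().any()
        ]
    report = {}
    for name in variables:
        spec = schema[name]
        mask = cohort.records[name].isna().to_numpy()
        if not mask.any():
            warnings.warn(f"variable {name!r} has no missing entries; skipped")
            report[name] = {"skipped": True, "reason": "fully observed"}
            continue
        obs = cohort.records[name][~mask]
        imp = completed[name][mask]
        if spec.is_categorical or spec.kind == "binary":
            levels = list(spec.levels) if spec.levels else [0.0, 1.0]
            f_obs = np.array([np.mean(obs == lvl) for lvl in levels])
            f_imp = np.array([np.mean(imp == lvl) for lvl in levels])
            report[name] = {
                "skipped": False,
                "type": "categorical",
                "levels": [str(l) for l in levels],
                "observed_freqs": f_obs.tolist(),
                "imputed_freqs": f_imp.tolist(),
                "tv_distance": float(0.5 * np.abs(f_obs - f_imp).sum()),
                "n_observed": int((~mask).sum()),
                "n_imputed": int(mask.sum()),
            }
        else:
            o = obs.to_numpy(dtype=float)
            i = imp.to_numpy(dtype=float)
            ks = ks_2samp(o, i)
            report[name] = {
                "skipped": False,
                "type": "continuous",
                "observed_mean": float(o.mean()),
                "observed_sd": float(o.std(ddof=1)),
                "imputed_mean": float(i.mean()),
                "imputed_sd": float(i.std(ddof=1)),
                "ks_statistic": float(ks.statistic),
                "ks_pvalue": float(ks.pvalue),
                "n_observed": len(o),
                "n_imputed": len(i),
            }
    return report
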