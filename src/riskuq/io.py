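"""File round-trips: cohorts (CSV + sidecar schema JSON), profiles (JSON or
single-row CSV), fitted model sets (JSON), risk distributions and
reclassification flows (CSV + JSON summaries).

Missing values are encoded as empty CSV fields and JSON ``null``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as _m
from .cohort import ReferenceCohort
from .mice import ImputationModelSet
from .reclassification import ReclassificationFlow
from .risk import IndividualProfile
from .schema import RiskFactorSchema, VariableSpec
from .uncertainty import RiskDistribution

__all__ = [
    "schema_to_dict",
    "schema_from_dict",
    "write_schema",
    "read_schema",
    "write_cohort",
    "read_cohort",
    "write_profile",
    "read_profile",
    "write_model_set",
    "read_model_set",
    "write_distribution",
    "write_flow",
]


# -- schema ---------------------------------------------------------------

def schema_to_dict(schema: RiskFactorSchema) -> dict:
    return {
        "variables": [
            {
                "name": v.name,
                "kind": v.kind,
                "group": v.group,
                "transform": v.transform,
                "levels": list(v.levels),
                "risk_effect": v.risk_effect,
                "center": v.center,
                "scale": v.scale,
                "reference": v.reference,
                "description": v.description,
            }
            for v in schema
        ],
        "pv_variable": schema.pv_variable,
        "pgs_variable": schema.pgs_variable,
    }


def schema_from_dict(d: dict) -> RiskFactorSchema:
    variables = tuple(
        VariableSpec(
            name=v["name"],
            kind=v["kind"],
            group=v["group"],
            transform=v.get("transform", "identity"),
            levels=tuple(v.get("levels", ())),
            risk_effect=v["risk_effect"],
            center=v.get("center", 0.0),
            scale=v.get("scale", 1.0),
            reference=v.get("reference"),
            description=v.get("description", ""),
        )
        for v in d["variables"]
    )
    return RiskFactorSchema(
        variables=variables,
        pv_variable=d.get("pv_variable"),
        pgs_variable=d.get("pgs_variable"),
    )


def write_schema(schema: RiskFactorSchema, path) -> None:
    Path(path).write_text(json.dumps(schema_to_dict(schema), indent=2, sort_keys=True))


def read_schema(path) -> RiskFactorSchema:
    return schema_from_dict(json.loads(Path(path).read_text()))


# -- cohort ---------------------------------------------------------------

def write_cohort(cohort: ReferenceCohort, csv_path) -> None:
    """Cohort CSV with empty fields for missing entries, plus sidecar
    ``<stem>.schema.json`` and ``<stem>.provenance.json`` files."""
    csv_path = Path(csv_path)
    cohort.records.to_csv(csv_path, index=False, na_rep="")
    write_schema(cohort.schema, csv_path.with_suffix(".schema.json"))
    csv_path.with_suffix(".provenance.json").write_text(
        json.dumps(cohort.provenance, indent=2, sort_keys=True)
    )


def read_cohort(csv_path, schema: RiskFactorSchema | None = None) -> ReferenceCohort:
    csv_path = Path(csv_path)
    if schema is None:
        schema = read_schema(csv_path.with_suffix(".schema.json"))
    records = pd.read_csv(csv_path, keep_default_na=True)
    def _level_str(x):
        # numeric level labels survive the CSV round-trip as ints/floats
        if isinstance(x, float) and x.is_integer():
            return str(int(x))
        return str(x)

    for v in schema:
        if v.is_categorical or (v.kind == "binary" and v.levels):
            col = records[v.name].astype(object)
            ok = col.notna()
            records[v.name] = col
            records.loc[ok, v.name] = col[ok].map(_level_str)
    prov_path = csv_path.with_suffix(".provenance.json")
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return ReferenceCohort(records=records, schema=schema, provenance=provenance)


# -- profile --------------------------------------------------------------

def write_profile(profile: IndividualProfile, path) -> None:
    d = {"age": profile.age, "horizon": profile.horizon, "values": {}}
    for k, v in profile.values.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            d["values"][k] = None
        elif isinstance(v, (np.floating, np.integer)):
            d["values"][k] = v.item()
        else:
            d["values"][k] = v
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def read_profile(path, schema: RiskFactorSchema | None = None) -> IndividualProfile:
    """Read a profile from JSON (or single-row CSV; empty fields = missing)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        row = pd.read_csv(path).iloc[0]
        values = {}
        age = int(row.pop("age"))
        horizon = int(row.pop("horizon")) if "horizon" in row else 10
        for k, v in row.items():
            values[k] = None if pd.isna(v) else v
        prof = IndividualProfile(age=age, horizon=horizon, values=values)
    else:
        d = json.loads(path.read_text())
        prof = IndividualProfile(
            age=d["age"], horizon=d.get("horizon", 10), values=dict(d["values"])
        )
    if schema is not None:
        # coerce level labels / numerics to the declared domains
        vals = {}
        for v in schema:
            raw = prof.values.get(v.name)
            if raw is None:
                vals[v.name] = None
            elif v.is_categorical or (v.kind == "binary" and v.levels):
                vals[v.name] = str(raw)
            else:
                vals[v.name] = float(raw)
        prof = IndividualProfile(age=prof.age, horizon=prof.horizon, values=vals)
        prof.validate(schema)
    return prof


# -- fitted model set -----------------------------------------------------

def _model_to_dict(model) -> dict:
    if isinstance(model, _m.LinearConditionalModel):
        return {
            "family": "linear",
            "beta": model.beta.tolist(),
            "xtx_inv_chol": model.xtx_inv_chol.tolist(),
            "sigma2": model.sigma2,
            "df": model.df,
            "transform": model.transform,
        }
    if isinstance(model, _m.LogisticConditionalModel):
        return {
            "family": "logistic",
            "beta": model.beta.tolist(),
            "cov_chol": model.cov_chol.tolist(),
            "ridged": model.ridged,
        }
    if isinstance(model, _m.MultinomialConditionalModel):
        return {
            "family": "multinomial",
            "theta": model.theta.tolist(),
            "cov_chol": model.cov_chol.tolist(),
            "n_classes": model.n_classes,
            "ridged": model.ridged,
        }
    if isinstance(model, _m.TwoPartConditionalModel):
        return {
            "family": "two-part",
            "zero_part": _model_to_dict(model.zero_part),
            "positive_part": _model_to_dict(model.positive_part),
        }
    raise TypeError(f"unknown model type {type(model)!r}")


def _model_from_dict(d: dict):
    fam = d["family"]
    if fam == "linear":
        return _m.LinearConditionalModel(
            beta=np.asarray(d["beta"]),
            xtx_inv_chol=np.asarray(d["xtx_inv_chol"]),
            sigma2=float(d["sigma2"]),
            df=int(d["df"]),
            transform=d["transform"],
        )
    if fam == "logistic":
        return _m.LogisticConditionalModel(
            beta=np.asarray(d["beta"]),
            cov_chol=np.asarray(d["cov_chol"]),
            ridged=bool(d["ridged"]),
        )
    if fam == "multinomial":
        return _m.MultinomialConditionalModel(
            theta=np.asarray(d["theta"]),
            cov_chol=np.asarray(d["cov_chol"]),
            n_classes=int(d["n_classes"]),
            ridged=bool(d["ridged"]),
        )
    if fam == "two-part":
        return _m.TwoPartConditionalModel(
            zero_part=_model_from_dict(d["zero_part"]),
            positive_part=_model_from_dict(d["positive_part"]),
        )
    raise ValueError(f"unknown model family {fam!r}")


def write_model_set(models: ImputationModelSet, path) -> None:
    d = {
        "schema": schema_to_dict(models.schema),
        "models": {k: _model_to_dict(m) for k, m in models.models.items()},
        "visit_order": models.visit_order,
        "marginal_pools": {k: np.asarray(v).tolist() for k, v in models.marginal_pools.items()},
        "provenance": models.provenance,
    }
    Path(path).write_text(json.dumps(d, sort_keys=True))


def read_model_set(path) -> ImputationModelSet:
    d = json.loads(Path(path).read_text())
    return ImputationModelSet(
        schema=schema_from_dict(d["schema"]),
        models={k: _model_from_dict(m) for k, m in d["models"].items()},
        visit_order=list(d["visit_order"]),
        marginal_pools={k: np.asarray(v, dtype=float) for k, v in d["marginal_pools"].items()},
        provenance=d.get("provenance", {}),
    )


# -- results --------------------------------------------------------------

def write_distribution(dist: RiskDistribution, out_dir, stem="risk_distribution") -> dict:
    """Samples CSV + summary JSON; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples_path = out_dir / f"{stem}_samples.csv"
    pd.DataFrame({"risk": dist.samples}).to_csv(samples_path, index=False)
    summary = dist.summary()
    if dist.convergence is not None:
        summary["rhat"] = dist.convergence.rhat
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"samples": str(samples_path), "summary": str(summary_path)}


def write_flow(flow: ReclassificationFlow, out_dir, stem="reclassification") -> dict:
    """Tidy transition CSV (Sankey-ready) + JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tidy_path = out_dir / f"{stem}_flow.csv"
    pd.DataFrame(flow.to_tidy_rows()).to_csv(tidy_path, index=False)
    summary = {
        "stage_labels": flow.stage_labels,
        "categories": list(flow.categories),
        "membership": flow.membership.tolist(),
        "group_order": flow.group_order,
        "skipped_groups": flow.skipped_groups,
        "M": flow.M,
        "seed": flow.seed,
    }
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"flow": str(tidy_path), "summary": str(summary_path)}
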