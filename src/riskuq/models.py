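"""Conditional regression models used inside chained-equations imputation.

One model family per variable kind:

* continuous / continuous-positive — linear regression on the declared
  transform scale (log for positive variables), Gaussian residuals;
* semicontinuous-zero-inflated — a two-part model: logistic for the
  probability of a positive value plus linear regression on the log of the
  positive part;
* binary — logistic regression;
* categorical / ordinal-count — multinomial logistic regression (reference
  coded; 2-level ordinals reduce to logistic).

"Proper" imputation draws model parameters from their asymptotic sampling
distribution before drawing each missing value, so parameter uncertainty
propagates into the imputations (residual variance is drawn from its
scaled inverse-chi-square distribution for linear models).

Fits go through statsmodels; when a logistic or multinomial fit fails to
converge or shows (quasi-)separation, a small ridge penalty is applied via
a hand-rolled Newton solver whose penalized Hessian provides the parameter
covariance — rare pathogenic-variant categories make separation likely at
realistic cohort sizes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .schema import RiskFactorSchema, VariableSpec

__all__ = [
    "encode_frame",
    "decode_codes",
    "predictor_matrix",
    "n_predictors",
    "fit_variable_model",
    "LinearConditionalModel",
    "LogisticConditionalModel",
    "MultinomialConditionalModel",
    "TwoPartConditionalModel",
    "SeparationError",
]

_MAX_COEF = 20.0  # |coef| beyond this on a standardized-ish scale flags separation
_RIDGE_ALPHA = 0.5


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic/multinomial fit."""


# ---------------------------------------------------------------------------
# numeric encoding of mixed-type covariate tables
# ---------------------------------------------------------------------------

def encode_frame(frame: pd.DataFrame, schema: RiskFactorSchema) -> dict:
    """Encode a covariate table as {name: float array}; NaN marks missing.

    Categorical/ordinal values become integer level codes; binary becomes
    0/1; continuous values stay on the natural scale.
    """
    out = {}
    for v in schema:
        col = frame[v.name]
        if v.is_categorical or (v.kind == "binary" and v.levels):
            codes = col.map({lvl: i for i, lvl in enumerate(v.levels)})
            out[v.name] = codes.to_numpy(dtype=float, copy=True)
        else:
            # copy=True: imputation writes into these arrays and must never
            # mutate the caller's DataFrame through a view
            out[v.name] = col.to_numpy(dtype=float, copy=True)
    return out


def decode_codes(codes: dict, schema: RiskFactorSchema) -> pd.DataFrame:
    """Inverse of :func:`encode_frame` (level codes back to labels)."""
    out = {}
    for v in schema:
        arr = codes[v.name]
        if v.is_categorical or (v.kind == "binary" and v.levels):
            levels = np.asarray(v.levels, dtype=object)
            vals = np.empty(len(arr), dtype=object)
            ok = ~np.isnan(arr)
            vals[ok] = levels[arr[ok].astype(int)]
            vals[~ok] = np.nan
            out[v.name] = vals
        elif v.kind == "binary":
            out[v.name] = arr.astype(float)
        else:
            out[v.name] = arr.astype(float)
    return pd.DataFrame(out, columns=schema.names)


def _predictor_columns(spec: VariableSpec):
    """Column labels a predictor variable contributes to a design matrix."""
    if spec.is_categorical:
        return [f"{spec.name}[{lvl}]" for lvl in spec.levels[1:]]
    if spec.kind == "semicontinuous-zero-inflated":
        return [f"{spec.name}>0", f"log({spec.name})"]
    if spec.transform == "log":
        return [f"log({spec.name})"]
    return [spec.name]


def n_predictors(schema: RiskFactorSchema, target: str) -> int:
    """Number of design columns (incl. intercept) for a target's model."""
    return 1 + sum(
        len(_predictor_columns(v)) for v in schema if v.name != target
    )


def predictor_matrix(
    codes: dict, schema: RiskFactorSchema, target: str, rows: np.ndarray | None = None
) -> np.ndarray:
    """Design matrix (with intercept) for *target* from encoded covariates.

    Every other schema variable is a predictor: continuous on its transform
    scale, semicontinuous as (positive indicator, log of positive part),
    categorical as reference-coded indicators.
    """
    first = next(iter(codes.values()))
    n = len(first) if rows is None else len(rows)
    cols = [np.ones(n)]
    for v in schema:
        if v.name == target:
            continue
        x = codes[v.name] if rows is None else codes[v.name][rows]
        if v.is_categorical:
            xi = x.astype(int)
            for k in range(1, len(v.levels)):
                cols.append((xi == k).astype(float))
        elif v.kind == "semicontinuous-zero-inflated":
            pos = x > 0
            logx = np.zeros_like(x)
            logx[pos] = np.log(x[pos])
            cols.append(pos.astype(float))
            cols.append(logx)
        elif v.transform == "log":
            cols.append(np.log(x))
        else:
            cols.append(x.astype(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# penalized Newton solvers (separation fallback)
# ---------------------------------------------------------------------------

def _ridge_logistic(X, y, alpha, max_iter=100, tol=1e-8):
    """Ridge-penalized logistic MLE; returns (beta, covariance)."""
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 1e-6  # intercept essentially unpenalized
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))

    def _hess(beta):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen + 1e-8
        return H, mu

    for _ in range(max_iter):
        H, mu = _hess(beta)
        grad = X.T @ (y - mu) - pen * beta
        step = np.linalg.solve(H, grad)
        norm = np.max(np.abs(step))
        if norm > 2.0:
            step *= 2.0 / norm
        beta = beta + step
        if norm < tol:
            break
    H, _ = _hess(beta)
    return beta, np.linalg.inv(H)


def _ridge_multinomial(X, y_codes, n_classes, alpha, max_iter=200, tol=1e-8):
    """Ridge-penalized multinomial logistic MLE.

    Parameters are flattened equation-by-equation (class 1..K-1 vs the
    reference class 0), matching statsmodels' covariance ordering. Returns
    (theta, covariance).
    """
    n, p = X.shape
    K = n_classes
    q = (K - 1) * p
    # intercepts get a whisper of penalty for numerical stability only
    pen = np.tile(np.r_[1e-6, np.full(p - 1, alpha)], K - 1)
    theta = np.zeros(q)
    counts = np.bincount(y_codes.astype(int), minlength=K).astype(float)
    theta[::p] = np.log(counts[1:] / counts[0])  # warm-start intercepts
    Y = np.zeros((n, K - 1))
    for k in range(1, K):
        Y[:, k - 1] = y_codes == k

    def _hess_grad(theta):
        B = theta.reshape(K - 1, p)
        eta = X @ B.T  # (n, K-1)
        eta = np.column_stack([np.zeros(n), eta])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        Pk = P[:, 1:]  # (n, K-1)
        grad = (X.T @ (Y - Pk)).T.reshape(-1) - pen * theta
        H = np.zeros((q, q))
        for a in range(K - 1):
            for b in range(a, K - 1):
                w = Pk[:, a] * ((a == b) - Pk[:, b])
                block = (X * w[:, None]).T @ X
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
                if a != b:
                    H[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
        H[np.diag_indices_from(H)] += pen + 1e-8
        return H, grad

    for _ in range(max_iter):
        H, grad = _hess_grad(theta)
        step = np.linalg.solve(H, grad)
        norm = np.max(np.abs(step))
        if norm > 2.0:  # damp: rare classes make full Newton overshoot
            step *= 2.0 / norm
        theta = theta + step
        if norm < tol:
            break
    H, _ = _hess_grad(theta)
    return theta, np.linalg.inv(H)


def _chol_psd(cov):
    """Cholesky factor, nudging tiny negative eigenvalues if needed."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 1e-12, None)
        return V @ np.diag(np.sqrt(w))


def _draw_betas(beta, chol, M, rng):
    """M draws from N(beta, chol @ chol.T); shape (M, len(beta))."""
    z = rng.standard_normal((M, len(beta)))
    return beta[None, :] + z @ chol.T


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------

@dataclass
class LinearConditionalModel:
    """Gaussian linear model on the target's transform scale."""

    beta: np.ndarray
    xtx_inv_chol: np.ndarray  # chol of (X'X)^{-1}
    sigma2: float
    df: int
    transform: str = "identity"
    family = "linear"

    @classmethod
    def fit(cls, X, y, transform="identity"):
        t = np.log(y) if transform == "log" else y
        res = sm.OLS(t, X).fit()
        df = int(res.df_resid)
        if df <= 0:
            raise ValueError("not enough residual degrees of freedom")
        sigma2 = float(res.ssr / df)
        # pinv: rank-deficient designs (e.g. an all-zero rare-category dummy
        # among the training rows) get zero variance in the null directions
        xtx_inv = np.linalg.pinv(X.T @ X)
        return cls(
            beta=np.asarray(res.params, dtype=float),
            xtx_inv_chol=_chol_psd(xtx_inv),
            sigma2=sigma2,
            df=df,
            transform=transform,
        )

    def draw(self, X, rng, proper=True, common_params=False):
        M = len(X)
        if proper:
            n_par = 1 if common_params else M
            s2 = self.sigma2 * self.df / rng.chisquare(self.df, size=n_par)
            z = rng.standard_normal((n_par, len(self.beta)))
            betas = self.beta[None, :] + np.sqrt(s2)[:, None] * (z @ self.xtx_inv_chol.T)
            if common_params:
                betas = np.broadcast_to(betas, (M, len(self.beta)))
                s2 = np.broadcast_to(s2, (M,))
        else:
            betas = np.broadcast_to(self.beta[None, :], (M, len(self.beta)))
            s2 = np.full(M, self.sigma2)
        mu = np.einsum("ij,ij->i", X, betas)
        t = mu + np.sqrt(s2) * rng.standard_normal(M)
        return np.exp(t) if self.transform == "log" else t

    def conditional_mean(self, X):
        mu = X @ self.beta
        if self.transform == "log":
            return np.exp(mu + 0.5 * self.sigma2)
        return mu


@dataclass
class LogisticConditionalModel:
    beta: np.ndarray
    cov_chol: np.ndarray
    ridged: bool = False
    family = "logistic"

    @classmethod
    def fit(cls, X, y, ridge_alpha=_RIDGE_ALPHA):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
            ok = (
                res.mle_retvals.get("converged", False)
                and np.all(np.isfinite(beta))
                and np.all(np.isfinite(cov))
                and np.max(np.abs(beta)) < _MAX_COEF
            )
        except Exception:
            ok = False
        if not ok:
            if ridge_alpha is None:
                raise SeparationError(
                    "logistic fit failed to converge (likely separation); "
                    "set a ridge penalty (ridge_alpha) to regularize"
                )
            beta, cov = _ridge_logistic(X, y, ridge_alpha)
            return cls(beta=beta, cov_chol=_chol_psd(cov), ridged=True)
        return cls(beta=beta, cov_chol=_chol_psd(cov), ridged=False)

    def draw(self, X, rng, proper=True, common_params=False):
        M = len(X)
        if proper:
            if common_params:
                betas = np.broadcast_to(_draw_betas(self.beta, self.cov_chol, 1, rng), (M, len(self.beta)))
            else:
                betas = _draw_betas(self.beta, self.cov_chol, M, rng)
            eta = np.einsum("ij,ij->i", X, betas)
        else:
            eta = X @ self.beta
        return (rng.random(M) < expit(eta)).astype(float)

    def probabilities(self, X):
        return expit(X @ self.beta)


@dataclass
class MultinomialConditionalModel:
    """Reference-coded multinomial logistic model (K >= 2 classes).

    ``theta`` is flattened equation-by-equation: coefficients of class k vs
    the reference class, for k = 1..K-1.
    """

    theta: np.ndarray
    cov_chol: np.ndarray
    n_classes: int
    ridged: bool = False
    family = "multinomial"

    @classmethod
    def fit(cls, X, y_codes, n_classes, ridge_alpha=_RIDGE_ALPHA):
        K = int(n_classes)
        present = np.unique(y_codes.astype(int))
        if len(present) < K:
            # caller should have checked; be safe
            raise ValueError("not all levels present in training data")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MNLogit(y_codes.astype(int), X).fit(disp=0, maxiter=200)
            theta = np.asarray(res.params, dtype=float).ravel(order="F")
            cov = np.asarray(res.cov_params(), dtype=float)
            ok = (
                res.mle_retvals.get("converged", False)
                and np.all(np.isfinite(theta))
                and np.all(np.isfinite(cov))
                and np.max(np.abs(theta)) < _MAX_COEF
            )
        except Exception:
            ok = False
        if not ok:
            if ridge_alpha is None:
                raise SeparationError(
                    "multinomial fit failed to converge (likely separation); "
                    "set a ridge penalty (ridge_alpha) to regularize"
                )
            theta, cov = _ridge_multinomial(X, y_codes, K, ridge_alpha)
            return cls(theta=theta, cov_chol=_chol_psd(cov), n_classes=K, ridged=True)
        return cls(theta=theta, cov_chol=_chol_psd(cov), n_classes=K, ridged=False)

    def _probs(self, X, thetas=None):
        n, p = X.shape
        K = self.n_classes
        if thetas is None:
            B = self.theta.reshape(K - 1, p)
            eta = X @ B.T
        else:
            B = thetas.reshape(n, K - 1, p)
            eta = np.einsum("ij,ikj->ik", X, B)
        eta = np.column_stack([np.zeros(n), eta])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def draw(self, X, rng, proper=True, common_params=False, chunk=200_000):
        M = len(X)
        out = np.empty(M)
        for lo in range(0, M, chunk):
            hi = min(lo + chunk, M)
            Xc = X[lo:hi]
            if proper:
                if common_params:
                    th = _draw_betas(self.theta, self.cov_chol, 1, rng)
                    th = np.broadcast_to(th, (hi - lo, len(self.theta)))
                else:
                    th = _draw_betas(self.theta, self.cov_chol, hi - lo, rng)
                P = self._probs(Xc, th)
            else:
                P = self._probs(Xc)
            cum = np.cumsum(P, axis=1)
            u = rng.random(hi - lo)
            out[lo:hi] = (u[:, None] > cum).sum(axis=1)
        return out

    def probabilities(self, X):
        return self._probs(X)


@dataclass
class TwoPartConditionalModel:
    """Zero-inflated semicontinuous model: logistic zero-part + log-linear."""

    zero_part: LogisticConditionalModel  # models P(value > 0)
    positive_part: LinearConditionalModel  # log of positive values
    family = "two-part"

    @classmethod
    def fit(cls, X, y, ridge_alpha=_RIDGE_ALPHA):
        pos = y > 0
        if pos.sum() < X.shape[1] + 2:
            raise ValueError("too few positive observations for the two-part model")
        zero_part = LogisticConditionalModel.fit(X, pos.astype(float), ridge_alpha)
        positive_part = LinearConditionalModel.fit(X[pos], y[pos], transform="log")
        return cls(zero_part=zero_part, positive_part=positive_part)

    def draw(self, X, rng, proper=True, common_params=False):
        pos = self.zero_part.draw(X, rng, proper, common_params).astype(bool)
        out = np.zeros(len(X))
        if pos.any():
            out[pos] = self.positive_part.draw(X[pos], rng, proper, common_params)
        return out


def fit_variable_model(
    spec: VariableSpec, X, y, ridge_alpha=_RIDGE_ALPHA
):
    """Fit the appropriate conditional model family for one variable."""
    if spec.kind in ("continuous", "continuous-positive"):
        return LinearConditionalModel.fit(X, y, transform=spec.transform)
    if spec.kind == "semicontinuous-zero-inflated":
        return TwoPartConditionalModel.fit(X, y, ridge_alpha)
    if spec.kind == "binary":
        return LogisticConditionalModel.fit(X, y, ridge_alpha)
    if spec.is_categorical:
        K = len(spec.levels)
        if K == 2:
            return LogisticConditionalModel.fit(X, y, ridge_alpha)
        return MultinomialConditionalModel.fit(X, y, K, ridge_alpha)
    raise ValueError(f"no model family for kind {spec.kind!r}")
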