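"""Firth bias-reduced binary logistic regression.

Ordinary maximum-likelihood logistic regression fails under complete or
quasi-complete separation: some coefficient diverges and presence/absence
data with few events (individual tool types across a few dozen assemblages)
hit this constantly. Firth's remedy penalizes the likelihood with the
Jeffreys prior, maximizing

    l*(beta) = l(beta) + 0.5 * log det I(beta),

where I is the Fisher information X' W X. The penalty shrinks estimates
toward zero, guarantees finite coefficients under separation, and reduces
the O(1/n) small-sample bias of the MLE. Estimation is by Newton iteration
on the modified score

    U*_j = sum_i (y_i - p_i + h_i (0.5 - p_i)) x_ij,

with h the leverages of the weighted hat matrix, plus step-halving on the
penalized log-likelihood. Inference is Wald, from the inverse Fisher
information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DesignError, InvalidConfigError


@dataclass
class FirthFit:
    """Penalized-likelihood logistic fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik_penalized: float
    converged: bool
    iterations: int

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.coef / self.se, np.inf)

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.wald_z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coef,
                "se": self.se,
                "z": self.wald_z,
                "p": self.wald_p,
            }
        )


def _penalized_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically safe log-likelihood
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(
    y,
    X,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FirthFit:
    """Fit a Firth-penalized logistic regression.

    ``X`` must include its intercept column and be of full column rank;
    ``tol`` is on the max-norm of the modified score. Non-convergence within
    ``max_iter`` returns the last iterate flagged ``converged=False``.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DesignError("X must be 2-D with one row per observation")
    n, k = X.shape
    if n <= k:
        raise DesignError("need more observations than parameters")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidConfigError("responses must be binary 0/1")
    if np.linalg.matrix_rank(X) < k:
        raise DesignError("design matrix is rank deficient")
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, k)]

    beta = np.zeros(k)
    ll = _penalized_loglik(y, X, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        Xw = X * w[:, None]
        info = X.T @ Xw
        info_inv = np.linalg.inv(info)
        # leverages of the weighted hat matrix
        sw = np.sqrt(w)
        Xs = X * sw[:, None]
        h = np.einsum("ij,jk,ik->i", Xs, info_inv, Xs)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) <= tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving: accept only non-decreasing penalized likelihood
        lam = 1.0
        for _ in range(25):
            ll_new = _penalized_loglik(y, X, beta + lam * step)
            if ll_new >= ll - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
        ll = _penalized_loglik(y, X, beta)

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return FirthFit(
        names=list(names),
        coef=beta,
        se=se,
        loglik_penalized=ll,
        converged=converged,
        iterations=it,
    )


def tool_response_models(
    table: pd.DataFrame,
    predictors: list[str],
    tools: list[str] | None = None,
    exclusions: list[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """One Firth logistic fit per tool type: presence ~ predictors.

    Continuous predictors are standardized (sample sd); binary 0/1 columns
    enter as-is. ``exclusions`` removes predictors by name (e.g. variables
    only available as distance matrices). Tool columns that are constant
    (all present or all absent) are skipped with a logged reason. Returns a
    tidy frame: tool, term, coef, se, z, p, converged, skipped/reason.
    """
    if tools is None:
        tools = [c for c in table.columns if c.startswith("tool_")]
    if not tools:
        raise InvalidConfigError("no tool columns to model")
    predictors = [p for p in predictors if p not in set(exclusions or [])]
    if not predictors:
        raise InvalidConfigError("empty predictor set")

    X_cols = []
    for pcol in predictors:
        v = table[pcol].to_numpy(float)
        is_binary = np.isin(v, (0.0, 1.0)).all()
        if standardize and not is_binary:
            s = v.std(ddof=1)
            if s == 0:
                raise DesignError(f"predictor {pcol!r} is constant")
            v = (v - v.mean()) / s
        X_cols.append(v)
    X = np.column_stack([np.ones(len(table))] + X_cols)
    names = ["intercept"] + list(predictors)

    rows = []
    for tool in tools:
        y = table[tool].to_numpy(float)
        if y.min() == y.max():
            rows.append(
                {
                    "tool": tool,
                    "term": None,
                    "coef": np.nan,
                    "se": np.nan,
                    "z": np.nan,
                    "p": np.nan,
                    "converged": False,
                    "skipped": True,
                    "reason": "constant response",
                }
            )
            continue
        fit = firth_fit(y, X, names=names)
        for term, c, s, z, p in zip(fit.names, fit.coef, fit.se, fit.wald_z, fit.wald_p):
            rows.append(
                {
                    "tool": tool,
                    "term": term,
                    "coef": float(c),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                    "converged": fit.converged,
                    "skipped": False,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)


def effect_sign_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per tool x predictor: direction of significant effects (+/-/0)."""
    df = results[(~results["skipped"]) & (results["term"] != "intercept")].copy()
    df["effect"] = np.where(
        df["p"] <= alpha, np.where(df["coef"] > 0, "+", "-"), "0"
    )
    return df.pivot_table(
        index="tool", columns="term", values="effect", aggfunc="first"
    )
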