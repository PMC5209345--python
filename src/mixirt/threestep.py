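"""Bias-adjusted three-step regression of latent class membership.

Step 1 fits the measurement model, step 2 assigns persons to their modal
class, step 3 regresses class membership on covariates.  Treating modal
labels as known attenuates covariate effects, so step 3 maximizes the
ML-corrected likelihood in which the observed label enters through the
classification-error matrix D (Vermunt's adjusted three-step approach):

    L_v = sum_t P(true = t | x_v; B) * D[label_v, t]

with ``D[s, t] = P(assigned s | true t)`` estimated from the step-1
posteriors.  When classification is perfect (D = identity) the corrected
estimator coincides with an ordinary multinomial logit on the labels.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, DataError

__all__ = [
    "classification_error_matrix",
    "dummy_encode",
    "three_step_multinomial",
    "ThreeStepResult",
]


def classification_error_matrix(posterior: np.ndarray, modal_labels: np.ndarray):
    """D[s, t] = P(assigned class s | true class t), columns summing to 1.

    Estimated from the fitted posteriors: the expected number of true-t
    persons carried into assigned class s, normalized per true class.
    """
    posterior = np.asarray(posterior, dtype=float)
    modal_labels = np.asarray(modal_labels, dtype=int)
    n, G = posterior.shape
    if np.any(np.abs(posterior.sum(axis=1) - 1.0) > 1e-8):
        raise DataError("posterior rows must sum to 1")
    D = np.zeros((G, G))
    for s in range(G):
        D[s] = posterior[modal_labels == s].sum(axis=0)
    col = D.sum(axis=0)
    if np.any(col <= 0):
        bad = int(np.flatnonzero(col <= 0)[0])
        raise DataError(f"true class {bad} has no posterior support")
    return D / col


def dummy_encode(table: pd.DataFrame, references: dict | None = None):
    """Design matrix with an intercept, k-1 dummies per categorical column.

    ``references`` maps column name -> reference level; unmentioned
    categorical columns use their first declared category.  Numeric columns
    pass through unchanged.  Returns ``(design DataFrame, column metadata)``
    where the metadata allows decoding levels back.
    """
    references = references or {}
    if table.isna().any().any():
        raise DataError(
            "missing covariate values are not accepted; impute or drop "
            "before the regression stage"
        )
    cols = {"intercept": np.ones(len(table))}
    meta = {}
    for name in table.columns:
        col = table[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            col = col.astype("category")
            levels = list(col.cat.categories)
            ref = references.get(name, levels[0])
            if ref not in levels:
                raise DataError(f"reference level '{ref}' not a level of '{name}'")
            others = [l for l in levels if l != ref]
            for lev in others:
                cols[f"{name}[{lev}]"] = (col == lev).astype(float).to_numpy()
            meta[name] = {"kind": "categorical", "reference": ref, "levels": levels}
        else:
            cols[name] = col.astype(float).to_numpy()
            meta[name] = {"kind": "numeric"}
    return pd.DataFrame(cols, index=table.index), meta


@dataclass
class ThreeStepResult:
    """Corrected multinomial-logit estimates in odds-ratio form."""

    coefficients: pd.DataFrame  # per contrast: B, SE, OR, CI bounds
    misclassification: np.ndarray
    log_likelihood: float
    pseudo_r2: float  # McFadden, in percent
    reference_class: int
    raw_B: np.ndarray  # (p, G-1) coefficients, classes 2..G vs class 1
    covariance: np.ndarray

    def contrast(self, class_a: int, class_b: int) -> np.ndarray:
        """Coefficient vector for class_a vs class_b (1-based labels)."""
        full = np.concatenate(
            [np.zeros((self.raw_B.shape[0], 1)), self.raw_B], axis=1
        )
        return full[:, class_a - 1] - full[:, class_b - 1]


def _negll_grad(B_flat, X, label_D, G):
    """Corrected-likelihood objective: -sum log sum_t p_t(x) D[label, t]."""
    n, p = X.shape
    B = B_flat.reshape(p, G - 1)
    eta = np.concatenate([np.zeros((n, 1)), X @ B], axis=1)
    log_p = eta - logsumexp(eta, axis=1, keepdims=True)
    P = np.exp(log_p)
    L = np.sum(P * label_D, axis=1)
    L = np.maximum(L, 1e-300)
    # dlogL/deta_t = w_t - p_t with w_t = p_t D[label, t] / L
    W = P * label_D / L[:, None]
    G_eta = W - P
    grad = X.T @ G_eta[:, 1:]
    return -float(np.sum(np.log(L))), -grad.ravel()


def three_step_multinomial(
    modal_labels: np.ndarray,
    D: np.ndarray,
    design: pd.DataFrame,
    reference_class: int = 1,
    max_iter: int = 2000,
) -> ThreeStepResult:
    """ML-corrected multinomial logit of true class on covariates.

    ``modal_labels`` are 0-based assigned classes, ``D`` the
    classification-error matrix, ``design`` an intercept-bearing design
    matrix (see :func:`dummy_encode`).  Reports per non-reference class:
    B, SE (inverse observed information), odds ratio ``e^B`` and the 95%
    Wald interval ``exp(B +/- 1.96 SE)``; plus McFadden's pseudo-R^2 on
    the corrected likelihood (in percent).  Any pairwise contrast follows
    from coefficient differences (:meth:`ThreeStepResult.contrast`).
    """
    modal_labels = np.asarray(modal_labels, dtype=int)
    D = np.asarray(D, dtype=float)
    G = D.shape[0]
    if np.linalg.cond(D) > 1e8:
        raise ConfigurationError("classification-error matrix is ill-conditioned")
    if reference_class != 1:
        raise ConfigurationError("class 1 (largest) is the fixed reference here")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    label_D = D[modal_labels]  # (n, G): D[s_v, t] over t

    def solve(X_use, p_use):
        x0 = np.zeros(p_use * (G - 1))
        res = minimize(
            _negll_grad,
            x0,
            args=(X_use, label_D, G),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        if not res.success:
            # accept an iteration-capped stop only if the score has vanished
            _, g = _negll_grad(res.x, X_use, label_D, G)
            if np.max(np.abs(g)) > 1e-4 * max(1, X_use.shape[0]):
                raise ConvergenceError(
                    f"multinomial step did not converge: {res.message}"
                )
        return res

    res = solve(X, p)
    B = res.x.reshape(p, G - 1)
    if np.any(np.abs(B) > 15):
        warnings.warn("very large coefficients; possible separation")

    # null (intercept-only) corrected model for McFadden's pseudo-R^2
    res0 = solve(X[:, :1], 1)
    ll, ll0 = -res.fun, -res0.fun
    pseudo_r2 = 100.0 * (1.0 - ll / ll0) if ll0 != 0 else np.nan

    # observed information by central differences of the analytic gradient
    k = B.size
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(res.x[j]))
        vp, vm = res.x.copy(), res.x.copy()
        vp[j] += h
        vm[j] -= h
        _, gp = _negll_grad(vp, X, label_D, G)
        _, gm = _negll_grad(vm, X, label_D, G)
        H[j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(p, G - 1)

    rows = []
    for g in range(1, G):
        for j, name in enumerate(design.columns):
            b, s = B[j, g - 1], se[j, g - 1]
            rows.append(
                {
                    "contrast": f"class_{g + 1}_vs_class_1",
                    "term": name,
                    "B": b,
                    "SE": s,
                    "OR": np.exp(b),
                    "CI_low": np.exp(b - 1.96 * s),
                    "CI_high": np.exp(b + 1.96 * s),
                    "z": b / s if s > 0 else np.nan,
                }
            )
    return ThreeStepResult(
        coefficients=pd.DataFrame(rows),
        misclassification=D,
        log_likelihood=float(ll),
        pseudo_r2=float(pseudo_r2),
        reference_class=1,
        raw_B=B,
        covariance=cov,
    )
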