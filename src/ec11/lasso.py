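"""L1-penalised regression for the variable-importance stage.

Implements the glmnet-style estimator the selection procedure relies on:
predictors standardised to unit standard deviation, a log-spaced penalty
path of 100 values down to ``1e-4 * lambda_max``, coordinate descent
(gaussian) or IRLS + weighted coordinate descent (binomial), and penalty
selection by 10-fold cross-validation with the one-standard-error rule
(the most regularised model whose CV error is within one SE of the
minimum).  Inner loops are numba-compiled.

The absolute standardised coefficients are the raw variable importances of
the selection stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["LassoFit", "lambda_grid", "lasso_path", "cv_lasso_1se"]

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4


@njit(cache=False, fastmath=True)
def _soft(z, lam):
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


@njit(cache=False, fastmath=True)
def _cd_active(XT, r, beta, lam, n, active, tol, max_sweeps):
    """Coordinate descent restricted to the active set (unit weights).

    XT is the transposed design (features x samples, row-contiguous);
    feature rows have unit (1/n) variance, so the update denominator is 1.
    Features are never removed from the active set once entered
    (ever-active convention); a zero coefficient simply stays zero.
    """
    p = XT.shape[0]
    for _ in range(max_sweeps):
        max_change = 0.0
        for j in range(p):
            if not active[j]:
                continue
            zj = 0.0
            for i in range(n):
                zj += XT[j, i] * r[i]
            zj = zj / n + beta[j]
            new = _soft(zj, lam)
            d = new - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * XT[j, i]
                beta[j] = new
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        if max_change < tol:
            break
    for j in range(p):  # working set shrinks to the support; KKT re-admits
        active[j] = beta[j] != 0.0


@njit(cache=False, fastmath=True)
def _cd_gaussian_path(XT, y, lambdas, tol, max_sweeps, dfmax):
    """Coordinate-descent path for 0.5/n ||y - Xb||^2 + lam ||b||_1.

    X columns must be centred and scaled to unit (1/n) variance, y centred.
    Warm starts along the decreasing penalty path; per penalty the active
    set is optimised by coordinate descent and inactive features are
    admitted through KKT scans of the gradient until none violate
    |x_j' r| / n <= lam.
    """
    p, n = XT.shape
    out = np.zeros((lambdas.shape[0], p))
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    r = y.copy()
    null_rss = y @ y
    prev_rss = null_rss
    saturated_from = -1
    for li in range(lambdas.shape[0]):
        lam = lambdas[li]
        for _ in range(100):  # KKT admission rounds
            _cd_active(XT, r, beta, lam, n, active, tol, max_sweeps)
            admitted = False
            for j in range(p):
                if active[j]:
                    continue
                zj = 0.0
                for i in range(n):
                    zj += XT[j, i] * r[i]
                if abs(zj) / n > lam * (1.0 + 1e-6) + 1e-12:
                    active[j] = True
                    admitted = True
            if not admitted:
                break
        out[li] = beta
        # glmnet-style path termination: explained variance saturated, no
        # further improvement, or support larger than dfmax
        nz = 0
        for j in range(p):
            if beta[j] != 0.0:
                nz += 1
        rss = r @ r
        if (
            rss < 0.001 * null_rss
            or nz > dfmax
            or (li >= 20 and (prev_rss - rss) < 1e-4 * null_rss)
        ):
            saturated_from = li
            break
        prev_rss = rss
    if saturated_from >= 0:
        for li in range(saturated_from + 1, lambdas.shape[0]):
            out[li] = out[saturated_from]
    return out


@njit(cache=False, fastmath=True)
def _wcd_active(XT, w, r, beta, b0, wsum, lam, n, active, tol, max_sweeps):
    """Weighted coordinate descent on the active set + unpenalised
    intercept; returns the updated intercept.  Weighted squared feature
    norms are cached (the weights are fixed within one IRLS step)."""
    p = XT.shape[0]
    vjn = np.full(p, -1.0)  # lazily cached sum_i w_i x_ij^2 / n
    for _ in range(max_sweeps):
        max_change = 0.0
        for j in range(p):
            if not active[j]:
                continue
            if vjn[j] < 0.0:
                vj = 0.0
                for i in range(n):
                    vj += w[i] * XT[j, i] * XT[j, i]
                vjn[j] = vj / n
            if vjn[j] <= 0.0:
                continue
            num = 0.0
            for i in range(n):
                num += w[i] * XT[j, i] * r[i]
            num = num / n + vjn[j] * beta[j]
            new = _soft(num, lam) / vjn[j]
            d = new - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * XT[j, i]
                beta[j] = new
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        di = 0.0
        for i in range(n):
            di += w[i] * r[i]
        di /= wsum
        if di != 0.0:
            b0 += di
            for i in range(n):
                r[i] -= di
            if abs(di) > max_change:
                max_change = abs(di)
        if max_change < tol:
            break
    return b0


@njit(cache=False, fastmath=True)
def _cd_binomial_path(XT, y, lambdas, tol, max_sweeps, max_irls, dfmax):
    """IRLS + weighted coordinate-descent path for penalised logistic loss
    (1/n) sum log(1 + exp(-(2y-1) eta)) + lam ||b||_1, intercept unpenalised.

    X columns centred/scaled as for the gaussian path; y in {0, 1}.  Per
    penalty, IRLS with coordinate descent runs on the active set only;
    inactive features are admitted through KKT scans of the score
    |x_j'(y - p)| / n at the converged fit (ever-active convention along
    the warm-started path).  The convergence tolerance scales with the
    largest coefficient magnitude, since coefficients legitimately blow up
    under separation at tiny penalties.  The path stops early once the
    deviance is essentially saturated or no longer improves (glmnet-style);
    remaining penalties reuse the last solution.  Returns
    (coefs, intercepts).
    """
    p, n = XT.shape
    out = np.zeros((lambdas.shape[0], p))
    out0 = np.zeros(lambdas.shape[0])
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("binomial response has a single class")
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    saturated_from = -1
    null_dev = -2.0 * n * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    prev_dev = null_dev
    w = np.empty(n)
    r = np.empty(n)
    prob = np.empty(n)
    for li in range(lambdas.shape[0]):
        lam = lambdas[li]
        for _ in range(100):  # KKT admission rounds
            for _ in range(max_irls):
                bmax = 1.0
                for j in range(p):
                    if abs(beta[j]) > bmax:
                        bmax = abs(beta[j])
                tol_eff = tol * bmax
                # quadratic approximation at current (b0, beta)
                for i in range(n):
                    pi = 1.0 / (1.0 + np.exp(-eta[i]))
                    wi = pi * (1.0 - pi)
                    if wi < 1e-5:
                        wi = 1e-5
                    w[i] = wi
                    r[i] = (y[i] - pi) / wi  # working residual z - eta
                wsum = w.sum()
                b0_old = b0
                snapshot = beta.copy()
                b0 = _wcd_active(XT, w, r, beta, b0, wsum, lam, n, active, tol_eff, max_sweeps)
                # refresh eta from the quadratic solution: eta_new = z - r
                for i in range(n):
                    eta[i] = eta[i] + (y[i] - 1.0 / (1.0 + np.exp(-eta[i]))) / w[i] - r[i]
                step = abs(b0 - b0_old)
                for j in range(p):
                    d = abs(beta[j] - snapshot[j])
                    if d > step:
                        step = d
                if step < tol_eff:
                    break
            # KKT scan: admit inactive features with score above lam
            for i in range(n):
                prob[i] = y[i] - 1.0 / (1.0 + np.exp(-eta[i]))
            admitted = False
            for j in range(p):
                if active[j]:
                    continue
                gj = 0.0
                for i in range(n):
                    gj += XT[j, i] * prob[i]
                if abs(gj) / n > lam * (1.0 + 1e-6) + 1e-12:
                    active[j] = True
                    admitted = True
            if not admitted:
                break
        out[li] = beta
        out0[li] = b0
        # glmnet-style path termination
        dev = 0.0
        for i in range(n):
            pi = 1.0 / (1.0 + np.exp(-eta[i]))
            if pi < 1e-10:
                pi = 1e-10
            elif pi > 1.0 - 1e-10:
                pi = 1.0 - 1e-10
            if y[i] > 0.5:
                dev -= 2.0 * np.log(pi)
            else:
                dev -= 2.0 * np.log(1.0 - pi)
        nz = 0
        for j in range(p):
            if beta[j] != 0.0:
                nz += 1
        if (
            dev < 0.001 * null_dev
            or nz > dfmax
            or (li >= 20 and (prev_dev - dev) < 1e-4 * null_dev)
        ):
            saturated_from = li
            break
        prev_dev = dev
    if saturated_from >= 0:
        for li in range(saturated_from + 1, lambdas.shape[0]):
            out[li] = out[saturated_from]
            out0[li] = out0[saturated_from]
    return out, out0


def _standardise(X, allow_constant: bool = True):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0, glmnet's 1/n convention
    if np.any(sd == 0):
        if not allow_constant:
            raise ValueError("fixed (constant) predictor column in lasso design")
        sd = np.where(sd == 0, 1.0, sd)  # column becomes zeros; coefficient stays 0
    return (X - mean) / sd, mean, sd


def lambda_grid(X, y, family: str) -> np.ndarray:
    """Log-spaced penalty grid: 100 values from lambda_max (the smallest
    penalty with an all-zero solution) down to 1e-4 * lambda_max."""
    Xs, _, _ = _standardise(np.asarray(X, float))
    y = np.asarray(y, float)
    n = len(y)
    resid = y - y.mean()  # gaussian score at null; binomial uses y - ybar
    lam_max = np.max(np.abs(Xs.T @ resid)) / n
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * LAMBDA_MIN_RATIO, N_LAMBDA)


@dataclass
class LassoFit:
    family: str
    lambda_: float
    lambdas: np.ndarray
    coef_std: np.ndarray  # standardised-scale coefficients at lambda_
    intercept: float  # on the standardised scale
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.coef_std != 0))


def lasso_path(X, y, lambdas, family: str = "gaussian", tol: float = 1e-6):
    """Standardised-scale coefficient path.

    Returns ``(coefs, intercepts, mean, sd)``: ``coefs[k]`` solves the
    penalised problem at ``lambdas[k]`` with predictors standardised
    internally to unit SD (coefficients are on that standardised scale, as
    used for variable importance); ``mean``/``sd`` reproduce the
    standardisation for prediction on new data.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    lambdas = np.asarray(lambdas, float)
    Xs, mean, sd = _standardise(X)
    XsT = np.ascontiguousarray(Xs.T)
    n = len(y)
    # glmnet-style dfmax: past this support size the model is far into the
    # overfitting tail; the path is frozen there (CV never selects it)
    dfmax = max(20, min(XsT.shape[0], n // 10))
    if family == "gaussian":
        coefs = _cd_gaussian_path(XsT, y - y.mean(), lambdas, tol, 200, dfmax)
        b0 = np.full(len(lambdas), y.mean())
    elif family == "binomial":
        if len(np.unique(y)) < 2:
            raise ValueError("binomial response has a single class")
        coefs, b0 = _cd_binomial_path(XsT, y, lambdas, tol, 20, 4, dfmax)
    else:
        raise ValueError(f"unknown family {family!r}")
    return coefs, b0, mean, sd


def _fold_errors(X, y, lambdas, family, folds):
    """Held-out prediction error per (fold, lambda)."""
    errs = np.empty((len(folds), len(lambdas)))
    for fi, test_idx in enumerate(folds):
        mask = np.ones(len(y), bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Xte, yte = X[test_idx], y[test_idx]
        coefs, b0, mean, sd = lasso_path(Xtr, ytr, lambdas, family)
        eta = ((Xte - mean) / sd) @ coefs.T + b0
        if family == "gaussian":
            errs[fi] = np.mean((yte[:, None] - eta) ** 2, axis=0)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = yte[:, None] * np.log(p) + (1 - yte[:, None]) * np.log(1 - p)
            errs[fi] = -ll.mean(axis=0)
    return errs


def cv_lasso_1se(
    X,
    y,
    family: str = "gaussian",
    n_folds: int = 10,
    rng=None,
    lambdas=None,
) -> LassoFit:
    """Fit the penalty path and select lambda by the 10-fold 1-SE rule.

    The chosen penalty is the largest lambda whose mean CV error does not
    exceed the minimum mean error plus one standard error (across folds) at
    the minimiser; the final model is refit on all data at that penalty.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if lambdas is None:
        lambdas = lambda_grid(X, y, family)
    lambdas = np.asarray(lambdas, float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 training samples")
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    errs = _fold_errors(X, y, lambdas, family, folds)
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(len(folds))
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    # grid is decreasing, so the first qualifying index is the largest lambda
    i_1se = int(np.nonzero(cv_mean <= threshold)[0][0])
    coefs, b0, _, _ = lasso_path(X, y, lambdas, family)
    return LassoFit(
        family=family,
        lambda_=float(lambdas[i_1se]),
        lambdas=lambdas,
        coef_std=coefs[i_1se],
        intercept=float(b0[i_1se]),
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=float(lambdas[i_min]),
    )
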