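"""Ridge-stabilised GLM fits used by the prediction models.

Plain maximum likelihood (least squares, binomial logistic, multinomial
logistic) with a tiny fixed L2 penalty (default 1e-6) on slope
coefficients, intercepts unpenalised.  The ridge guarantees a finite,
unique optimum when a genotype perfectly separates the classes — which
does happen on synthetic cohorts — while perturbing well-posed fits far
below any reported precision.  Multinomial and logistic fits use full
Newton iterations with convergence declared at gradient norm 1e-8 (cap 200
iterations).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_linear", "fit_multinomial", "softmax_probs", "RIDGE"]

RIDGE = 1e-6
NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 200


def fit_linear(X, y, ridge: float = RIDGE):
    """Least squares with ridge on slopes: returns (intercept, coefs)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    H = A.T @ A
    H[1:, 1:] += ridge * np.eye(p)
    b = np.linalg.solve(H, A.T @ y)
    return float(b[0]), b[1:]


def softmax_probs(eta: np.ndarray) -> np.ndarray:
    """Class probabilities from logits (last, reference class logit = 0)."""
    full = np.column_stack([eta, np.zeros(len(eta))])
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def fit_multinomial(X, y_index, n_classes: int, ridge: float = RIDGE):
    """Multinomial logistic MLE (+ridge on slopes) by Newton's method.

    ``y_index`` holds class indices 0..n_classes-1; the last class is the
    reference.  Returns ``B`` of shape (n_classes - 1, p + 1): per
    non-reference class an (intercept, slopes) row.  With ``n_classes=2``
    this is ordinary binomial logistic regression on class 0 vs class 1.
    """
    X = np.asarray(X, float)
    y_index = np.asarray(y_index, int)
    n, p = X.shape
    K = n_classes
    if len(np.unique(y_index)) < 2:
        raise ValueError("single-category training data")
    A = np.column_stack([np.ones(n), X])  # n x (p+1)
    d = p + 1
    B = np.zeros((K - 1, d))
    Y = np.zeros((n, K - 1))
    for k in range(K - 1):
        Y[:, k] = y_index == k
    pen = np.zeros(d)
    pen[1:] = ridge

    for _ in range(NEWTON_MAX_ITER):
        eta = A @ B.T  # n x (K-1)
        P = softmax_probs(eta)[:, : K - 1]
        G = A.T @ (Y - P) - (pen * B).T  # d x (K-1)
        grad = G.T.ravel()  # (K-1)*d, class-major
        if np.linalg.norm(grad) < NEWTON_TOL:
            break
        # Hessian of the negative log-likelihood, block (k, l):
        # sum_i a_i a_i^T (p_ik delta_kl - p_ik p_il)  (+ ridge on diag)
        H = np.empty(((K - 1) * d, (K - 1) * d))
        for k in range(K - 1):
            for l in range(k, K - 1):
                w = P[:, k] * ((k == l) - P[:, l])
                block = A.T @ (A * w[:, None])
                if k == l:
                    block = block + np.diag(pen)
                H[k * d : (k + 1) * d, l * d : (l + 1) * d] = block
                if l != k:
                    H[l * d : (l + 1) * d, k * d : (k + 1) * d] = block
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        B = B + step.reshape(K - 1, d)
    else:
        raise RuntimeError("multinomial Newton did not converge in 200 iterations")
    return B
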