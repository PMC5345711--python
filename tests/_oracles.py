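"""Independent reference implementations used only by the tests.

These deliberately avoid the package's closed-form determinant route: the
constrained multivariate-normal MLE is obtained by iterated feasible GLS on
the stacked (seemingly-unrelated) regression system, and elimination orders
by exhaustive single-removal search over refits.
"""

from __future__ import annotations

import numpy as np


def sur_mle_residual_det(Y: np.ndarray, x: np.ndarray, active: set[int],
                         tol: float = 1e-13, max_iter: int = 1000) -> float:
    """det of the MLE residual cross-product with genotype effects on `active`.

    Iterated FGLS on the stacked system (trait k regressed on [1, x] when
    k is active, on [1] otherwise) converges to the constrained maximum-
    likelihood estimate for the joint multivariate-normal model.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    N, p = Y.shape
    designs = [np.column_stack([np.ones(N), x]) if k in active else np.ones((N, 1))
               for k in range(p)]
    resid = np.empty((N, p))
    for k in range(p):
        Z = designs[k]
        b, *_ = np.linalg.lstsq(Z, Y[:, k], rcond=None)
        resid[:, k] = Y[:, k] - Z @ b
    for _ in range(max_iter):
        S = resid.T @ resid / N
        Sinv = np.linalg.inv(S)
        dims = [d.shape[1] for d in designs]
        off = np.cumsum([0] + dims)
        tot = off[-1]
        XtX = np.zeros((tot, tot))
        Xty = np.zeros(tot)
        for i in range(p):
            for j in range(p):
                XtX[off[i]:off[i + 1], off[j]:off[j + 1]] += (
                    Sinv[i, j] * designs[i].T @ designs[j])
            Xty[off[i]:off[i + 1]] += designs[i].T @ (Y * Sinv[i]).sum(axis=1)
        b = np.linalg.solve(XtX, Xty)
        old = resid.copy()
        for k in range(p):
            resid[:, k] = Y[:, k] - designs[k] @ b[off[k]:off[k + 1]]
        if np.max(np.abs(resid - old)) < tol:
            break
    return float(np.linalg.det(resid.T @ resid))


def sur_lrt(Y: np.ndarray, x: np.ndarray, active: set[int]) -> float:
    """Joint LRT for effects on `active` vs the no-QTL model, via the SUR MLE."""
    N = Y.shape[0]
    det0 = sur_mle_residual_det(Y, x, set())
    det1 = sur_mle_residual_det(Y, x, set(active))
    return N * np.log(det0 / det1)


def exhaustive_backward(Y: np.ndarray, x: np.ndarray
                        ) -> tuple[np.ndarray, list[int]]:
    """Backward elimination evaluating every single-removal refit exactly.

    Ties (equal statistics after removal) resolve to the lowest trait index.
    """
    p = Y.shape[1]
    active = list(range(p))
    best = np.empty(p)
    order = []
    best[p - 1] = sur_lrt(Y, x, set(active))
    while len(active) > 1:
        stats = [sur_lrt(Y, x, set(active) - {j}) for j in active]
        pick = int(np.argmax(stats))  # remove the trait losing least
        # argmax returns the first maximum; active is kept sorted so the
        # first maximum is the lowest trait index among ties
        order.append(active[pick])
        best[len(active) - 2] = stats[pick]
        active.pop(pick)
    order.append(active[0])
    return best, order


def univariate_lrt(y: np.ndarray, x: np.ndarray) -> float:
    """Single-trait LRT N * ln(RSS0 / RSS1) for regression of y on [1, x]."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    N = y.size
    yc = y - y.mean()
    xc = x - x.mean()
    rss0 = yc @ yc
    denom = xc @ xc
    if denom == 0:
        return 0.0
    beta = (xc @ yc) / denom
    resid = yc - beta * xc
    return N * np.log(rss0 / (resid @ resid))
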