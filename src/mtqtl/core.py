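"""Batched likelihood-ratio machinery for multivariate-normal QTL regression.

The single-locus model regresses p traits on an intercept and one coded
genotype column, allowing the genotype effect on an arbitrary subset K of
traits (the remaining traits keep intercept-only means but share the
residual covariance).  The constrained maximum-likelihood fit has a closed
form: factor the joint density into the marginal law of the unaffected
traits and the conditional law of the affected traits given them, each an
unrestricted regression.  Writing S for the centered trait cross-product
matrix and W for the cross-product of residuals after regressing every
trait on the genotype,

    n * det(Sigma_hat_K) = det(S[Kbar]) * det(W) / det(W[Kbar]),

with Kbar the complement of K, so the LRT against the no-QTL model is

    T(K) = N * ( ln det S - ln det S[Kbar] - ln det W + ln det W[Kbar] ).

Every statistic in the package (best-k backward-elimination sequences,
individual-effect and single-effect tests) therefore reduces to submatrix
log-determinants of the two p x p matrices S and W, which this module
evaluates in bulk across loci, permutations and bootstrap resamples.
Submatrix determinants use Jacobi's complementary-minor identity
det(S[A]) = det(S) * det(inv(S)[A^c]) whenever the complement is smaller,
so the working determinant order never exceeds p/2.
"""

from __future__ import annotations

import numpy as np

_MONO_EPS = 1e-12


def center(a: np.ndarray) -> np.ndarray:
    """Column-center a vector or matrix."""
    return a - a.mean(axis=0, keepdims=True)


def trait_cross_product(Y: np.ndarray) -> np.ndarray:
    """S = Yc' Yc, the centered p x p trait cross-product."""
    Yc = center(np.asarray(Y, dtype=float))
    return Yc.T @ Yc


def residual_cross_products(S: np.ndarray, Yc: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """W matrices for a block of centered genotype columns.

    Parameters
    ----------
    S : (p, p) centered trait cross-product.
    Yc : (N, p) centered traits.
    Xc : (N, m) centered genotype columns (one per locus/resample).

    Returns
    -------
    (m, p, p) array; column j gives the residual cross-product of the
    traits after removing genotype column j.  A monomorphic column
    (zero variance) yields W = S, hence every statistic 0.
    """
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    if Xc.ndim == 1:
        Xc = Xc[:, None]
    Xc = Xc - Xc.mean(axis=0, keepdims=True)  # idempotent for centered input
    sxx = np.einsum("nm,nm->m", Xc, Xc)
    sxy = Yc.T @ Xc  # (p, m)
    safe = np.where(sxx > _MONO_EPS, sxx, np.inf)
    outer = sxy.T[:, :, None] * sxy.T[:, None, :]  # (m, p, p)
    return S[None, :, :] - outer / safe[:, None, None]


def _det_closed(A: np.ndarray) -> np.ndarray:
    """Determinants of stacked small symmetric matrices, order <= 4."""
    q = A.shape[-1]
    if q == 0:
        return np.ones(A.shape[:-2])
    if q == 1:
        return A[..., 0, 0]
    if q == 2:
        return A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    if q == 3:
        a, b, c = A[..., 0, 0], A[..., 0, 1], A[..., 0, 2]
        d, e, f = A[..., 1, 0], A[..., 1, 1], A[..., 1, 2]
        g, h, i = A[..., 2, 0], A[..., 2, 1], A[..., 2, 2]
        return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    if q == 4:
        # cofactor expansion along the first row using 3x3 minors
        minors = []
        cols = np.arange(4)
        for j in range(4):
            keep = cols[cols != j]
            sub = A[..., 1:, :][..., :, keep]
            minors.append(_det_closed(sub))
        return (A[..., 0, 0] * minors[0] - A[..., 0, 1] * minors[1]
                + A[..., 0, 2] * minors[2] - A[..., 0, 3] * minors[3])
    raise ValueError("closed form limited to order <= 4")


def batched_logdet(A: np.ndarray) -> np.ndarray:
    """log|det| of stacked symmetric positive matrices of any small order."""
    q = A.shape[-1]
    if q <= 4:
        d = _det_closed(A)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(np.abs(d))
    sign, ld = np.linalg.slogdet(A)
    return np.where(sign > 0, ld, -np.inf)


def _gather_sub(A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Stacked principal submatrices A[idx, idx].

    A is (p, p) shared or (M, p, p) per-item; idx is (M, C, q).
    Returns (M, C, q, q).
    """
    rows = idx[:, :, :, None]
    cols = idx[:, :, None, :]
    if A.ndim == 2:
        return A[rows, cols]
    items = np.arange(A.shape[0])[:, None, None, None]
    return A[items, rows, cols]


class LocusWorkspace:
    """Precomputed determinant machinery for a batch of loci.

    Holds S (shared or per-item), the per-locus W matrices, their inverses
    and log-determinants, and answers submatrix log-determinant queries via
    whichever of the direct or complementary (Jacobi) route involves the
    smaller order.
    """

    def __init__(self, S: np.ndarray, W: np.ndarray, n_obs: int):
        self.S = np.asarray(S, dtype=float)
        self.W = np.asarray(W, dtype=float)
        self.n_obs = int(n_obs)
        self.m = self.W.shape[0]
        self.p = self.W.shape[-1]
        if self.S.ndim == 2:
            self.logdet_S = float(batched_logdet(self.S[None])[0])
            self._ldS_col = self.logdet_S
        else:
            self.logdet_S = batched_logdet(self.S)
            self._ldS_col = self.logdet_S[:, None]
        self.logdet_W = batched_logdet(self.W)
        self.Sinv = np.linalg.inv(self.S)
        self.Winv = np.linalg.inv(self.W)

    def _sub_logdet(self, direct_idx: np.ndarray, comp_idx: np.ndarray,
                    use: str) -> tuple[np.ndarray, np.ndarray]:
        """(ln det S[idx], ln det W[idx]) for stacked index sets.

        direct_idx : (M, C, q) indices of the submatrix itself.
        comp_idx   : (M, C, p-q) complementary indices.
        use        : 'direct' or 'comp' route selection.
        """
        if use == "direct":
            ls = batched_logdet(_gather_sub(self.S, direct_idx))
            lw = batched_logdet(_gather_sub(self.W, direct_idx))
        else:
            ls = self._ldS_col + batched_logdet(_gather_sub(self.Sinv, comp_idx))
            lw = self.logdet_W[:, None] + batched_logdet(_gather_sub(self.Winv, comp_idx))
        return ls, lw

    def full_stat(self) -> np.ndarray:
        """T with every effect in the model, per locus."""
        t = self.n_obs * (self.logdet_S - self.logdet_W)
        return np.clip(t, 0.0, None)

    def active_set_stat(self, active: np.ndarray) -> np.ndarray:
        """T(K) for one fixed active trait set, per locus."""
        active = np.asarray(active, dtype=int)
        kbar = np.setdiff1d(np.arange(self.p), active)
        if kbar.size == 0:
            return self.full_stat()
        M = self.m
        if kbar.size <= active.size:
            idx = np.broadcast_to(kbar, (M, 1, kbar.size))
            ls, lw = self._sub_logdet(idx, None, "direct")
        else:
            comp = np.broadcast_to(active, (M, 1, active.size))
            ls, lw = self._sub_logdet(None, comp, "comp")
        t = self.full_stat() - self.n_obs * (ls[:, 0] - lw[:, 0])
        return np.clip(t, 0.0, None)

    def individual_stats(self) -> np.ndarray:
        """(M, p) tests of each effect given all others: T(full) - T(full\\k)."""
        dS = np.diagonal(self.S, axis1=-2, axis2=-1)
        dW = np.diagonal(self.W, axis1=-2, axis2=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.n_obs * (np.log(dS) - np.log(dW))
        t = np.broadcast_to(t, (self.m, self.p)).copy() if t.ndim == 1 else t
        return np.clip(np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0), 0.0, None)

    def single_effect_stats(self) -> np.ndarray:
        """(M, p) tests of each effect alone, all others excluded (H4-type).

        T({k}) = N * (ln Winv_kk - ln Sinv_kk) by the complementary-minor
        identity applied to the (p-1)-order determinants.
        """
        dSi = np.diagonal(self.Sinv, axis1=-2, axis2=-1)
        dWi = np.diagonal(self.Winv, axis1=-2, axis2=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.n_obs * (np.log(dWi) - np.log(dSi))
        if t.ndim == 1 or t.shape[0] != self.m:
            t = np.broadcast_to(t, (self.m, self.p)).copy()
        return np.clip(np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0), 0.0, None)

    def backward_eliminate(self) -> tuple[np.ndarray, np.ndarray]:
        """Best-k statistic sequences by backward elimination, per locus.

        Returns
        -------
        best_k : (M, p) array; column k-1 is the joint LRT of the k effects
            surviving after p-k removals.  Nondecreasing along k.
        order : (M, p) int array; the trait removed at each step, first
            removal first (the last entry is the sole survivor).

        At each step the effect whose removal reduces the joint statistic
        least is dropped; ties go to the lowest trait index.
        """
        M, p = self.m, self.p
        n = self.n_obs
        t_full = self.full_stat()
        best = np.empty((M, p))
        order = np.empty((M, p), dtype=int)
        best[:, p - 1] = t_full
        active = np.tile(np.arange(p), (M, 1))
        removed = np.empty((M, 0), dtype=int)
        rows = np.arange(M)
        for step in range(p - 1):
            k = p - step          # current active-set size
            q = step + 1          # candidate removed-set size
            cand = np.concatenate(
                [np.broadcast_to(removed[:, None, :], (M, k, step)),
                 active[:, :, None]], axis=2)
            if q <= k - 1:
                ls, lw = self._sub_logdet(cand, None, "direct")
            else:
                comp = np.empty((M, k, k - 1), dtype=int)
                for c in range(k):
                    comp[:, c, :c] = active[:, :c]
                    comp[:, c, c:] = active[:, c + 1:]
                ls, lw = self._sub_logdet(None, comp, "comp")
            score = ls - lw
            score = np.nan_to_num(score, nan=np.inf, posinf=np.inf, neginf=np.inf)
            choice = np.argmin(score, axis=1)  # first minimum -> lowest index
            chosen = active[rows, choice]
            order[:, step] = chosen
            best[:, k - 2] = t_full - n * score[rows, choice]
            removed = np.concatenate([removed, chosen[:, None]], axis=1)
            keep = np.ones((M, k), dtype=bool)
            keep[rows, choice] = False
            active = active[keep].reshape(M, k - 1)
        order[:, p - 1] = active[:, 0]
        best = np.clip(best, 0.0, None)
        np.maximum.accumulate(best, axis=1, out=best)  # numerical guard
        return best, order


def workspace_for_loci(Y: np.ndarray, X: np.ndarray) -> LocusWorkspace:
    """Build a LocusWorkspace for traits Y against genotype columns X."""
    Y = np.asarray(Y, dtype=float)
    Yc = center(Y)
    S = Yc.T @ Yc
    W = residual_cross_products(S, Yc, X)
    return LocusWorkspace(S, W, Y.shape[0])
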