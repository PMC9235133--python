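"""Spectral profile of the covariance kernel along one variance ratio.

Writing the bracketed kernel as K(r) = M + r*Delta (M collects the other
two ratios plus the residual identity, Delta = K_j - I), a Cholesky of M
and one symmetric eigendecomposition give the Gaussian log-likelihood at
ANY r in O(n) afterwards:

    K(r) = L (I + r W) L',   W = L^{-1} Delta L^{-T} = U diag(d) U',
    log|K(r)| = log|M| + sum log(1 + r d_i),
    e' K(r)^{-1} e = sum z_i^2 / (1 + r d_i),  z = U' L^{-1} e.

This makes the Metropolis step on a ratio and the 129-point quadrature of
its conditional density (for the Savage-Dickey ordinate at zero) share a
single O(n^3) factorization per ratio per iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh, solve_triangular

LOG2PI = float(np.log(2.0 * np.pi))


def chol_logdet(cho) -> float:
    c, _ = cho
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def factor(K: np.ndarray):
    """Cholesky factorization of a PD kernel (scipy cho_factor tuple)."""
    return cho_factor(K, lower=True, check_finite=False)


def gaussian_loglik(resid: np.ndarray, cho, sigma2: float) -> float:
    """log MVN(resid; 0, sigma2*K) given the Cholesky of K."""
    n = resid.size
    S = float(resid @ cho_solve(cho, resid, check_finite=False))
    return -0.5 * (n * (LOG2PI + np.log(sigma2)) + chol_logdet(cho) + S / sigma2)


class RatioProfile:
    """Eigen-profile of K(r) = M + r*Delta for one variance ratio."""

    def __init__(self, M: np.ndarray, Delta: np.ndarray):
        L = cholesky(M, lower=True, check_finite=False)
        self.logdetM = 2.0 * float(np.sum(np.log(np.diag(L))))
        T = solve_triangular(L, Delta, lower=True, check_finite=False)
        W = solve_triangular(L, T.T, lower=True, check_finite=False)
        d, U = eigh(W, check_finite=False)
        self.d = d
        # rows of B map a residual to the eigenbasis: z = B @ resid
        self.B = solve_triangular(L, U, lower=True, trans="T", check_finite=False).T
        self.n = M.shape[0]

    def transform(self, resid: np.ndarray) -> np.ndarray:
        return self.B @ resid

    def loglik(self, r, z: np.ndarray, sigma2: float):
        """MVN log-likelihood at ratio value(s) ``r`` (scalar or 1-D array)."""
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        a = 1.0 + r_arr[:, None] * self.d[None, :]  # (G, n)
        out = np.full(r_arr.shape, -np.inf)
        ok = a.min(axis=1) > 0.0
        if np.any(ok):
            ak = a[ok]
            logdet = self.logdetM + np.sum(np.log(ak), axis=1)
            quad = np.sum((z * z)[None, :] / ak, axis=1)
            out[ok] = -0.5 * (
                self.n * (LOG2PI + np.log(sigma2)) + logdet + quad / sigma2
            )
        return out if np.ndim(r) else float(out[0])
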