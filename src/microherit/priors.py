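"""Variance-ratio parameterization: the simplex prior, its Beta(1,3)
marginals, and the phenotypic covariance structure V.

The model expresses the covariance of the n observations directly in
terms of the heritability h2, litter ratio l2 and cage ratio c2,

    V = sigma2_P * [K_A h2 + K_L l2 + K_C c2 + I (1 - h2 - l2 - c2)],

with K_A = Z_A A Z_A', K_L = Z_L Z_L', K_C = Z_C Z_C'.  The joint prior
of (h2, l2, c2) is uniform (density 6) on the unit 3-simplex
{r_i >= 0, sum <= 1}; each marginal is then Beta(1,3) = 3(1-r)^2, which
equals 3 at r = 0 — the prior ordinate entering the Bayes factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RATIO_NAMES = ("h2", "l2", "c2")


@dataclass(frozen=True)
class VarianceRatios:
    """(h2, l2, c2) constrained to the unit simplex."""

    h2: float
    l2: float
    c2: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < 0) or arr.sum() > 1.0 + 1e-12:
            raise ValueError(f"variance ratios off the unit simplex: {tuple(arr)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.h2, self.l2, self.c2], dtype=float)

    @property
    def residual(self) -> float:
        return 1.0 - self.h2 - self.l2 - self.c2


@dataclass(frozen=True)
class PhenotypicVariance:
    sigma2_P: float

    def __post_init__(self):
        if not self.sigma2_P > 0:
            raise ValueError("sigma2_P must be strictly positive")


@dataclass
class CovarianceKernels:
    """The three n x n covariance kernels of the ratio parameterization."""

    K_A: np.ndarray
    K_L: np.ndarray
    K_C: np.ndarray

    def __post_init__(self):
        n = self.K_A.shape[0]
        for name in ("K_A", "K_L", "K_C"):
            K = getattr(self, name)
            if K.shape != (n, n):
                raise ValueError(f"kernel {name} is not {n}x{n}")
            if not np.allclose(K, K.T):
                raise ValueError(f"kernel {name} is not symmetric")

    @property
    def n(self) -> int:
        return self.K_A.shape[0]

    @classmethod
    def from_design(cls, K_A: np.ndarray, design) -> "CovarianceKernels":
        return cls(K_A=K_A, K_L=design.Z_L @ design.Z_L.T, K_C=design.Z_C @ design.Z_C.T)


def sample_ratio_prior(n_draws: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw (h2, l2, c2) uniformly on the unit 3-simplex interior.

    Uses the Dirichlet(1,1,1,1) construction and drops the implicit fourth
    (residual) coordinate, which is exactly uniform on
    {r >= 0, sum(r) <= 1} with density 6.  Returns an ``(n_draws, 3)`` array.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_exponential(size=(n_draws, 4))
    return g[:, :3] / g.sum(axis=1, keepdims=True)


def joint_prior_density(h2, l2, c2) -> np.ndarray | float:
    """Joint prior density of the variance ratios: the constant 6 on the
    unit simplex {r >= 0, h2+l2+c2 <= 1} (the reciprocal of its volume),
    0 elsewhere.  Accepts scalars or broadcastable arrays."""
    h2, l2, c2 = np.asarray(h2, float), np.asarray(l2, float), np.asarray(c2, float)
    inside = (h2 >= 0) & (l2 >= 0) & (c2 >= 0) & (h2 + l2 + c2 <= 1.0)
    out = np.where(inside, 6.0, 0.0)
    return out if out.ndim else float(out)


def marginal_prior_density(r) -> np.ndarray | float:
    """Beta(1,3) marginal density 3(1-r)^2 of any single variance ratio."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("ratio outside [0, 1]")
    out = 3.0 * (1.0 - r) ** 2
    return out if out.ndim else float(out)


def ratio_kernel(ratios: VarianceRatios, kernels: CovarianceKernels) -> np.ndarray:
    """The bracketed correlation-scale matrix K(h2,l2,c2) of V = sigma2_P*K."""
    h2, l2, c2 = ratios.h2, ratios.l2, ratios.c2
    K = h2 * kernels.K_A + l2 * kernels.K_L + c2 * kernels.K_C
    K[np.diag_indices_from(K)] += 1.0 - h2 - l2 - c2
    return K


def build_V(
    ratios: VarianceRatios, sigma2_P: PhenotypicVariance | float, kernels: CovarianceKernels
) -> np.ndarray:
    """The phenotypic covariance matrix V (symmetric PSD)."""
    s2 = sigma2_P.sigma2_P if isinstance(sigma2_P, PhenotypicVariance) else float(sigma2_P)
    if not s2 > 0:
        raise ValueError("sigma2_P must be strictly positive")
    return s2 * ratio_kernel(ratios, kernels)
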