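"""Hierarchical zero-inflated Poisson (ZIP) mixed model sampler.

A count trait y_i is a structural zero with probability p, or Poisson
with mean lambda_i = exp(lambda*_i) with probability 1 - p.  Working on
the log/logit scale (lambda*_i, p*), the data likelihood is

    prod_{y_i=0} [ (1/(1+e^{p*})) (e^{p*} + e^{-exp(lambda*_i)}) ]
  * prod_{y_i>0} [ (1/(1+e^{p*})) e^{-exp(lambda*_i) + lambda*_i y_i} / y_i! ],

the structural-zero indicators being marginalized out.  The second
hierarchical stage puts the Gaussian animal model on lambda*:
lambda* ~ MVN(X beta, V) with the same ratio-parameterized V as the
linear model, so the Gibbs/Metropolis machinery for (beta, sigma2_P,
h2, l2, c2) is shared with the LMM.  p* carries a uniform prior on
[-5, 5]; each lambda*_i and p* are updated by random-walk Metropolis.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cho_solve, lapack
from scipy.special import expit, gammaln

from . import _linalg
from .lmm import Chain, GaussianRatioSampler, MCMCSettings
from .priors import CovarianceKernels, ratio_kernel

__all__ = ["zip_log_likelihood", "link_transforms", "run_zip_mcmc",
           "mh_update_lambda_star", "mh_update_pstar", "PSTAR_BOUND"]

#: uniform prior bound on the zero-inflation logit
PSTAR_BOUND = 5.0

_EXP_CLIP = 700.0  # exp() overflow guard on the log-mean scale


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("ZIP data must be non-negative integers")
    return y.astype(np.int64)


def zip_log_likelihood(y, lambda_star, p_star: float) -> float:
    """Stable log-space evaluation of the marginalized ZIP likelihood."""
    y = _validate_counts(y)
    lam_star = np.asarray(lambda_star, dtype=float)
    lam = np.exp(np.minimum(lam_star, _EXP_CLIP))
    zero = y == 0
    # every observation carries the -log(1 + e^{p*}) normalizer
    total = -y.size * np.logaddexp(0.0, p_star)
    total += float(np.sum(np.logaddexp(p_star, -lam[zero])))
    pos = ~zero
    total += float(np.sum(-lam[pos] + lam_star[pos] * y[pos] - gammaln(y[pos] + 1.0)))
    return float(total)


def link_transforms(lambda_star=None, p_star=None):
    """Recover (lambda, p) from the log / logit working scales."""
    lam = None if lambda_star is None else np.exp(np.asarray(lambda_star, dtype=float))
    p = None if p_star is None else expit(p_star)
    if lam is None:
        return p
    if p is None:
        return lam
    return lam, p


def _data_term(y_i: int, lam_star_i: float, p_star: float) -> float:
    """Per-observation log data term as a function of lambda*_i
    (the shared 1/(1+e^{p*}) normalizer dropped)."""
    lam = math.exp(min(lam_star_i, _EXP_CLIP))
    if y_i == 0:
        # logaddexp(p*, -lam) with scalar math
        hi, lo = (p_star, -lam) if p_star >= -lam else (-lam, p_star)
        return hi + math.log1p(math.exp(lo - hi))
    return -lam + lam_star_i * y_i


def mh_update_lambda_star(i, state, y, X, kernels: CovarianceKernels,
                          step: float, rng: np.random.Generator) -> float:
    """One Metropolis try on lambda*_i against its ZIP data term times the
    conditional normal of lambda*_i | lambda*_{-i} under MVN(X beta, V).

    Reference implementation used in tests; the run loop performs the same
    update with a precision matrix cached per iteration.
    """
    lam_star = np.asarray(state.lambda_star, dtype=float)
    resid = lam_star - (X @ state.beta if X is not None and np.size(state.beta) else 0.0)
    K = ratio_kernel(state.ratios, kernels)
    P = cho_solve(_linalg.factor(K), np.eye(K.shape[0]), check_finite=False) / state.sigma2
    q = P @ resid
    prop = lam_star[i] + step * rng.standard_normal()
    delta = prop - lam_star[i]
    d_data = _data_term(int(y[i]), prop, state.p_star) - _data_term(
        int(y[i]), lam_star[i], state.p_star)
    d_prior = -(delta * q[i] + 0.5 * delta * delta * P[i, i])
    if np.log(rng.uniform()) < d_data + d_prior:
        return prop
    return lam_star[i]


def _pstar_logtarget(p_star: float, n: int, neg_lam_zero: np.ndarray) -> float:
    return -n * np.logaddexp(0.0, p_star) + float(
        np.sum(np.logaddexp(p_star, neg_lam_zero)))


def mh_update_pstar(state, y, step: float, rng: np.random.Generator) -> float:
    """Reflected random-walk Metropolis on p* within [-5, 5]."""
    from .lmm import _reflect

    y = _validate_counts(y)
    lam_star = np.asarray(state.lambda_star, dtype=float)
    neg_lam_zero = -np.exp(np.minimum(lam_star[y == 0], _EXP_CLIP))
    prop = _reflect(state.p_star + step * rng.standard_normal(),
                    -PSTAR_BOUND, PSTAR_BOUND)
    d = _pstar_logtarget(prop, y.size, neg_lam_zero) - _pstar_logtarget(
        state.p_star, y.size, neg_lam_zero)
    if np.log(rng.uniform()) < d:
        return prop
    return state.p_star


class ZIPState:
    """Current draw of the ZIP sampler: per-animal log Poisson means, the
    zero-inflation logit, and the Gaussian second-stage parameters."""

    def __init__(self, lambda_star, p_star, beta, ratios, sigma2):
        self.lambda_star = lambda_star
        self.p_star = p_star
        self.beta = beta
        self.ratios = ratios
        self.sigma2 = sigma2


def run_zip_mcmc(y, design, kernels: CovarianceKernels,
                 settings: MCMCSettings = MCMCSettings()) -> Chain:
    """Run the full ZIP chain: per iteration a sweep over all lambda*_i,
    a p* update, then the shared Gaussian stage (beta, sigma2_P, ratios)
    with lambda* playing the role of the data.  Deterministic given seed.
    """
    from .lmm import _reflect, _StepAdapter

    y = _validate_counts(y)
    n = y.size
    X = getattr(design, "X", design)
    rng = np.random.default_rng(settings.seed)
    stage = GaussianRatioSampler(X, kernels, settings, rng)

    lam_star = np.where(y > 0, np.log(np.maximum(y, 1) + 0.5), np.log(0.5))
    gstate = stage.initial_state(lam_star)
    zero_frac = float(np.mean(y == 0))
    p_star = float(np.log(np.clip(zero_frac, 0.02, 0.98)
                          / (1.0 - np.clip(zero_frac, 0.02, 0.98))))
    p_star = float(np.clip(p_star, -PSTAR_BOUND, PSTAR_BOUND))

    lam_adapt = _StepAdapter(settings.step_lambda, settings.adapt, every=5 * n)
    pst_adapt = _StepAdapter(settings.step_pstar, settings.adapt)

    n_kept = settings.n_iter - settings.burnin
    kept_r = np.empty((n_kept, 3))
    kept_s2 = np.empty(n_kept)
    kept_beta = np.empty((n_kept, gstate.beta.size))
    kept_dev = np.empty(n_kept)
    kept_pstar = np.empty(n_kept)
    lam_mean = np.zeros(n)
    logs = {nm: [] for nm in stage.free}
    zero_idx = y == 0

    for it in range(settings.n_iter):
        adapting = it < settings.burnin
        k = it - settings.burnin

        # precision of lambda* under the current second-stage draw
        K = ratio_kernel(gstate.ratios, kernels)
        cho = _linalg.factor(K)
        Pinv, info = lapack.dpotri(cho[0], lower=True)
        if info:
            raise np.linalg.LinAlgError("kernel inversion failed")
        P = np.tril(Pinv) + np.tril(Pinv, -1).T
        P /= gstate.sigma2
        mu = X @ gstate.beta if stage.X is not None else np.zeros(n)
        resid = lam_star - mu
        q = P @ resid
        Pdiag = np.diag(P).copy()

        # elementwise Metropolis sweep over lambda*
        steps = lam_adapt.step * rng.standard_normal(n)
        logu = np.log(rng.uniform(size=n))
        yl, ll = y.tolist(), lam_star.tolist()
        for i in range(n):
            cur = ll[i]
            delta = steps[i]
            prop = cur + delta
            d_data = _data_term(yl[i], prop, p_star) - _data_term(yl[i], cur, p_star)
            d_prior = -(delta * q[i] + 0.5 * delta * delta * Pdiag[i])
            acc = logu[i] < d_data + d_prior
            lam_adapt.record(acc, adapting)
            if acc:
                ll[i] = prop
                q += delta * P[:, i]
        lam_star = np.asarray(ll)

        # zero-inflation logit, reflected inside its uniform prior bounds
        neg_lam_zero = -np.exp(np.minimum(lam_star[zero_idx], _EXP_CLIP))
        prop = _reflect(p_star + pst_adapt.step * rng.standard_normal(),
                        -PSTAR_BOUND, PSTAR_BOUND)
        d = _pstar_logtarget(prop, n, neg_lam_zero) - _pstar_logtarget(
            p_star, n, neg_lam_zero)
        acc = np.log(rng.uniform()) < d
        pst_adapt.record(bool(acc), adapting)
        if acc:
            p_star = prop

        # shared Gaussian stage on lambda* (ratios unchanged since `cho`)
        want_bf = (settings.bf_stride > 0 and not adapting
                   and k % settings.bf_stride == 0)
        _, log_zero = stage.sweep(lam_star, gstate, adapting, want_bf, cho=cho)

        if not adapting:
            kept_r[k] = gstate.ratios.as_array()
            kept_s2[k] = gstate.sigma2
            kept_beta[k] = gstate.beta
            kept_pstar[k] = p_star
            kept_dev[k] = -2.0 * zip_log_likelihood(y, lam_star, p_star)
            lam_mean += lam_star
            for nm, v in log_zero.items():
                logs[nm].append(v)

    return Chain(
        model="zip",
        ratios=kept_r, sigma2=kept_s2, beta=kept_beta, deviance=kept_dev,
        log_zero_density={nm: np.array(v) for nm, v in logs.items()},
        n_kept=n_kept, n_burnin=settings.burnin, seed=settings.seed,
        accept_rates={
            **{nm: a.rate for nm, a in stage.adapters.items()},
            "lambda_star": lam_adapt.rate, "p_star": pst_adapt.rate,
        },
        p_star=kept_pstar, lambda_star_mean=lam_mean / n_kept,
    )
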