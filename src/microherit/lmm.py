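"""Metropolis-within-Gibbs sampler for the linear mixed animal model
parameterized on variance ratios.

Data model:  y | beta, V  ~  MVN(X beta, V),  with
V = sigma2_P * [K_A h2 + K_L l2 + K_C c2 + I(1 - h2 - l2 - c2)].

Priors: flat on beta, flat on sigma2_P over the positive reals, and the
uniform simplex prior (density 6) on (h2, l2, c2).  beta and sigma2_P
have closed-form conditionals and are updated by Gibbs; each ratio is
updated by a reflected Gaussian random-walk Metropolis step on
[0, 1 - (sum of the other two)].  Alongside the draws, the sampler
evaluates the normalized conditional density of each ratio at zero (the
Savage-Dickey posterior ordinate feeding the Bayes factors) and the
deviance -2 log MVN(y; X beta, V).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from . import _linalg
from .bayesfactor import log_conditional_density_at_zero
from .priors import RATIO_NAMES, CovarianceKernels, VarianceRatios, ratio_kernel

__all__ = [
    "MCMCSettings",
    "Chain",
    "lmm_log_likelihood",
    "gibbs_update_beta",
    "gibbs_update_sigma2",
    "mh_update_ratio",
    "run_lmm_mcmc",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings; defaults follow the emulated study design
    (10,000 iterations with the first 1000 discarded, no thinning)."""

    n_iter: int = 10_000
    burnin: int = 1_000
    step_ratio: float = 0.05
    step_lambda: float = 0.3
    step_pstar: float = 0.5
    adapt: bool = True
    bf_grid: int = 129
    #: evaluate the Savage-Dickey ordinates every `bf_stride` kept iterations
    #: (1 = every iteration; 0 disables the evaluation entirely).
    bf_stride: int = 1
    seed: int = 0
    #: ratios pinned to a constant (e.g. {"l2": 0.0, "c2": 0.0} for a
    #: single-ratio reduced model); pinned ratios are neither updated nor
    #: given Savage-Dickey ordinates.
    fix_ratios: dict | None = None

    def __post_init__(self):
        if self.n_iter <= self.burnin:
            raise ValueError("n_iter must exceed burnin")
        if self.step_ratio <= 0:
            raise ValueError("step_ratio must be positive")


@dataclass
class Chain:
    """Post-burn-in draws plus the per-iteration Savage-Dickey ordinates
    (log scale) and the deviance trace."""

    model: str
    ratios: np.ndarray  # (n_kept, 3) in (h2, l2, c2) order
    sigma2: np.ndarray  # (n_kept,)
    beta: np.ndarray  # (n_kept, p)
    deviance: np.ndarray  # (n_kept,)
    log_zero_density: dict  # ratio name -> (n_evaluated,) log ordinates
    n_kept: int
    n_burnin: int
    seed: int
    accept_rates: dict = field(default_factory=dict)
    p_star: np.ndarray | None = None  # ZIP only
    lambda_star_mean: np.ndarray | None = None  # ZIP only

    def ratio(self, name: str) -> np.ndarray:
        return self.ratios[:, RATIO_NAMES.index(name)]

    def posterior_mean_state(self):
        """Posterior means of (beta, ratios, sigma2_P) for DIC's D(theta-bar)."""
        r = self.ratios.mean(axis=0)
        return (
            self.beta.mean(axis=0),
            VarianceRatios(*np.minimum(r, 1.0)),
            float(self.sigma2.mean()),
        )


# ---------------------------------------------------------------------------
# Elementary conditional updates (also the public, test-facing operations)
# ---------------------------------------------------------------------------

def lmm_log_likelihood(y: np.ndarray, beta: np.ndarray, V: np.ndarray, X: np.ndarray | None) -> float:
    """Multivariate-normal log density of y at mean X beta, covariance V."""
    resid = y - (X @ beta if X is not None and np.size(beta) else 0.0)
    cho = _linalg.factor(V)
    return _linalg.gaussian_loglik(np.asarray(resid, dtype=float), cho, 1.0)


def gibbs_update_beta(y, X, V, rng: np.random.Generator) -> np.ndarray:
    """Draw beta ~ MVN((X'V^-1 X)^-1 X'V^-1 y, (X'V^-1 X)^-1) (flat prior)."""
    cho = _linalg.factor(V)
    Vi_X = cho_solve(cho, X, check_finite=False)
    G = X.T @ Vi_X
    Gc = cho_factor(G, lower=False, check_finite=False)
    mean = cho_solve(Gc, Vi_X.T @ y, check_finite=False)
    # G = U'U  =>  cov = G^-1 = U^-1 U^-T ; draw = mean + U^-1 z
    z = rng.standard_normal(X.shape[1])
    return mean + solve_triangular(Gc[0], z, lower=False, check_finite=False)


def gibbs_update_sigma2(y, X, beta, ratios: VarianceRatios, kernels: CovarianceKernels,
                        rng: np.random.Generator) -> float:
    """Draw sigma2_P from its scaled inverse-chi-square conditional.

    The flat positive prior gives p(sigma2 | rest) proportional to
    (sigma2)^(-n/2) exp(-S / (2 sigma2)) with S = (y - X beta)' K^-1 (y - X beta),
    i.e. inverse-gamma with shape n/2 - 1 and scale S/2.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 2:
        raise ValueError("sigma2 update needs n > 2")
    resid = y - (X @ beta if X is not None and np.size(beta) else 0.0)
    cho = _linalg.factor(ratio_kernel(ratios, kernels))
    S = float(resid @ cho_solve(cho, resid, check_finite=False))
    if S <= 0:
        raise ValueError("non-positive residual quadratic form")
    return (S / 2.0) / rng.gamma(n / 2.0 - 1.0)


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    t = (x - lo) % (2.0 * width)
    return lo + (width - abs(t - width))


def mh_update_ratio(which: str, state, w, X, kernels: CovarianceKernels,
                    step: float, rng: np.random.Generator):
    """One reflected random-walk Metropolis try on a single variance ratio.

    The proposal is Normal(current, step^2) reflected into [0, ub] with
    ub = 1 - (sum of the other two ratios); the flat simplex prior cancels,
    so acceptance uses the Gaussian likelihood ratio alone.  Returns
    ``(new_ratios, accepted)``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    j = RATIO_NAMES.index(which)
    r = state.ratios.as_array()
    ub = 1.0 - (r.sum() - r[j])
    if ub <= 0:
        return state.ratios, False
    prop = _reflect(r[j] + step * rng.standard_normal(), 0.0, ub)
    resid = w - (X @ state.beta if X is not None and np.size(state.beta) else 0.0)
    prof = _ratio_profile(j, r, kernels)
    z = prof.transform(resid)
    ll_cur = prof.loglik(r[j], z, state.sigma2)
    ll_prop = prof.loglik(prop, z, state.sigma2)
    if np.log(rng.uniform()) < ll_prop - ll_cur:
        r = r.copy()
        r[j] = prop
        return VarianceRatios(*r), True
    return state.ratios, False


def _ratio_profile(j: int, r: np.ndarray, kernels: CovarianceKernels) -> _linalg.RatioProfile:
    Ks = (kernels.K_A, kernels.K_L, kernels.K_C)
    n = kernels.n
    M = np.zeros((n, n))
    other_sum = 0.0
    for k in range(3):
        if k != j:
            M += r[k] * Ks[k]
            other_sum += r[k]
    M[np.diag_indices_from(M)] += 1.0 - other_sum
    Delta = Ks[j] - np.eye(n)
    return _linalg.RatioProfile(M, Delta)


# ---------------------------------------------------------------------------
# Full sampler
# ---------------------------------------------------------------------------

@dataclass
class LMMState:
    """Current draw of the Gaussian stage: systematic effects, variance
    ratios on the simplex, and the phenotypic variance."""

    beta: np.ndarray
    ratios: VarianceRatios
    sigma2: float


class _StepAdapter:
    """Adapt a random-walk step toward 20-45% acceptance during burn-in,
    then freeze (adapting kept samples would bias the ordinate average)."""

    def __init__(self, step: float, enabled: bool, every: int = 25):
        self.step = step
        self.enabled = enabled
        self.every = every
        self.tries = 0
        self.accepts = 0
        self.total_tries = 0
        self.total_accepts = 0

    def record(self, accepted: bool, adapting: bool):
        self.tries += 1
        self.accepts += accepted
        if not adapting:
            self.total_tries += 1
            self.total_accepts += accepted
        if adapting and self.enabled and self.tries >= self.every:
            rate = self.accepts / self.tries
            if rate < 0.20:
                self.step *= 0.7
            elif rate > 0.45:
                self.step *= 1.3
            self.tries = 0
            self.accepts = 0

    @property
    def rate(self) -> float:
        return self.total_accepts / max(self.total_tries, 1)


class GaussianRatioSampler:
    """One Metropolis-within-Gibbs sweep over (beta, sigma2_P, h2, l2, c2)
    for a Gaussian vector w ~ MVN(X beta, sigma2_P * K(ratios)).

    Used directly by the linear model (w = y) and as the second stage of
    the zero-inflated Poisson model (w = lambda*).  Update order is
    beta -> sigma2_P -> h2 -> l2 -> c2, one Metropolis try per ratio.
    """

    def __init__(self, X, kernels: CovarianceKernels, settings: MCMCSettings,
                 rng: np.random.Generator):
        self.X = X if X is not None and X.size else None
        self.kernels = kernels
        self.settings = settings
        self.rng = rng
        fixed = settings.fix_ratios or {}
        self.free = [nm for nm in RATIO_NAMES if nm not in fixed]
        self.fixed = dict(fixed)
        self.adapters = {nm: _StepAdapter(settings.step_ratio, settings.adapt)
                         for nm in self.free}
        self._Ks = (kernels.K_A, kernels.K_L, kernels.K_C)
        self._eye = np.eye(kernels.n)

    def initial_state(self, w) -> LMMState:
        p = self.X.shape[1] if self.X is not None else 0
        r = {nm: self.fixed.get(nm, 0.1) for nm in RATIO_NAMES}
        beta = np.zeros(p)
        if self.X is not None:
            beta, *_ = np.linalg.lstsq(self.X, w, rcond=None)
        resid = w - (self.X @ beta if self.X is not None else 0.0)
        s2 = max(float(np.var(resid)), 1e-8)
        return LMMState(beta, VarianceRatios(r["h2"], r["l2"], r["c2"]), s2)

    def sweep(self, w, state: LMMState, adapting: bool, want_bf: bool, cho=None):
        """Update state in place; return (loglik, {name: log ordinate}).

        ``cho`` may pass a Cholesky of the CURRENT ratio kernel to avoid a
        refactorization (the ZIP loop already holds one).
        """
        rng = self.rng
        n = w.size
        r = state.ratios.as_array()
        K = ratio_kernel(state.ratios, self.kernels)
        if cho is None:
            cho = _linalg.factor(K)
        logdetK = _linalg.chol_logdet(cho)

        if self.X is not None:
            Ki_X = cho_solve(cho, self.X, check_finite=False)
            G = self.X.T @ Ki_X
            Gc = cho_factor(G, lower=False, check_finite=False)
            mean = cho_solve(Gc, Ki_X.T @ w, check_finite=False)
            z = rng.standard_normal(self.X.shape[1])
            state.beta = mean + np.sqrt(state.sigma2) * solve_triangular(
                Gc[0], z, lower=False, check_finite=False)
            resid = w - self.X @ state.beta
        else:
            resid = np.asarray(w, dtype=float)

        S = float(resid @ cho_solve(cho, resid, check_finite=False))
        state.sigma2 = (S / 2.0) / rng.gamma(n / 2.0 - 1.0)
        loglik = -0.5 * (n * (_linalg.LOG2PI + np.log(state.sigma2))
                         + logdetK + S / state.sigma2)

        log_zero = {}
        for nm in self.free:
            j = RATIO_NAMES.index(nm)
            ub = 1.0 - (r.sum() - r[j])
            adapter = self.adapters[nm]
            if ub <= 0:
                adapter.record(False, adapting)
                continue
            prop = _reflect(r[j] + adapter.step * rng.standard_normal(), 0.0, ub)
            if want_bf:
                prof = _ratio_profile(j, r, self.kernels)
                zres = prof.transform(resid)
                ll_cur = prof.loglik(r[j], zres, state.sigma2)
                ll_prop = prof.loglik(prop, zres, state.sigma2)
            else:
                prof = None
                ll_cur = loglik
                d = prop - r[j]
                Kp = K + d * self._Ks[j]
                Kp[np.diag_indices_from(Kp)] -= d
                try:
                    chp = _linalg.factor(Kp)
                    ll_prop = _linalg.gaussian_loglik(resid, chp, state.sigma2)
                except np.linalg.LinAlgError:
                    ll_prop = -np.inf
            accepted = np.log(rng.uniform()) < ll_prop - ll_cur
            adapter.record(bool(accepted), adapting)
            if accepted:
                if prof is None:
                    loglik = ll_prop
                    K += (prop - r[j]) * self._Ks[j]
                    K[np.diag_indices_from(K)] -= prop - r[j]
                r[j] = prop
            if prof is not None:
                # Savage-Dickey ordinate of this ratio's conditional at zero,
                # all other parameters held at their current draws.
                log_zero[nm] = log_conditional_density_at_zero(
                    lambda g: prof.loglik(g, zres, state.sigma2),
                    upper=ub, grid_size=self.settings.bf_grid)
                loglik = prof.loglik(r[j], zres, state.sigma2)
        state.ratios = VarianceRatios(*r)
        return loglik, log_zero


def run_lmm_mcmc(y, design, kernels: CovarianceKernels,
                 settings: MCMCSettings = MCMCSettings()) -> Chain:
    """Run the full Metropolis-within-Gibbs chain for the linear model.

    ``design`` may be a DesignMatrices instance, a bare X matrix, or None
    (known zero mean).  Deterministic given ``settings.seed``.
    """
    y = np.asarray(y, dtype=float)
    X = getattr(design, "X", design)
    rng = np.random.default_rng(settings.seed)
    sampler = GaussianRatioSampler(X, kernels, settings, rng)
    state = sampler.initial_state(y)

    n_kept = settings.n_iter - settings.burnin
    kept_r = np.empty((n_kept, 3))
    kept_s2 = np.empty(n_kept)
    kept_beta = np.empty((n_kept, state.beta.size))
    kept_dev = np.empty(n_kept)
    logs = {nm: [] for nm in sampler.free}

    for it in range(settings.n_iter):
        adapting = it < settings.burnin
        k = it - settings.burnin
        want_bf = (settings.bf_stride > 0 and not adapting
                   and k % settings.bf_stride == 0)
        loglik, log_zero = sampler.sweep(y, state, adapting, want_bf)
        if not adapting:
            kept_r[k] = state.ratios.as_array()
            kept_s2[k] = state.sigma2
            kept_beta[k] = state.beta
            kept_dev[k] = -2.0 * loglik
            for nm, v in log_zero.items():
                logs[nm].append(v)

    return Chain(
        model="lmm",
        ratios=kept_r, sigma2=kept_s2, beta=kept_beta, deviance=kept_dev,
        log_zero_density={nm: np.array(v) for nm, v in logs.items()},
        n_kept=n_kept, n_burnin=settings.burnin, seed=settings.seed,
        accept_rates={nm: a.rate for nm, a in sampler.adapters.items()},
    )
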