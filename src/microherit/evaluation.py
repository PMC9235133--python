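"""Model evaluation: DIC and model choice, the Geweke convergence
diagnostic, and posterior summaries.

DIC = Dbar + pD with Dbar the posterior mean deviance and
pD = Dbar - D(theta-bar) the effective number of parameters.  The
deviance focus is conditional: for the linear model
D = -2 log MVN(y | X beta, V) with theta-bar the posterior means of
(beta, ratios, sigma2_P); for the zero-inflated Poisson model
D = -2 log ZIP(y | lambda*, p*) with theta-bar the posterior means of
(lambda*, p*).  The two models are compared at face value on their DIC,
the lower value winning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lmm import lmm_log_likelihood
from .priors import build_V

__all__ = ["DICResult", "compute_dic", "dic_from_chain", "select_model",
           "geweke_z", "spectral_variance", "posterior_summary"]


@dataclass(frozen=True)
class DICResult:
    dic: float
    dbar: float
    pd: float
    model: str


def compute_dic(deviance_trace, deviance_at_posterior_mean: float,
                model: str = "lmm") -> DICResult:
    """DIC from a deviance trace and the deviance at the posterior mean."""
    trace = np.asarray(deviance_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty deviance trace")
    if not (np.all(np.isfinite(trace)) and np.isfinite(deviance_at_posterior_mean)):
        raise ValueError("non-finite deviance values")
    dbar = float(trace.mean())
    pd = dbar - float(deviance_at_posterior_mean)
    return DICResult(dic=dbar + pd, dbar=dbar, pd=pd, model=model)


def dic_from_chain(chain, y, design, kernels) -> DICResult:
    """DIC of a fitted chain against its data."""
    X = getattr(design, "X", design)
    if chain.model == "lmm":
        beta, ratios, s2 = chain.posterior_mean_state()
        d_at_mean = -2.0 * lmm_log_likelihood(
            np.asarray(y, dtype=float), beta, build_V(ratios, s2, kernels), X)
    else:
        from .zipmodel import zip_log_likelihood

        d_at_mean = -2.0 * zip_log_likelihood(
            y, chain.lambda_star_mean, float(chain.p_star.mean()))
    return compute_dic(chain.deviance, d_at_mean, model=chain.model)


def select_model(dic_lmm: DICResult, dic_zip: DICResult) -> tuple[str, bool]:
    """Pick the lower-DIC model; returns ``(choice, tied)``; a numerical tie
    falls to the linear model."""
    delta = dic_lmm.dic - dic_zip.dic
    if abs(delta) < 1e-9:
        return "lmm", True
    return ("lmm", False) if delta < 0 else ("zip", False)


def spectral_variance(x: np.ndarray, window_frac: float = 0.04) -> float:
    """Spectral density of a chain segment at frequency zero, by
    Bartlett-tapered autocovariances over a ``window_frac`` lag window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    L = max(int(np.floor(window_frac * n)), 1)
    g0 = float(xc @ xc) / n
    s = g0
    for k in range(1, L + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gk
    return max(s, 0.0)


def geweke_z(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means.

    z = (mean_first - mean_last) / sqrt(s0_first/n_first + s0_last/n_last)
    with s0 the spectral density of the segment at zero.  Returns NaN for
    degenerate (zero-variance) segments.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic")
    if first_frac + last_frac > 1.0:
        raise ValueError("segments overlap")
    a = x[: int(first_frac * n)]
    b = x[n - int(last_frac * n):]
    va = spectral_variance(a) / a.size
    vb = spectral_variance(b) / b.size
    denom = va + vb
    if denom <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def posterior_summary(values, threshold: float = 0.10) -> tuple[float, float, float]:
    """Posterior mean, sample sd, and P(value > threshold) of a chain."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty chain")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd, float(np.mean(x > threshold))
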