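"""Savage-Dickey Bayes factors for null variance ratios.

For a nested point null (e.g. h2 = 0) the Bayes factor of the model WITH
the effect against the model without it is the prior ordinate over the
posterior ordinate at zero,

    BF = p(h2 = 0) / p(h2 = 0 | y),

with prior ordinate 3 from the Beta(1,3) marginal of the simplex prior.
The posterior ordinate is estimated from the MCMC output: at each kept
iteration the conditional density of the ratio (all other parameters at
their current draws) is normalized by numerical quadrature and evaluated
at zero; the per-iteration ordinates are then averaged on the log scale
with a max-shift (log-sum-exp) so that extremely small or large ordinates
neither underflow nor overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

#: Evidence thresholds for the numerator (effect) model.
SUBSTANTIAL, STRONG, DECISIVE = 3.2, 10.0, 100.0

EVIDENCE_LEVELS = ("none", "substantial", "strong", "decisive")


@dataclass(frozen=True)
class BFEntry:
    """Bayes factor for one variance ratio with its evidence classification."""

    bf: float
    reciprocal: float
    evidence: str
    null_supported: bool


def log_conditional_density_at_zero(
    log_f, upper: float, grid_size: int = 129
) -> float:
    """Log of the normalized conditional density at 0.

    ``log_f`` is a vectorized callable giving the unnormalized log density
    on [0, upper]; beyond ``upper`` (the moving simplex bound 1 minus the
    other two ratios) the density is zero, so normalizing the quadrature
    over [0, upper] is normalization over [0, 1].  Evaluation max-shifts
    the log values and integrates with Simpson's rule.
    """
    if not 0 < upper <= 1:
        raise ValueError("upper must be in (0, 1]")
    if grid_size < 16:
        raise ValueError("grid_size must be >= 16")
    grid = np.linspace(0.0, upper, grid_size)
    vals = np.asarray(log_f(grid), dtype=float)
    m = np.max(vals)
    if not np.isfinite(m):
        raise ValueError("log density non-finite over the whole grid")
    w = np.exp(vals - m)
    integral = simpson(w, x=grid)
    return float(vals[0] - m - np.log(integral))


def conditional_density_at_zero(log_f, upper: float, grid_size: int = 129) -> float:
    """Normalized conditional density at 0 (natural scale)."""
    return float(np.exp(log_conditional_density_at_zero(log_f, upper, grid_size)))


def average_density_at_zero(log_values: np.ndarray) -> float:
    """Max-shifted (log-sum-exp) arithmetic mean of per-iteration ordinates.

    Stable for log values near +/-700; ``-inf`` entries (zero ordinate)
    are allowed.
    """
    log_values = np.asarray(log_values, dtype=float)
    if log_values.size == 0:
        raise ValueError("no density evaluations supplied")
    m = np.max(log_values)
    if m == -np.inf:
        return 0.0
    return float(np.exp(np.log(np.mean(np.exp(log_values - m))) + m))


def compute_bf(mean_density_at_zero: float, prior_density_at_zero: float = 3.0) -> BFEntry:
    """Bayes factor from the averaged posterior ordinate at zero.

    Defaults to prior ordinate 3 (Beta(1,3) marginal of the three-ratio
    simplex prior); a reduced model with a different prior on the tested
    ratio passes its own ordinate.
    """
    if mean_density_at_zero < 0:
        raise ValueError("mean posterior density cannot be negative")
    bf = np.inf if mean_density_at_zero == 0 else prior_density_at_zero / mean_density_at_zero
    recip = 0.0 if np.isinf(bf) else 1.0 / bf
    return BFEntry(
        bf=float(bf),
        reciprocal=float(recip),
        evidence=classify_evidence(bf),
        null_supported=bool(recip > SUBSTANTIAL),
    )


def classify_evidence(bf: float) -> str:
    """Evidence category for the effect model: none / substantial (>=3.2) /
    strong (>=10) / decisive (>=100)."""
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if bf < SUBSTANTIAL:
        return "none"
    if bf < STRONG:
        return "substantial"
    if bf < DECISIVE:
        return "strong"
    return "decisive"


def chain_bayes_factors(chain, prior_density_at_zero: float = 3.0) -> dict[str, BFEntry]:
    """Savage-Dickey BFs for every free ratio of an MCMC chain."""
    out = {}
    for name, logs in chain.log_zero_density.items():
        mean = average_density_at_zero(logs)
        out[name] = compute_bf(mean, prior_density_at_zero)
    return out
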