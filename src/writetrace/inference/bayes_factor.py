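"""Savage-Dickey density-ratio Bayes factors for point nulls.

For a scalar effect with a proper prior, the Bayes factor in favour of a
non-zero effect is the ratio of prior to posterior density at zero:

    BF10 = p(effect = 0) / p(effect = 0 | data)

The posterior density at zero is estimated from MCMC draws with a Gaussian
kernel density (Scott plug-in bandwidth); the prior density is evaluated
analytically for a normal prior or by the same KDE on prior draws for
derived contrasts.  BF10 > 1 favours a non-zero effect (by the usual
convention, > 5 moderate and > 10 strong evidence); BF10 < 1 favours the
null.  Savage-Dickey ratios are prior-sensitive, so the prior enters the
result explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde, norm


def posterior_density_at(draws: np.ndarray, value: float = 0.0) -> float:
    """Gaussian-KDE estimate of the density of ``draws`` at ``value``.

    Returns 0.0 when no draw falls within 5 bandwidths of the value (the
    density is unestimable there; callers report the BF as a bound).
    """
    draws = np.asarray(draws, float)
    if draws.size < 10:
        raise ValueError("too few draws for a density estimate")
    if np.std(draws) == 0:
        return np.inf if draws[0] == value else 0.0
    kde = gaussian_kde(draws)
    bw = np.sqrt(float(kde.covariance.squeeze()))
    if np.min(np.abs(draws - value)) > 5 * bw:
        return 0.0
    return float(kde(value)[0])


def bayes_factor_savage_dickey(
    posterior_draws: np.ndarray,
    prior_sd: float | None = None,
    prior_draws: np.ndarray | None = None,
    at: float = 0.0,
) -> float:
    """BF10 for the point null ``effect = at``.

    Provide either ``prior_sd`` (zero-mean normal prior, evaluated
    analytically) or ``prior_draws`` (KDE on draws, for derived contrasts
    whose prior is not normal).  Returns ``inf`` when the posterior places
    no estimable mass at the null — evidence against the null beyond what
    the draws can quantify.
    """
    if (prior_sd is None) == (prior_draws is None):
        raise ValueError("provide exactly one of prior_sd or prior_draws")
    if prior_sd is not None:
        if not np.isfinite(prior_sd) or prior_sd <= 0:
            raise ValueError("prior must be proper: prior_sd must be finite and positive")
        prior_at = float(norm.pdf(at, 0.0, prior_sd))
    else:
        prior_at = posterior_density_at(np.asarray(prior_draws, float), at)
        if prior_at <= 0:
            raise ValueError("prior draws place no mass at the null; prior must be proper")
    post_at = posterior_density_at(np.asarray(posterior_draws, float), at)
    if post_at == 0.0:
        return np.inf
    return prior_at / post_at


def format_bf(bf: float, cap: float = 100.0) -> str:
    """Reporting convention: large Bayes factors are printed as '> cap'."""
    if bf > cap:
        return f"> {cap:g}"
    return f"{bf:.2f}"
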