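"""Scalar slice sampling and small MCMC utilities.

The hierarchical models in this package are sampled with Gibbs sweeps:
conjugate normal updates wherever the conditional is normal, and univariate
slice sampling (stepping-out then shrinkage) for every non-conjugate scalar.
Slice sampling needs no tuning beyond an initial width and is rejection-free,
which keeps the samplers robust across the model families used here.
"""

from __future__ import annotations

import numpy as np


def slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                 max_steps: int = 50, lower: float = -np.inf, upper: float = np.inf) -> float:
    """One update of a univariate slice sampler.

    ``logf`` is the log conditional density (up to a constant) of the scalar
    being updated; ``w`` the initial bracket width; ``lower``/``upper``
    hard support bounds.
    """
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise FloatingPointError(f"slice sampler started at zero density (x0={x0})")
    logy = f0 + np.log(rng.random())
    u = rng.random()
    left = x0 - u * w
    right = left + w
    j = int(np.floor(rng.random() * max_steps))
    k = max_steps - 1 - j
    while j > 0 and left > lower and logf(max(left, lower)) > logy:
        left -= w
        j -= 1
    while k > 0 and right < upper and logf(min(right, upper)) > logy:
        right += w
        k -= 1
    left = max(left, lower)
    right = min(right, upper)
    for _ in range(1000):
        x1 = left + rng.random() * (right - left)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pragma: no cover - numerically degenerate slice


def sample_truncated_normal(mean: float, sd: float, rng: np.random.Generator,
                            lower: float = 0.0) -> float:
    """Draw from N(mean, sd) truncated to (lower, inf) by inverse CDF."""
    from scipy.stats import norm

    a = norm.cdf((lower - mean) / sd)
    u = a + (1.0 - a) * rng.random()
    u = min(u, 1.0 - 1e-12)
    return mean + sd * float(norm.ppf(u))


def halfnormal_logpdf(x: float, sd: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / sd) ** 2


def chain_seeds(seed: int, chains: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(chains)]
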