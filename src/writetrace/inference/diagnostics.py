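"""Convergence checks shared by all model fits."""

from __future__ import annotations

import arviz as az
import numpy as np
import pandas as pd

from ..errors import ConvergenceError


def check_convergence(idata, var_names: list[str], rhat_threshold: float = 1.01,
                      min_ess: float = 100.0) -> pd.DataFrame:
    """Split-R-hat and bulk ESS for the reported parameters.

    Raises :class:`ConvergenceError` with the full diagnostic table when any
    reported parameter exceeds the R-hat threshold or falls below the ESS
    floor.  Single-chain fits skip the R-hat check (undefined).
    """
    rhat = az.rhat(idata, var_names=var_names)
    ess = az.ess(idata, var_names=var_names)
    rows = []
    for name in var_names:
        r = np.atleast_1d(np.asarray(rhat[name]))
        e = np.atleast_1d(np.asarray(ess[name]))
        for i, (ri, ei) in enumerate(zip(r.ravel(), e.ravel())):
            rows.append({"parameter": f"{name}[{i}]" if r.size > 1 else name,
                         "rhat": float(ri), "ess_bulk": float(ei)})
    report = pd.DataFrame(rows)
    n_chains = idata.posterior.sizes["chain"]
    bad_rhat = n_chains > 1 and (report["rhat"] > rhat_threshold).any()
    bad_ess = (report["ess_bulk"] < min_ess).any()
    if bad_rhat or bad_ess:
        worst = report.sort_values("rhat", ascending=False).head(8)
        raise ConvergenceError(
            "sampler did not converge "
            f"(max R-hat {report['rhat'].max():.4f}, min ESS {report['ess_bulk'].min():.0f}):\n"
            f"{worst.to_string(index=False)}",
            report=report,
        )
    return report


def quantile_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    lo = (1.0 - prob) / 2.0
    return float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo))
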