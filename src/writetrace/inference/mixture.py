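"""Two-component lognormal mixture for inter-keystroke intervals.

Each writing IKI is assumed to arise from one of two data-generating
processes.  When upstream planning keeps pace with output, the interval
reflects finger movement alone: the *fluent* component, whose log-location
is shared across languages and text locations but varies across participants
(typing motor skill).  When upstream processing lags, the interval belongs
to the *hesitation* component, modelled as the fluent log-location plus a
strictly positive, cell-specific shift.  On the log-millisecond scale, for
observation *i* with participant *p(i)* and cell *c(i)* (language x text
location):

    log y_i | z_i = 0  ~  Normal(mu_f + u_p,            sigma_f)
    log y_i | z_i = 1  ~  Normal(mu_f + u_p + delta_c,  sigma_h)
    z_i ~ Bernoulli(theta_cp),   logit(theta_cp) = alpha_c + b_p

with weakly-informative priors: mu_f ~ N(log 150, 0.5); log(delta_c) ~
N(0, 0.5), which keeps the shift strictly positive (preventing label
switching) and softly repelled from zero (preventing a degenerate
zero-separation mixture from absorbing fluent observations); alpha_c ~
N(0, 2.5); half-normal priors on the scales sigma_f, sigma_h and on the
random-effect SDs of u_p and b_p.  Configured and reported ms quantities are
the components' geometric means exp(mu); mixing proportions are reported at
b_p = 0 (a typical participant).

The posterior is sampled by Gibbs: the component indicators, mu_f and u_p
have conjugate normal conditionals; the shifts (on the log scale), the
scales and the logit-scale parameters are updated by univariate slice
sampling, with exact translation moves decorrelating each intercept from
its random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .diagnostics import check_convergence, quantile_interval
from .samplers import chain_seeds, halfnormal_logpdf, slice_sample


@dataclass
class MixtureSpec:
    """Priors and sampler settings for the IKI mixture."""

    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    mu_f_prior: tuple[float, float] = (np.log(150.0), 0.5)
    # prior on log(delta): strictly positive shift, softly repelled from
    # zero so a degenerate zero-separation mixture cannot absorb fluent data
    delta_log_prior: tuple[float, float] = (0.0, 0.5)
    alpha_prior_sd: float = 2.5
    sigma_prior_sd: float = 1.0
    tau_u_prior_sd: float = 0.5
    tau_b_prior_sd: float = 1.0
    rhat_threshold: float = 1.01
    min_ess: float = 100.0


@dataclass
class MixturePosterior:
    """Posterior draws of the mixture with ms-scale summaries."""

    idata: az.InferenceData
    cells: list[tuple[str, str]]  # (language, location)
    participants: list[str]
    spec: MixtureSpec
    diagnostics: pd.DataFrame | None = None

    def _draws(self, name: str) -> np.ndarray:
        return np.asarray(self.idata.posterior[name]).reshape(
            -1, *self.idata.posterior[name].shape[2:]
        )

    @property
    def fluent_ms(self) -> np.ndarray:
        """Draws of the fluent-component geometric mean, ms."""
        return np.exp(self._draws("mu_f"))

    def hesitation_ms(self, language: str, location: str) -> np.ndarray:
        c = self.cells.index((language, location))
        return np.exp(self._draws("mu_f") + self._draws("delta")[:, c])

    def theta(self, language: str, location: str) -> np.ndarray:
        c = self.cells.index((language, location))
        return expit(self._draws("alpha")[:, c])

    def cell_table(self, prob: float = 0.95) -> pd.DataFrame:
        """Estimated hesitation durations and proportions per cell."""
        rows = []
        for lang, loc in self.cells:
            dur = self.hesitation_ms(lang, loc)
            th = self.theta(lang, loc)
            dlo, dhi = quantile_interval(dur, prob)
            plo, phi = quantile_interval(th, prob)
            rows.append(
                {
                    "language": lang,
                    "location": loc,
                    "hesitation_ms": float(np.mean(dur)),
                    "hesitation_ms_lo": dlo,
                    "hesitation_ms_hi": dhi,
                    "proportion": float(np.mean(th)),
                    "proportion_lo": plo,
                    "proportion_hi": phi,
                }
            )
        out = pd.DataFrame(rows)
        flo, fhi = quantile_interval(self.fluent_ms, prob)
        out.attrs["fluent_ms"] = float(np.mean(self.fluent_ms))
        out.attrs["fluent_ms_interval"] = (flo, fhi)
        return out

    def language_effect(self, location: str, kind: str = "duration") -> np.ndarray:
        """L1 - L2 contrast draws for one location.

        ``duration``: difference of hesitation log-shifts (log scale);
        ``proportion``: difference of cell logits (logit scale).  With L2
        values larger than L1 the effect is negative.
        """
        c1 = self.cells.index(("L1", location))
        c2 = self.cells.index(("L2", location))
        name = "delta" if kind == "duration" else "alpha"
        d = self._draws(name)
        return d[:, c1] - d[:, c2]

    def prior_effect_draws(self, kind: str, n: int = 200_000, seed: int = 0) -> np.ndarray:
        """Draws of the same contrast under the prior (for Savage-Dickey)."""
        rng = np.random.default_rng(seed)
        if kind == "duration":
            m, s = self.spec.delta_log_prior
            a = np.exp(rng.normal(m, s, n))
            b = np.exp(rng.normal(m, s, n))
            return a - b
        sd = self.spec.alpha_prior_sd
        return rng.normal(0, sd, n) - rng.normal(0, sd, n)


def _prepare(transitions: pd.DataFrame):
    df = transitions
    y = np.log(df["iki"].to_numpy(float))
    participants = sorted(df["participant"].unique())
    cells = sorted({(l, loc) for l, loc in zip(df["language"], df["location"])})
    p_idx = df["participant"].map({p: i for i, p in enumerate(participants)}).to_numpy()
    c_idx = pd.Series(list(zip(df["language"], df["location"]))).map(
        {c: i for i, c in enumerate(cells)}
    ).to_numpy()
    return y, p_idx.astype(int), c_idx.astype(int), participants, cells


def fit_iki_mixture(
    transitions: pd.DataFrame, spec: MixtureSpec | None = None, check: bool = True
) -> MixturePosterior:
    """Fit the mixture to filtered, subsampled writing transitions.

    ``transitions`` needs columns participant, language, location, iki (ms).
    Raises :class:`~writetrace.errors.ConvergenceError` when split-R-hat or
    ESS of the reported parameters fail their thresholds (unless ``check``
    is disabled).
    """
    spec = spec or MixtureSpec()
    if (transitions["iki"] <= 0).any():
        raise ValueError("IKIs must be positive; filter the transitions first")
    y, p_idx, c_idx, participants, cells = _prepare(transitions)
    n = len(y)
    P, C = len(participants), len(cells)
    m0, s0 = spec.mu_f_prior

    store = {
        "mu_f": np.empty((spec.chains, spec.draws)),
        "sigma_f": np.empty((spec.chains, spec.draws)),
        "sigma_h": np.empty((spec.chains, spec.draws)),
        "tau_u": np.empty((spec.chains, spec.draws)),
        "tau_b": np.empty((spec.chains, spec.draws)),
        "delta": np.empty((spec.chains, spec.draws, C)),
        "alpha": np.empty((spec.chains, spec.draws, C)),
        "u": np.empty((spec.chains, spec.draws, P)),
        "b": np.empty((spec.chains, spec.draws, P)),
    }

    cp_index = c_idx * P + p_idx  # flat cell x participant index for counts
    n_cp = np.bincount(cp_index, minlength=C * P).reshape(C, P)

    for chain, rng in enumerate(chain_seeds(spec.seed, spec.chains)):
        mu_f = float(np.quantile(y, 0.3)) + rng.normal(0, 0.05)
        sigma_f, sigma_h = 0.3, 0.6
        tau_u, tau_b = 0.2, 0.5
        u = np.zeros(P)
        b = np.zeros(P)
        delta = np.full(C, 1.0)
        for c in range(C):
            cell_mean = np.mean(y[c_idx == c])
            delta[c] = max(cell_mean - mu_f, 0.2) + rng.normal(0, 0.05)
        alpha = np.zeros(C)
        z = (y > mu_f + 0.5 * delta[c_idx]).astype(int)

        for it in range(spec.warmup + spec.draws):
            # --- component indicators -----------------------------------
            eta_i = alpha[c_idx] + b[p_idx]
            mean_f = mu_f + u[p_idx]
            lp1 = (
                log_expit(eta_i)
                - np.log(sigma_h)
                - 0.5 * ((y - mean_f - delta[c_idx]) / sigma_h) ** 2
            )
            lp0 = log_expit(-eta_i) - np.log(sigma_f) - 0.5 * ((y - mean_f) / sigma_f) ** 2
            z = (rng.random(n) < expit(lp1 - lp0)).astype(int)
            zb = z.astype(bool)
            w = np.where(zb, sigma_h**-2, sigma_f**-2)

            # --- fluent location and participant offsets (conjugate) ----
            r = y - u[p_idx] - delta[c_idx] * z
            prec = 1.0 / s0**2 + w.sum()
            mean = (m0 / s0**2 + (w * r).sum()) / prec
            mu_f = mean + rng.normal() / np.sqrt(prec)

            r = y - mu_f - delta[c_idx] * z
            sw = np.bincount(p_idx, weights=w, minlength=P)
            swr = np.bincount(p_idx, weights=w * r, minlength=P)
            prec_u = 1.0 / tau_u**2 + sw
            u = swr / prec_u + rng.normal(size=P) / np.sqrt(prec_u)

            # --- hesitation shifts (slice on the log scale) -------------
            r_h = y - mu_f - u[p_idx]
            m_d, s_d = spec.delta_log_prior
            for c in range(C):
                m = zb & (c_idx == c)
                nz = int(m.sum())
                rsum = float(r_h[m].sum())
                rsq = float((r_h[m] ** 2).sum())

                def logf_logdelta(d, nz=nz, rsum=rsum, rsq=rsq):
                    dd = np.exp(d)
                    sse = rsq - 2 * dd * rsum + nz * dd * dd
                    return -sse / (2 * sigma_h**2) - 0.5 * ((d - m_d) / s_d) ** 2

                delta[c] = np.exp(
                    slice_sample(logf_logdelta, float(np.log(delta[c])), rng, w=0.3)
                )

            # --- component scales (slice) -------------------------------
            res_f = y - mu_f - u[p_idx]
            sse_f = float((res_f[~zb] ** 2).sum())
            n_f = int((~zb).sum())
            sse_h = float(((res_f - delta[c_idx])[zb] ** 2).sum())
            n_h = int(zb.sum())

            def make_scale_logf(sse, cnt):
                def logf(s):
                    if s <= 0:
                        return -np.inf
                    return -cnt * np.log(s) - sse / (2 * s * s) + halfnormal_logpdf(s, spec.sigma_prior_sd)

                return logf

            sigma_f = slice_sample(make_scale_logf(sse_f, n_f), sigma_f, rng, w=0.05, lower=1e-3)
            sigma_h = slice_sample(make_scale_logf(sse_h, n_h), sigma_h, rng, w=0.1, lower=1e-3)

            def tau_logf_factory(vec, prior_sd):
                ss = float((vec**2).sum())
                k = len(vec)

                def logf(t):
                    if t <= 0:
                        return -np.inf
                    return -k * np.log(t) - ss / (2 * t * t) + halfnormal_logpdf(t, prior_sd)

                return logf

            tau_u = slice_sample(tau_logf_factory(u, spec.tau_u_prior_sd), tau_u, rng, w=0.05, lower=1e-4)

            # translation move: shift mass between mu_f and the participant
            # offsets (likelihood depends only on their sum, so the shift has
            # an exact Gaussian conditional); decorrelates the two blocks
            prec_s = 1.0 / s0**2 + P / tau_u**2
            mean_s = ((m0 - mu_f) / s0**2 + u.sum() / tau_u**2) / prec_s
            shift = mean_s + rng.normal() / np.sqrt(prec_s)
            mu_f += shift
            u -= shift

            # --- mixing proportions (slice on logits) -------------------
            k_cp = np.bincount(cp_index, weights=z.astype(float), minlength=C * P).reshape(C, P)
            for c in range(C):
                kc, nc = k_cp[c], n_cp[c]

                def logf_alpha(a, kc=kc, nc=nc):
                    eta = a + b
                    return float(
                        (kc * log_expit(eta) + (nc - kc) * log_expit(-eta)).sum()
                        - 0.5 * (a / spec.alpha_prior_sd) ** 2
                    )

                alpha[c] = slice_sample(logf_alpha, alpha[c], rng, w=0.5)
            for p in range(P):
                kp, np_ = k_cp[:, p], n_cp[:, p]

                def logf_b(x, kp=kp, np_=np_):
                    eta = alpha + x
                    return float(
                        (kp * log_expit(eta) + (np_ - kp) * log_expit(-eta)).sum()
                        - 0.5 * (x / tau_b) ** 2
                    )

                b[p] = slice_sample(logf_b, b[p], rng, w=0.5)
            tau_b = slice_sample(tau_logf_factory(b, spec.tau_b_prior_sd), tau_b, rng, w=0.1, lower=1e-4)

            # matching translation move for the logit intercepts and the
            # by-participant mixing-proportion offsets
            prec_t = C / spec.alpha_prior_sd**2 + P / tau_b**2
            mean_t = (-alpha.sum() / spec.alpha_prior_sd**2 + b.sum() / tau_b**2) / prec_t
            shift_t = mean_t + rng.normal() / np.sqrt(prec_t)
            alpha += shift_t
            b -= shift_t

            if it >= spec.warmup:
                j = it - spec.warmup
                store["mu_f"][chain, j] = mu_f
                store["sigma_f"][chain, j] = sigma_f
                store["sigma_h"][chain, j] = sigma_h
                store["tau_u"][chain, j] = tau_u
                store["tau_b"][chain, j] = tau_b
                store["delta"][chain, j] = delta
                store["alpha"][chain, j] = alpha
                store["u"][chain, j] = u
                store["b"][chain, j] = b

    idata = az.from_dict(posterior=store)
    post = MixturePosterior(idata=idata, cells=cells, participants=participants, spec=spec)
    if check:
        post.diagnostics = check_convergence(
            idata,
            ["mu_f", "sigma_f", "sigma_h", "delta", "alpha"],
            rhat_threshold=spec.rhat_threshold,
            min_ess=spec.min_ess,
        )
    return post
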