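"""Bayesian mixed-effects models for editing rates and lookback metrics.

One engine covers the response families used downstream of the transition
and lookback tables: binomial (editing and lookback probabilities),
lognormal (lookback durations), negative binomial (words fixated, lookback
depth), Poisson (dispersion-limit checks) and normal (standardized text
measures).  All models share the fixed-effect structure

    eta = b0 + b_lang * lang + location contrasts (+ language interactions)
          + u0[participant] + lang * u1[participant]

with language sum-coded L1 = +1/2, L2 = -1/2 (so a measure that is larger in
L2 gets a negative language effect) and two location contrasts: pre-sentence
vs pre-word, and within-word vs before-word-or-sentence.  Priors are
weakly-informative: Normal(0, 1) on effects, Normal(0, 10) on the intercept,
half-normal on random-effect SDs and residual scales, and a wide normal on
the log of the negative-binomial dispersion.  Sampling is slice-within-Gibbs
(see :mod:`.samplers`); lognormal and negative-binomial cell estimates are
reported on the exp(eta) (geometric-mean / mean-count) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .diagnostics import check_convergence, quantile_interval
from .samplers import chain_seeds, halfnormal_logpdf, slice_sample

FAMILIES = ("binomial", "lognormal", "negbinomial", "poisson", "normal")

_LOC_ORDER = ("pre-sentence", "pre-word", "within-word")


@dataclass
class GlmmSpec:
    """Sampler settings and priors for the mixed-effects engine."""

    family: str = "binomial"
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    intercept_prior_sd: float = 10.0
    effect_prior_sd: float = 1.0
    re_sd_prior: float = 1.0
    sigma_prior_sd: float = 1.0
    log_phi_prior: tuple[float, float] = (2.0, 2.0)
    include_lang_slope: bool = True
    rhat_threshold: float = 1.01
    min_ess: float = 100.0


def _lang_code(lang: pd.Series) -> np.ndarray:
    return np.where(lang.to_numpy() == "L1", 0.5, -0.5)


def _contrast_columns(location: pd.Series, contrasts: str):
    loc = location.to_numpy()
    if contrasts == "full":
        c1 = np.select([loc == "pre-sentence", loc == "pre-word"], [0.5, -0.5], 0.0)
        c2 = np.where(loc == "within-word", 2.0 / 3.0, -1.0 / 3.0)
        return [("presentence_vs_preword", c1), ("within_vs_before", c2)]
    if contrasts == "word_within":
        cw = np.where(loc == "within-word", 0.5, -0.5)
        return [("within_vs_preword", cw)]
    if contrasts == "sentence_word":
        cs = np.where(loc == "pre-sentence", 0.5, -0.5)
        return [("presentence_vs_other", cs)]
    if contrasts == "none":
        return []
    raise ValueError(f"unknown contrast scheme {contrasts!r}")


def build_design(df: pd.DataFrame, contrasts: str = "full", interactions: bool = True):
    """Fixed-effect design matrix and column names for one model."""
    lang = _lang_code(df["language"])
    cols = [("intercept", np.ones(len(df))), ("lang", lang)]
    if "location" in df.columns and contrasts != "none":
        ccols = _contrast_columns(df["location"], contrasts)
        cols.extend(ccols)
        if interactions:
            cols.extend((f"lang_x_{name}", lang * c) for name, c in ccols)
    names = [n for n, _ in cols]
    X = np.column_stack([c for _, c in cols])
    return X, names


class _Likelihood:
    """Vectorized log likelihood with cheap row-subset evaluation."""

    def __init__(self, family: str, df: pd.DataFrame):
        self.family = family
        if family == "binomial":
            self.k = df["successes"].to_numpy(float)
            self.m = df["trials"].to_numpy(float)
        elif family == "lognormal":
            y = df["y"].to_numpy(float)
            self.w = np.log(y)
        elif family == "normal":
            self.w = df["y"].to_numpy(float)
        elif family in ("negbinomial", "poisson"):
            self.y = df["y"].to_numpy(float)
        else:
            raise ValueError(f"unknown family {family!r}")

    def rows(self, idx, eta: np.ndarray, extra: dict) -> float:
        f = self.family
        if f == "binomial":
            k, m = self.k[idx], self.m[idx]
            return float((k * eta - m * np.logaddexp(0.0, eta)).sum())
        if f in ("lognormal", "normal"):
            w = self.w[idx]
            s = extra["sigma"]
            return float(-len(w) * np.log(s) - ((w - eta) ** 2).sum() / (2 * s * s))
        if f == "negbinomial":
            y = self.y[idx]
            phi = np.exp(extra["log_phi"])
            return float(
                (
                    gammaln(y + phi)
                    - gammaln(phi)
                    + phi * np.log(phi)
                    + y * eta
                    - (y + phi) * np.log(phi + np.exp(eta))
                ).sum()
            )
        y = self.y[idx]
        return float((y * eta - np.exp(eta)).sum())

    def full(self, eta: np.ndarray, extra: dict) -> float:
        return self.rows(slice(None), eta, extra)


@dataclass
class GlmmPosterior:
    """Posterior draws plus helpers mirroring the reported tables."""

    idata: az.InferenceData
    names: list[str]
    family: str
    spec: GlmmSpec
    cells: list[tuple[str, str | None]]
    cell_design: np.ndarray
    diagnostics: pd.DataFrame | None = None

    def _beta(self) -> np.ndarray:
        return np.asarray(self.idata.posterior["beta"]).reshape(-1, len(self.names))

    def effect_draws(self, name: str) -> np.ndarray:
        return self._beta()[:, self.names.index(name)]

    def cell_eta(self, language: str, location: str | None = None) -> np.ndarray:
        i = self.cells.index((language, location))
        return self._beta() @ self.cell_design[i]

    def cell_estimate(self, language: str, location: str | None = None) -> np.ndarray:
        """Cell summaries on the response scale for a typical participant."""
        eta = self.cell_eta(language, location)
        if self.family == "binomial":
            return expit(eta)
        if self.family in ("lognormal", "negbinomial", "poisson"):
            return np.exp(eta)
        return eta

    def cell_table(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        for lang, loc in self.cells:
            d = self.cell_estimate(lang, loc)
            lo, hi = quantile_interval(d, prob)
            rows.append(
                {"language": lang, "location": loc, "estimate": float(np.mean(d)), "lo": lo, "hi": hi}
            )
        return pd.DataFrame(rows)

    def effect_table(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in self.names:
            d = self.effect_draws(name)
            lo, hi = quantile_interval(d, prob)
            rows.append({"effect": name, "estimate": float(np.mean(d)), "lo": lo, "hi": hi})
        return pd.DataFrame(rows)


def fit_glmm(
    df: pd.DataFrame,
    spec: GlmmSpec,
    contrasts: str = "full",
    interactions: bool = True,
    check: bool = True,
) -> GlmmPosterior:
    """Fit one mixed-effects model by slice-within-Gibbs.

    ``df`` must carry participant and language columns, a location column
    unless ``contrasts='none'``, and the response (``successes``/``trials``
    for binomial, ``y`` otherwise).
    """
    if spec.family not in FAMILIES:
        raise ValueError(f"unknown family {spec.family!r}")
    df = df.reset_index(drop=True)
    X, names = build_design(df, contrasts=contrasts, interactions=interactions)
    K = X.shape[1]
    participants = sorted(df["participant"].unique())
    P = len(participants)
    p_idx = df["participant"].map({p: i for i, p in enumerate(participants)}).to_numpy()
    lang = _lang_code(df["language"])
    lik = _Likelihood(spec.family, df)
    rows_of = [np.flatnonzero(p_idx == p) for p in range(P)]

    # When every language x location cell is observed the fixed-effect design
    # is square, and sampling the cell means (whose likelihood terms are
    # disjoint) instead of the effects removes the posterior correlations
    # between contrasts and interactions; the effect priors transform to a
    # Gaussian with cross-terms in the cell-mean basis.
    combos_pre, Xc_pre = _cell_designs(df, names, contrasts, interactions)
    gamma_mode = Xc_pre.shape[0] == K and abs(np.linalg.det(Xc_pre)) > 1e-8
    if gamma_mode:
        Tmat = Xc_pre
        Tinv = np.linalg.inv(Tmat)
        if "location" in df.columns and contrasts != "none":
            cell_key = list(zip(df["language"], df["location"]))
        else:
            cell_key = [(l, None) for l in df["language"]]
        cell_of_row = np.array([combos_pre.index(k) for k in cell_key])
        rows_of_cell = [np.flatnonzero(cell_of_row == c) for c in range(K)]

    has_sigma = spec.family in ("lognormal", "normal")
    has_phi = spec.family == "negbinomial"
    use_slope = spec.include_lang_slope

    store = {
        "beta": np.empty((spec.chains, spec.draws, K)),
        "tau0": np.empty((spec.chains, spec.draws)),
        "u0": np.empty((spec.chains, spec.draws, P)),
    }
    if use_slope:
        store["tau1"] = np.empty((spec.chains, spec.draws))
        store["u1"] = np.empty((spec.chains, spec.draws, P))
    if has_sigma:
        store["sigma"] = np.empty((spec.chains, spec.draws))
    if has_phi:
        store["log_phi"] = np.empty((spec.chains, spec.draws))

    prior_sd = np.full(K, spec.effect_prior_sd)
    prior_sd[0] = spec.intercept_prior_sd

    if gamma_mode:
        # prior precision of the cell means implied by the effect priors
        Qprior = Tinv.T @ np.diag(1.0 / prior_sd**2) @ Tinv

    for chain, rng in enumerate(chain_seeds(spec.seed, spec.chains)):
        beta = np.zeros(K)
        beta[0] = _init_intercept(spec.family, df)
        u0 = np.zeros(P)
        u1 = np.zeros(P)
        tau0 = tau1 = 0.3
        extra = {"sigma": 0.5, "log_phi": 2.0}
        gamma = Tmat @ beta if gamma_mode else None

        def eta_full():
            e = (gamma[cell_of_row] if gamma_mode else X @ beta) + u0[p_idx]
            if use_slope:
                e = e + lang * u1[p_idx]
            return e

        for it in range(spec.warmup + spec.draws):
            eta = eta_full()
            if gamma_mode:
                for c in range(K):
                    rws = rows_of_cell[c]
                    base = eta[rws] - gamma[c]
                    cross = float(Qprior[c] @ gamma - Qprior[c, c] * gamma[c])

                    def logf(x, c=c, rws=rws, base=base, cross=cross):
                        return (
                            lik.rows(rws, base + x, extra)
                            - 0.5 * Qprior[c, c] * x * x
                            - cross * x
                        )

                    gamma[c] = slice_sample(logf, gamma[c], rng, w=0.5)
                    eta[rws] = base + gamma[c]
                beta = Tinv @ gamma
            else:
                for j in range(K):
                    base = eta - X[:, j] * beta[j]

                    def logf(x, j=j, base=base):
                        return lik.full(base + X[:, j] * x, extra) - 0.5 * (x / prior_sd[j]) ** 2

                    beta[j] = slice_sample(logf, beta[j], rng, w=0.5)
                    eta = base + X[:, j] * beta[j]
            for p in range(P):
                rws = rows_of[p]
                base = eta[rws] - u0[p]

                def logf(x, rws=rws, base=base):
                    return lik.rows(rws, base + x, extra) - 0.5 * (x / tau0) ** 2

                u0[p] = slice_sample(logf, u0[p], rng, w=0.3)
                eta[rws] = base + u0[p]
            tau0 = slice_sample(_tau_logf(u0, spec.re_sd_prior), tau0, rng, w=0.1, lower=1e-4)
            # interweaved non-centered update: rescale the offsets with their
            # standardized values held fixed, so tau0 can move even when the
            # offsets sit near zero (breaks the funnel)
            z0 = u0 / tau0
            eta_no_u0 = eta - u0[p_idx]

            def logf_tau_nc(t, z0=z0, eta_no_u0=eta_no_u0):
                if t <= 0:
                    return -np.inf
                return lik.full(eta_no_u0 + t * z0[p_idx], extra) + halfnormal_logpdf(
                    t, spec.re_sd_prior
                )

            tau0 = slice_sample(logf_tau_nc, tau0, rng, w=0.1, lower=1e-4)
            u0 = tau0 * z0
            eta = eta_no_u0 + u0[p_idx]
            # translation move between the intercept and the participant
            # offsets: the likelihood sees only their sum, so the shift has
            # an exact Gaussian conditional and decorrelates the blocks
            prec_s = 1.0 / prior_sd[0] ** 2 + P / tau0**2
            mean_s = (-beta[0] / prior_sd[0] ** 2 + u0.sum() / tau0**2) / prec_s
            shift = mean_s + rng.normal() / np.sqrt(prec_s)
            beta[0] += shift
            u0 -= shift
            if gamma_mode:
                gamma += shift * Tmat[:, 0]
            if use_slope:
                for p in range(P):
                    rws = rows_of[p]
                    xl = lang[rws]
                    base = eta[rws] - xl * u1[p]

                    def logf(x, rws=rws, base=base, xl=xl):
                        return lik.rows(rws, base + xl * x, extra) - 0.5 * (x / tau1) ** 2

                    u1[p] = slice_sample(logf, u1[p], rng, w=0.3)
                    eta[rws] = base + xl * u1[p]
                tau1 = slice_sample(_tau_logf(u1, spec.re_sd_prior), tau1, rng, w=0.1, lower=1e-4)
                z1 = u1 / tau1
                eta_no_u1 = eta - lang * u1[p_idx]

                def logf_tau1_nc(t, z1=z1, eta_no_u1=eta_no_u1):
                    if t <= 0:
                        return -np.inf
                    return lik.full(eta_no_u1 + lang * (t * z1[p_idx]), extra) + halfnormal_logpdf(
                        t, spec.re_sd_prior
                    )

                tau1 = slice_sample(logf_tau1_nc, tau1, rng, w=0.1, lower=1e-4)
                u1 = tau1 * z1
                eta = eta_no_u1 + lang * u1[p_idx]
                j_lang = names.index("lang")
                prec_s = 1.0 / prior_sd[j_lang] ** 2 + P / tau1**2
                mean_s = (-beta[j_lang] / prior_sd[j_lang] ** 2 + u1.sum() / tau1**2) / prec_s
                shift = mean_s + rng.normal() / np.sqrt(prec_s)
                beta[j_lang] += shift
                u1 -= shift
                if gamma_mode:
                    gamma += shift * Tmat[:, j_lang]
            if has_sigma:
                sse = float(((lik.w - eta) ** 2).sum())
                n_obs = len(lik.w)

                def logf_sigma(s):
                    if s <= 0:
                        return -np.inf
                    return (
                        -n_obs * np.log(s)
                        - sse / (2 * s * s)
                        + halfnormal_logpdf(s, spec.sigma_prior_sd)
                    )

                extra["sigma"] = slice_sample(logf_sigma, extra["sigma"], rng, w=0.05, lower=1e-4)
            if has_phi:
                m_lp, s_lp = spec.log_phi_prior

                def logf_phi(x, eta=eta):
                    return lik.full(eta, {"log_phi": x}) - 0.5 * ((x - m_lp) / s_lp) ** 2

                extra["log_phi"] = slice_sample(logf_phi, extra["log_phi"], rng, w=0.3)

            if it >= spec.warmup:
                jd = it - spec.warmup
                store["beta"][chain, jd] = beta
                store["tau0"][chain, jd] = tau0
                store["u0"][chain, jd] = u0
                if use_slope:
                    store["tau1"][chain, jd] = tau1
                    store["u1"][chain, jd] = u1
                if has_sigma:
                    store["sigma"][chain, jd] = extra["sigma"]
                if has_phi:
                    store["log_phi"][chain, jd] = extra["log_phi"]

    idata = az.from_dict(posterior=store)
    cells, cell_design = _cell_designs(df, names, contrasts, interactions)
    post = GlmmPosterior(
        idata=idata,
        names=names,
        family=spec.family,
        spec=spec,
        cells=cells,
        cell_design=cell_design,
    )
    if check:
        post.diagnostics = check_convergence(
            idata, ["beta", "tau0"], rhat_threshold=spec.rhat_threshold, min_ess=spec.min_ess
        )
    return post


def _init_intercept(family: str, df: pd.DataFrame) -> float:
    if family == "binomial":
        p = df["successes"].sum() / max(df["trials"].sum(), 1)
        p = min(max(p, 1e-3), 1 - 1e-3)
        return float(np.log(p / (1 - p)))
    if family == "lognormal":
        return float(np.log(df["y"]).mean())
    if family in ("negbinomial", "poisson"):
        return float(np.log(max(df["y"].mean(), 0.1)))
    return float(df["y"].mean())


def _tau_logf(vec: np.ndarray, prior_sd: float):
    ss = float((vec**2).sum())
    k = len(vec)

    def logf(t):
        if t <= 0:
            return -np.inf
        return -k * np.log(t) - ss / (2 * t * t) + halfnormal_logpdf(t, prior_sd)

    return logf


def _cell_designs(df: pd.DataFrame, names, contrasts, interactions):
    if "location" in df.columns and contrasts != "none":
        combos = sorted(
            {(l, loc) for l, loc in zip(df["language"], df["location"])},
            key=lambda t: (t[0], _LOC_ORDER.index(t[1]) if t[1] in _LOC_ORDER else 9),
        )
        cell_df = pd.DataFrame(combos, columns=["language", "location"])
    else:
        combos = [(l, None) for l in sorted(df["language"].unique())]
        cell_df = pd.DataFrame({"language": [l for l, _ in combos]})
    Xc, names_c = build_design(cell_df, contrasts=contrasts, interactions=interactions)
    assert names_c == names
    return combos, Xc


# ---------------------------------------------------------------------------
# Named fits mirroring the reported analyses


def fit_binomial(df: pd.DataFrame, spec: GlmmSpec | None = None, **kw) -> GlmmPosterior:
    """Editing or lookback probability per cell (successes/trials rows)."""
    spec = spec or GlmmSpec(family="binomial")
    if spec.family != "binomial":
        raise ValueError("spec.family must be 'binomial'")
    return fit_glmm(df, spec, **kw)


def fit_lognormal_lmm(df: pd.DataFrame, spec: GlmmSpec | None = None, **kw) -> GlmmPosterior:
    """Lookback durations: unimodal lognormal mixed model."""
    spec = spec or GlmmSpec(family="lognormal")
    if spec.family != "lognormal":
        raise ValueError("spec.family must be 'lognormal'")
    if (df["y"] <= 0).any():
        raise ValueError("lognormal responses must be positive")
    if df["y"].nunique() == 1:
        raise ValueError("degenerate response: all durations identical")
    return fit_glmm(df, spec, **kw)


def fit_negbinomial(df: pd.DataFrame, spec: GlmmSpec | None = None, **kw) -> GlmmPosterior:
    """Counts (words fixated, lookback depth) as a negative binomial."""
    spec = spec or GlmmSpec(family="negbinomial")
    if spec.family != "negbinomial":
        raise ValueError("spec.family must be 'negbinomial'")
    return fit_glmm(df, spec, **kw)


def fit_poisson(df: pd.DataFrame, spec: GlmmSpec | None = None, **kw) -> GlmmPosterior:
    spec = spec or GlmmSpec(family="poisson")
    return fit_glmm(df, spec, **kw)


def fit_multivariate_text_model(
    measures: pd.DataFrame,
    spec: GlmmSpec | None = None,
    log_transform: bool = True,
    standardize: bool = True,
    check: bool = True,
) -> dict[str, GlmmPosterior]:
    """Language effects on the text measures, one standardized model each.

    ``measures`` is long format: participant, language, measure, value.
    Positive measures are log-scaled, then z-scored within measure, so the
    language coefficient is a standardized effect.  Each measure gets a
    normal model with participant random intercepts (one text per
    participant and language, so no by-participant language slope is
    identifiable).
    """
    out: dict[str, GlmmPosterior] = {}
    for name, sub in measures.groupby("measure", sort=True):
        v = sub["value"].to_numpy(float)
        if log_transform:
            if (v <= 0).any():
                raise ValueError(f"measure {name!r} has non-positive values; disable log_transform")
            v = np.log(v)
        if standardize:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"measure {name!r} is constant")
            v = (v - v.mean()) / sd
        sub = sub.assign(y=v)
        base = spec.__dict__ if spec is not None else {}
        mspec = GlmmSpec(**{**base, "family": "normal", "include_lang_slope": False})
        out[name] = fit_glmm(sub, mspec, contrasts="none", check=check)
    return out
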