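import numpy as np
import pandas as pd
import pytest

from writetrace.inference import (
    GlmmSpec,
    build_design,
    fit_binomial,
    fit_lognormal_lmm,
    fit_multivariate_text_model,
    fit_negbinomial,
    fit_poisson,
)
from writetrace.synthetic import simulate_lognormal_cells, simulate_negbinomial_cells

SMALL = dict(chains=2, draws=300, warmup=300)

LOCS = ("pre-sentence", "pre-word", "within-word")


def cell_frame(values):
    rows = []
    for (loc, lang), v in values.items():
        rows.append({"language": lang, "location": loc, "value": v})
    return pd.DataFrame(rows)


class TestDesign:
    def test_contrast_coding(self):
        df = pd.DataFrame(
            {"language": ["L1", "L2", "L1"], "location": ["pre-sentence", "pre-word", "within-word"]}
        )
        X, names = build_design(df)
        assert names == [
            "intercept", "lang", "presentence_vs_preword", "within_vs_before",
            "lang_x_presentence_vs_preword", "lang_x_within_vs_before",
        ]
        assert X[0, 1] == 0.5 and X[1, 1] == -0.5  # L1 positive: L2-larger => negative effect
        assert X[0, 2] == 0.5 and X[1, 2] == -0.5 and X[2, 2] == 0.0
        assert X[2, 3] == pytest.approx(2 / 3)

    def test_word_within_scheme(self):
        df = pd.DataFrame({"language": ["L1", "L1"], "location": ["pre-word", "within-word"]})
        X, names = build_design(df, contrasts="word_within")
        assert names == ["intercept", "lang", "within_vs_preword", "lang_x_within_vs_preword"]


class TestBinomial:
    def test_all_zero_successes_estimates_near_zero(self):
        rows = [
            {"participant": f"p{p:02d}", "language": lang, "location": loc,
             "successes": 0, "trials": 50}
            for p in range(8) for lang in ("L1", "L2") for loc in LOCS
        ]
        post = fit_binomial(pd.DataFrame(rows), GlmmSpec(family="binomial", seed=1, **SMALL),
                            check=False)
        table = post.cell_table()
        assert (table["estimate"] < 0.05).all()
        assert (table["hi"] < 0.2).all()  # the prior bounds the interval


class TestLognormal:
    def test_scale_equivariance(self):
        meds = {(loc, lang): m for (loc, lang), m in zip(
            [(l, g) for l in LOCS for g in ("L1", "L2")], [1900, 2700, 1150, 1420, 800, 1000])}
        df = simulate_lognormal_cells(meds, n_per_cell=6, n_participants=10, seed=3)
        spec = GlmmSpec(family="lognormal", seed=2, **SMALL)
        post = fit_lognormal_lmm(df, spec, check=False)
        post_scaled = fit_lognormal_lmm(df.assign(y=df["y"] * 10), spec, check=False)
        for lang, loc in post.cells:
            a = np.log(post.cell_estimate(lang, loc)).mean()
            b = np.log(post_scaled.cell_estimate(lang, loc)).mean()
            assert b - a == pytest.approx(np.log(10), abs=0.1)

    def test_degenerate_input_rejected(self):
        df = pd.DataFrame(
            {"participant": ["p0"] * 4, "language": ["L1", "L1", "L2", "L2"],
             "location": ["pre-word"] * 4, "y": [500.0] * 4}
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_lognormal_lmm(df)
        with pytest.raises(ValueError, match="positive"):
            fit_lognormal_lmm(df.assign(y=[1.0, 2.0, 3.0, -1.0]))


class TestNegativeBinomial:
    def test_poisson_limit_agrees_with_poisson_fit(self):
        rng = np.random.default_rng(11)
        means = {("pre-word", "L1"): 4.0, ("pre-word", "L2"): 5.0,
                 ("within-word", "L1"): 2.5, ("within-word", "L2"): 2.6}
        rows = []
        for (loc, lang), mu in means.items():
            for p in range(10):
                for y in rng.poisson(mu, 12):
                    rows.append({"participant": f"p{p:02d}", "language": lang,
                                 "location": loc, "y": int(y)})
        df = pd.DataFrame(rows)
        nb = fit_negbinomial(df, GlmmSpec(family="negbinomial", seed=4, **SMALL),
                             contrasts="word_within", check=False)
        po = fit_poisson(df, GlmmSpec(family="poisson", seed=4, **SMALL),
                         contrasts="word_within", check=False)
        for lang, loc in nb.cells:
            a = nb.cell_estimate(lang, loc).mean()
            b = po.cell_estimate(lang, loc).mean()
            assert a == pytest.approx(b, rel=0.1)
        # with no overdispersion the fitted dispersion runs large
        assert np.exp(np.asarray(nb.idata.posterior["log_phi"])).mean() > 5

    def test_equal_counts_give_near_zero_effects(self):
        rows = [
            {"participant": f"p{p:02d}", "language": lang, "location": loc, "y": 3}
            for p in range(8) for lang in ("L1", "L2") for loc in ("pre-word", "within-word")
        ]
        post = fit_negbinomial(pd.DataFrame(rows), GlmmSpec(family="negbinomial", seed=5, **SMALL),
                               contrasts="word_within", check=False)
        eff = post.effect_table()
        non_intercept = eff[eff["effect"] != "intercept"]
        assert (non_intercept["estimate"].abs() < 0.15).all()


class TestTextModel:
    def _measures(self, rng, shift=0.0):
        rows = []
        for p in range(15):
            base = rng.normal(0, 0.3)
            for lang, code in (("L1", 0.5), ("L2", -0.5)):
                rows.append({"participant": f"p{p:02d}", "language": lang,
                             "measure": "word_count", "value": rng.normal(code * shift + base, 1.0)})
        return pd.DataFrame(rows)

    def test_identical_distributions_straddle_zero(self):
        rng = np.random.default_rng(21)
        fits = fit_multivariate_text_model(
            self._measures(rng), GlmmSpec(family="normal", seed=6, **SMALL),
            log_transform=False, standardize=False, check=False,
        )
        d = fits["word_count"].effect_draws("lang")
        lo, hi = np.quantile(d, [0.025, 0.975])
        assert lo < 0 < hi

    def test_measure_order_does_not_change_results(self):
        rng = np.random.default_rng(22)
        df = self._measures(rng)
        df2 = df.assign(measure="aaa_first")
        both = pd.concat([df, df2], ignore_index=True)
        fits = fit_multivariate_text_model(
            both, GlmmSpec(family="normal", seed=6, **SMALL),
            log_transform=False, standardize=False, check=False,
        )
        fits_rev = fit_multivariate_text_model(
            both.iloc[::-1].reset_index(drop=True), GlmmSpec(family="normal", seed=6, **SMALL),
            log_transform=False, standardize=False, check=False,
        )
        for k in fits:
            assert np.allclose(fits[k].effect_draws("lang"), fits_rev[k].effect_draws("lang"))
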