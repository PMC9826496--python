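import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from multistress.meta import (
    AsymmetryAccuracyGLM,
    MultilevelMetaAnalysis,
    classify_mean_effect,
    fit_gamma_glm,
    fit_multilevel_meta,
)


def _simulate_meta(seed, n_study=12, per=3, tau2_s=0.3, tau2_id=0.1,
                   means=(-0.5, 0.0, 0.4)):
    rng = np.random.default_rng(seed)
    levels = [chr(ord("a") + i) for i in range(len(means))]
    rows = []
    for s in range(n_study):
        u = rng.normal(0, np.sqrt(tau2_s))
        for i, (lev, mu) in enumerate(zip(levels, means)):
            v = rng.uniform(0.05, 0.3)
            d = mu + u + rng.normal(0, np.sqrt(tau2_id)) + rng.normal(0, np.sqrt(v))
            rows.append(
                dict(study_id=f"S{s}", response_id=f"I{i}", lev=lev, d=d, v_d=v)
            )
    return pd.DataFrame(rows)


class TestMultilevelMeta:
    def test_single_effect(self):
        fit = MultilevelMetaAnalysis([0.5], [0.2], ["S1"]).fit()
        assert fit.params["overall"] == pytest.approx(0.5)
        assert fit.tau2_study == fit.tau2_id == 0
        assert fit.qe == pytest.approx(0.0, abs=1e-12)
        assert fit.bse["overall"] == pytest.approx(np.sqrt(0.2))

    def test_identical_effects_zero_heterogeneity(self):
        d = [0.7] * 6
        v = [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]
        fit = MultilevelMetaAnalysis(d, v, [f"S{i}" for i in range(6)]).fit()
        assert fit.params["overall"] == pytest.approx(0.7)
        assert fit.qe == pytest.approx(0.0, abs=1e-10)
        assert fit.tau2_study + fit.tau2_id == pytest.approx(0.0, abs=1e-4)

    def test_fixed_effect_reduction_matches_closed_form(self):
        df = _simulate_meta(3)
        fit = MultilevelMetaAnalysis.from_dataframe(
            df, moderator_col="lev"
        ).fit(tau2=(0.0, 0.0))
        for lev, sub in df.groupby("lev"):
            w = 1.0 / sub["v_d"]
            expected = float((w * sub["d"]).sum() / w.sum())
            assert fit.params[lev] == pytest.approx(expected, abs=1e-8)

    def test_qe_equals_cochran_q_of_moderator_model(self):
        df = _simulate_meta(4)
        fit = fit_multilevel_meta(df, moderator_col="lev")
        # independent Q: weighted residual SS around 1/v-weighted level means
        q = 0.0
        for lev, sub in df.groupby("lev"):
            w = 1.0 / sub["v_d"].to_numpy()
            mu = (w * sub["d"]).sum() / w.sum()
            q += float((w * (sub["d"] - mu) ** 2).sum())
        assert fit.qe == pytest.approx(q, rel=1e-10)
        assert fit.qe_df == len(df) - 3

    def test_reduces_to_single_level_random_effects(self):
        # One effect per study and tau2_id fixed at 0: pooled mean equals the
        # DerSimonian-Laird random-effects mean when tau2_study is matched.
        rng = np.random.default_rng(8)
        k = 15
        d = rng.normal(0.3, 0.4, k)
        v = rng.uniform(0.05, 0.2, k)
        res = combine_effects(d, v, method_re="dl")
        tau2_dl = res.tau2
        fit = MultilevelMetaAnalysis(d, v, [f"S{i}" for i in range(k)]).fit(
            tau2=(tau2_dl, 0.0)
        )
        w = 1.0 / (v + tau2_dl)
        expected = float((w * d).sum() / w.sum())
        assert fit.params["overall"] == pytest.approx(expected, abs=1e-10)
        summ = res.summary_frame()
        assert fit.params["overall"] == pytest.approx(
            summ.loc["random effect", "eff"], abs=1e-8
        )

    def test_saturated_model_fits_exactly(self):
        # k == p: each level holds one effect; means reproduce the data and
        # variance components stay at zero.
        fit = MultilevelMetaAnalysis(
            [0.1, -0.2], [0.1, 0.2], ["S1", "S2"], moderator=["a", "b"]
        ).fit()
        assert fit.params["a"] == pytest.approx(0.1)
        assert fit.params["b"] == pytest.approx(-0.2)
        assert fit.tau2_study == fit.tau2_id == 0.0
        assert fit.qe == pytest.approx(0.0, abs=1e-12)

    def test_ci_contains_point_estimate_and_level_table(self):
        fit = fit_multilevel_meta(_simulate_meta(5), moderator_col="lev")
        tab = fit.level_table()
        assert ((tab["ci_low"] <= tab["mean_d"]) & (tab["mean_d"] <= tab["ci_high"])).all()
        assert tab["k"].sum() == fit.k
        assert fit.tau2_study >= 0 and fit.tau2_id >= 0
        assert "Multilevel" in fit.summary()

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_agrees_with_metafor_rma_mv(self, tmp_path):
        """Independent oracle: R metafor rma.mv with ID nested in Study."""
        df = _simulate_meta(42)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            "suppressMessages(library(jsonlite))\n"
            f"df <- read.csv('{csv}')\n"
            "fit <- rma.mv(d, v_d, mods = ~ lev - 1,"
            " random = ~ 1 | study_id/response_id, data=df, method='REML')\n"
            "cat(toJSON(list(b=as.numeric(fit$b), se=as.numeric(fit$se),"
            " sigma2=as.numeric(fit$sigma2), QE=fit$QE, QM=fit$QM), digits=10))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        fit = fit_multilevel_meta(df, moderator_col="lev")
        np.testing.assert_allclose(fit.params.to_numpy(), ref["b"], atol=1e-4)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref["se"], atol=1e-4)
        np.testing.assert_allclose(
            [fit.tau2_study, fit.tau2_id], ref["sigma2"], atol=1e-4
        )
        assert fit.qe == pytest.approx(ref["QE"][0], rel=1e-6)
        assert fit.qm == pytest.approx(ref["QM"][0], rel=1e-3)


class TestClassifyMeanEffect:
    @pytest.mark.parametrize("mean,lo,hi,expected", [
        (-0.6, -1.0, -0.2, "antagonistic"),
        (-0.1, -0.4, 0.2, "null"),
        (0.5, 0.1, 0.9, "synergistic_or_amplified"),
    ])
    def test_examples(self, mean, lo, hi, expected):
        assert classify_mean_effect(mean, lo, hi) == expected


class TestGammaGLM:
    def test_constant_response_identity(self):
        res = fit_gamma_glm([2.5] * 10, np.linspace(0, 100, 10))
        assert res.intercept == pytest.approx(np.log(2.5), abs=1e-8)
        assert res.slope == pytest.approx(0.0, abs=1e-8)

    def test_predict_matches_link(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, 50)
        y = rng.gamma(2.0, np.exp(0.2 - 0.005 * x) / 2.0)
        res = fit_gamma_glm(y + 1e-9, x, subset="other", epsilon_all=True)
        np.testing.assert_allclose(
            res.predict(x), np.exp(res.intercept + res.slope * x)
        )

    def test_zero_response_requires_epsilon(self):
        y = [0.0, 0.4, 1.2, 0.8, 0.3, 2.0, 1.1, 0.6]
        x = [80, 60, 55, 70, 90, 52, 65, 75]
        with pytest.raises(ValueError, match="epsilon"):
            fit_gamma_glm(y, x, subset="other")
        # temperature-prevailing subset gets the constant automatically
        res = fit_gamma_glm(y, x, subset="temperature")
        assert np.isfinite(res.slope)
        # epsilon_all makes the other subset fittable too
        res2 = fit_gamma_glm(y, x, subset="other", epsilon_all=True)
        assert res2.slope == pytest.approx(res.slope)

    def test_multiplicative_rescaling_shifts_intercept_only(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 50, 200)
        y = rng.gamma(3.0, np.exp(0.5 - 0.01 * x) / 3.0)
        r1 = fit_gamma_glm(y, x)
        r2 = fit_gamma_glm(10 * y, x)
        assert r2.slope == pytest.approx(r1.slope, abs=1e-8)
        assert r2.intercept - r1.intercept == pytest.approx(np.log(10), abs=1e-8)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="3 observations"):
            AsymmetryAccuracyGLM([1.0, 2.0], [0.0, 1.0])
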