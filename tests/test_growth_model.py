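import numpy as np
import pandas as pd
import pytest

from ringwue.growth_model import (ModelSpec, GrowthParams, SamplerSettings,
                                  compare_models, gelman_rubin,
                                  linear_predictor, log_likelihood,
                                  model_metrics, params_at, sample_posterior,
                                  PosteriorSamples)


def make_params(alpha=0.2, beta_row=(0.1, -0.07, 0.06, 0.5, 0.2, 0.05),
                sigma2_p=1.0):
    covs = ("precip", "tmax", "interaction", "lag1", "lag2", "dbh")
    return GrowthParams(sites=["S1"], groups=["G1"], covariates=covs,
                        alpha_s=np.array([alpha]),
                        beta=np.array(beta_row, float).reshape(6, 1),
                        sigma2_p=sigma2_p)


def obs_row(precip=1.0, tmax=1.0, inter=1.0, lag1=0.4, lag2=0.1, dbh=2.0,
            y=0.0):
    return pd.DataFrame([{"site_id": "S1", "group": "G1",
                          "log_growth": y, "precip_scaled": precip,
                          "tmax_scaled": tmax, "interaction": inter,
                          "lag1_log_growth": lag1, "lag2_log_growth": lag2,
                          "dbh_scaled": dbh}])


class TestLinearPredictor:
    def test_all_zero_slopes_return_intercept(self):
        p = make_params(alpha=0.5, beta_row=np.zeros(6))
        assert linear_predictor(p, obs_row())[0] == pytest.approx(0.5)

    def test_zero_covariates_return_intercept(self):
        p = make_params(alpha=0.3)
        g = linear_predictor(p, obs_row(0, 0, 0, 0, 0, 0))
        assert g[0] == pytest.approx(0.3)

    def test_hand_arithmetic(self):
        # 0.2 + 0.1 - 0.07 + 0.06 + 0.5*0.4 + 0.2*0.1 + 0.05*2 = 0.61
        p = make_params()
        assert linear_predictor(p, obs_row())[0] == pytest.approx(0.61)

    def test_unknown_site_rejected(self):
        p = make_params()
        bad = obs_row().assign(site_id="NOPE")
        with pytest.raises(KeyError):
            linear_predictor(p, bad)


class TestLogLikelihood:
    def test_unit_density_closed_form(self):
        # at y == g with variance 1/(2*pi) the normal log-density is 0
        p = make_params(alpha=0.61, beta_row=np.zeros(6),
                        sigma2_p=1.0 / (2 * np.pi))
        row = obs_row(y=0.61)
        assert log_likelihood(p, row) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_data_doubles_loglik(self):
        p = make_params()
        rows = obs_row(y=0.3)
        double = pd.concat([rows, rows], ignore_index=True)
        assert log_likelihood(p, double) == pytest.approx(
            2 * log_likelihood(p, rows))

    def test_matches_independent_density_sum(self):
        rng = np.random.default_rng(12)
        rows = pd.concat([obs_row(*rng.uniform(-1, 1, 6), y=rng.normal())
                          for _ in range(10)], ignore_index=True)
        p = make_params(sigma2_p=0.3)
        g = linear_predictor(p, rows)
        y = rows["log_growth"].to_numpy()
        manual = np.sum(-0.5 * np.log(2 * np.pi * 0.3)
                        - (y - g) ** 2 / (2 * 0.3))
        assert log_likelihood(p, rows) == pytest.approx(manual, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        p = make_params(sigma2_p=0.0)
        with pytest.raises(ValueError):
            log_likelihood(p, obs_row())


class TestGelmanRubin:
    def _samples(self, chains):
        draws = np.asarray(chains, float)[:, :, None]
        return PosteriorSamples(draws, ["theta"],
                                SamplerSettings(iterations=40, burn_in=20,
                                                thin=1, chains=len(chains)))

    def test_identical_chains_give_unity(self):
        x = np.random.default_rng(0).normal(size=200)
        rhat = gelman_rubin(self._samples([x, x, x]))
        assert rhat["theta"] == pytest.approx(1.0, abs=1e-2)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 200)
        b = rng.normal(10, 1, 200)
        rhat = gelman_rubin(self._samples([a, b]))
        assert rhat["theta"] > 1.5

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(0, 1, (3, 150))
        chains[1] += 0.3
        rhat = gelman_rubin(self._samples(list(chains)))["theta"]
        # independent loop-based between/within computation
        m, n = chains.shape
        means = [np.mean(c) for c in chains]
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B = n * np.var(means, ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat == pytest.approx(expected, abs=1e-8)

    def test_single_chain_rejected(self):
        x = np.random.default_rng(3).normal(size=(1, 50, 1))
        s = PosteriorSamples(x, ["theta"],
                             SamplerSettings(iterations=100, burn_in=50,
                                             thin=1, chains=2))
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin(s)


class TestSampler:
    def test_identical_seeds_give_identical_draws(self, small_obs):
        obs, _ = small_obs
        settings = SamplerSettings(iterations=200, burn_in=100, thin=2,
                                   chains=2, seed=21)
        a = sample_posterior(obs, ModelSpec(), settings)
        b = sample_posterior(obs, ModelSpec(), settings)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_prior_support_respected(self, small_fit):
        for name in small_fit.names:
            if name.startswith("mu_"):
                x = small_fit.flat(name)
                assert np.all(x >= -2) and np.all(x <= 2)
            if name.startswith("sigma2"):
                assert np.all(small_fit.flat(name) > 0)

    def test_retained_count_contract(self, small_fit):
        st = small_fit.settings
        assert small_fit.draws.shape[:2] == (
            st.chains, (st.iterations - st.burn_in) // st.thin)

    def test_chains_below_two_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            SamplerSettings(chains=1)

    def test_recovery_on_small_dataset(self, small_obs, small_fit,
                                       small_dataset):
        """Posterior means should track the generating coefficients; with
        a small dataset allow one of the 24 slopes to stray past 2 sd."""
        truth = small_dataset["truth"]
        summ = small_fit.summary()
        n_out = 0
        for k in ("precip", "tmax", "interaction", "lag1", "lag2", "dbh"):
            for g, val in truth["beta"].items():
                row = summ.loc[f"beta_{k}[{g}]"]
                if abs(row["mean"] - val[k]) > 2 * row["sd"]:
                    n_out += 1
        assert n_out <= 3  # ~5% expected misses out of 24, small-n slack

    def test_label_permutation_preserves_site_intercepts(self, small_obs):
        obs, _ = small_obs
        settings = SamplerSettings(iterations=400, burn_in=200, thin=2,
                                   chains=2, seed=5)
        fit = sample_posterior(obs, ModelSpec(), settings)
        renamed = obs.assign(site_id="Z" + obs["site_id"])
        fit2 = sample_posterior(renamed, ModelSpec(), settings)
        for s in fit.meta["sites"]:
            a = fit.flat(f"alpha[{s}]").mean()
            b = fit2.flat(f"alpha[Z{s}]").mean()
            assert a == pytest.approx(b, abs=0.05)


class TestMetrics:
    def test_heldout_metrics_match_manual_computation(self, small_fit,
                                                      small_obs):
        obs, _ = small_obs
        train, test = obs.iloc[:-100], obs.iloc[-100:]
        d = model_metrics(small_fit, train, test)
        pred = linear_predictor(params_at(small_fit), test)
        y = test["log_growth"].to_numpy()
        assert d.mspe == pytest.approx(np.mean((pred - y) ** 2))
        assert d.bias == pytest.approx(np.mean(pred - y))
        assert d.r2 == pytest.approx(
            1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))
        assert d.r2 > 0.5  # the fit genuinely explains held-out growth

    def test_dic_matches_deviance_decomposition(self, small_obs):
        obs, _ = small_obs
        settings = SamplerSettings(iterations=300, burn_in=200, thin=1,
                                   chains=2, seed=3)
        fit = sample_posterior(obs, ModelSpec(), settings)
        d = model_metrics(fit, obs.iloc[:200], None)
        # recompute: Dbar over all 200 retained draws + pD
        devs = []
        for ch in range(fit.draws.shape[0]):
            for it in range(fit.draws.shape[1]):
                one = PosteriorSamples(fit.draws[ch:ch + 1, it:it + 1],
                                       fit.names, settings, fit.meta)
                devs.append(-2 * log_likelihood(params_at(one),
                                                obs.iloc[:200]))
        dbar = np.mean(devs)
        dhat = -2 * log_likelihood(params_at(fit), obs.iloc[:200])
        assert d.dic == pytest.approx(2 * dbar - dhat, rel=1e-9)

    def test_empty_test_flags_undefined(self, small_fit, small_obs):
        obs, _ = small_obs
        d = model_metrics(small_fit, obs, None)
        assert d.r2 is None and d.mspe is None


class TestCompare:
    def test_duplicate_specs_identical(self, small_obs):
        obs, _ = small_obs
        settings = SamplerSettings(iterations=200, burn_in=100, thin=2,
                                   chains=2, seed=4)
        raw = obs.drop(columns=["precip_scaled", "tmax_scaled",
                                "interaction", "dbh_scaled", "group"])
        train, test = raw.iloc[:-150], raw.iloc[-150:]
        table = compare_models(train, test,
                               [ModelSpec(), ModelSpec()], settings)
        assert table.loc[0, "dic"] == table.loc[1, "dic"]
        assert table.loc[0, "r2"] == table.loc[1, "r2"]
        assert not table["failed"].any()
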