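import numpy as np
import pandas as pd
import pytest

from bruvkit.models import (CandidateConfig, ModelSpec, aicc,
                            build_candidate_set, fit_and_rank, fit_glm,
                            rank_models)


class TestBuildCandidateSet:
    PREDICTORS = ["depth_m", "sst_c", "relief", "exposure_deg", "remoteness_m"]

    def test_default_recipe_count(self):
        # null + 5 singles + 5 habitat interactions + depth+relief = 12
        specs = build_candidate_set(self.PREDICTORS, "richness")
        assert len(specs) == 12
        assert sum(s.is_null for s in specs) == 1

    def test_empty_predictors_null_only(self):
        specs = build_candidate_set([], "richness")
        assert len(specs) == 1 and specs[0].is_null

    def test_seventeen_with_extra_pairs(self):
        pairs = tuple((a, b) for a, b in
                      [("depth_m", "sst_c"), ("depth_m", "exposure_deg"),
                       ("depth_m", "remoteness_m"), ("relief", "sst_c"),
                       ("relief", "remoteness_m")])
        cfg = CandidateConfig(extra_additive_pairs=pairs)
        specs = build_candidate_set(self.PREDICTORS, "richness", config=cfg)
        assert len(specs) == 17

    def test_duplicates_collapsed(self, caplog):
        cfg = CandidateConfig(extra_additive_pairs=(("depth_m", "relief"),))
        with caplog.at_level("WARNING"):
            specs = build_candidate_set(self.PREDICTORS, "richness", config=cfg)
        assert len(specs) == 12  # duplicate of the complex model collapsed
        assert any("duplicate" in r.message for r in caplog.records)

    def test_mandatory_terms_in_every_spec(self):
        for spec in build_candidate_set(self.PREDICTORS, "richness"):
            assert "spatial_lag" in spec.mandatory
            assert "C(year)" in spec.mandatory


class TestAicc:
    def test_direct_arithmetic(self):
        # -2(-100) + 2*3 + 2*3*4/96 = 206.25
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_k_zero_limit(self):
        assert aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_large_n_approaches_aic(self):
        ll, k = -500.0, 5
        aic = -2 * ll + 2 * k
        assert abs(aicc(ll, k, 100_000) - aic) < 0.01

    def test_small_n_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-10.0, 5, 6)


def _sim_data(rng, n=280, beta_depth=0.05):
    depth = rng.uniform(0, 40, n)
    habitat = rng.choice(["Reefs", "Sediments"], n)
    noise1 = rng.normal(size=n)
    noise2 = rng.normal(size=n)
    eta = -0.5 + beta_depth * depth
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame({"y": y, "depth_m": depth, "habitat": habitat,
                         "noise1": noise1, "noise2": noise2,
                         "year": rng.choice([2022, 2023], n),
                         "spatial_lag": rng.normal(size=n)})


class TestFitGlm:
    def test_gamma_intercept_only_recovers_mean(self):
        df = pd.DataFrame({"y": [2.0, 2.0, 2.0, 2.0],
                           "year": [2022] * 4, "spatial_lag": [0.0] * 4})
        spec = ModelSpec("y", (), family="gamma", link="log", mandatory=())
        fit = fit_glm(spec, df)
        assert np.exp(fit.params["Intercept"]) == pytest.approx(2.0)

    def test_gamma_rejects_nonpositive(self):
        df = pd.DataFrame({"y": [1.0, 0.0], "year": [1, 2],
                           "spatial_lag": [0., 0.]})
        spec = ModelSpec("y", (), family="gamma", link="log", mandatory=())
        with pytest.raises(ValueError, match="positive"):
            fit_glm(spec, df)

    def test_poisson_recovery_within_2se(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 40
        for _ in range(reps):
            df = _sim_data(rng)
            spec = ModelSpec("y", ("depth_m",), family="poisson",
                             mandatory=())
            fit = fit_glm(spec, df)
            err = abs(fit.params["depth_m"] - 0.05)
            hits += err <= 2 * fit.bse["depth_m"]
        assert hits / reps >= 0.85

    def test_negbin_on_poisson_data_agrees_with_poisson(self):
        rng = np.random.default_rng(1)
        df = _sim_data(rng, n=500)
        sp_p = ModelSpec("y", ("depth_m",), family="poisson", mandatory=())
        sp_nb = ModelSpec("y", ("depth_m",), family="negbin", mandatory=())
        fp, fnb = fit_glm(sp_p, df), fit_glm(sp_nb, df)
        assert fnb.alpha < 0.05  # near-zero overdispersion
        assert abs(fnb.aicc - fp.aicc) < 2.5
        assert fnb.params["depth_m"] == pytest.approx(fp.params["depth_m"],
                                                      abs=0.005)

    def test_negbin_estimates_true_dispersion(self):
        rng = np.random.default_rng(2)
        n, k_true = 2000, 1.5
        mu = np.exp(rng.uniform(0.5, 2.0, n))
        y = rng.negative_binomial(k_true, k_true / (k_true + mu))
        df = pd.DataFrame({"y": y, "logmu": np.log(mu)})
        spec = ModelSpec("y", ("logmu",), family="negbin", mandatory=())
        fit = fit_glm(spec, df)
        # statsmodels NB2 alpha = 1/k
        assert fit.alpha == pytest.approx(1.0 / k_true, rel=0.25)

    def test_k_counts_dispersion_parameters(self):
        rng = np.random.default_rng(3)
        df = _sim_data(rng, n=100)
        df["y"] = df["y"] + 1.0
        for family, extra in [("poisson", 0), ("negbin", 1), ("gamma", 1),
                              ("gaussian", 1)]:
            link = "identity" if family == "gaussian" else "log"
            spec = ModelSpec("y", ("depth_m",), family=family, link=link,
                             mandatory=())
            fit = fit_glm(spec, df)
            assert fit.k == 2 + extra


class TestRankModels:
    def _fits(self, aiccs):
        out = []
        for i, a in enumerate(aiccs):
            spec = ModelSpec("y", (f"x{i}",) if i else (), label=f"m{i}")
            out.append(type("F", (), {
                "spec": spec, "converged": True, "aicc": a, "k": 2,
                "n": 100, "loglik": -a / 2, "pseudo_r2": 0.1})())
        return out

    def test_equal_aicc_equal_weights(self):
        tab = rank_models(self._fits([100.0, 100.0]))
        np.testing.assert_allclose(tab["weight"], [0.5, 0.5])

    def test_delta_two_closed_form(self):
        tab = rank_models(self._fits([100.0, 102.0]))
        expected = np.exp(-1.0) / (1.0 + np.exp(-1.0))
        assert tab["weight"].iloc[1] == pytest.approx(expected, abs=1e-6)
        assert tab["weight"].iloc[0] == pytest.approx(1 - expected, abs=1e-6)

    def test_weights_sum_to_one_and_delta_nonnegative(self):
        rng = np.random.default_rng(4)
        tab = rank_models(self._fits(list(100 + rng.uniform(0, 30, 9))))
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert (tab["delta_aicc"] >= 0).all()
        assert tab["delta_aicc"].iloc[0] == 0.0

    def test_ranking_invariant_to_loglik_shift(self):
        a = self._fits([100.0, 105.0, 103.0])
        b = self._fits([110.0, 115.0, 113.0])
        ta, tb = rank_models(a), rank_models(b)
        assert list(ta["label"]) == list(tb["label"])
        np.testing.assert_allclose(ta["weight"], tb["weight"])

    def test_delta_to_null_reported(self):
        tab = rank_models(self._fits([100.0, 90.0]))
        assert "delta_aicc_to_null" in tab.columns
        # null model AICc 100; best model 90 -> +10 improvement
        assert tab.loc[tab["terms"] != "(null)",
                       "delta_aicc_to_null"].iloc[0] == pytest.approx(10.0)


class TestSelectionOnSimulatedData:
    def test_true_model_enters_confidence_set(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 25
        for _ in range(reps):
            df = _sim_data(rng, beta_depth=0.05)
            specs = build_candidate_set(
                ["depth_m", "noise1", "noise2"], "y", family="poisson",
                config=CandidateConfig(mandatory=(), complex_terms=()))
            _, rank = fit_and_rank(specs, df)
            in_set = rank[rank["in_confidence_set"]]["terms"]
            hits += any(t == "depth_m" or t.startswith("depth_m")
                        for t in in_set)
        assert hits / reps >= 0.9

    def test_null_behind_signal_models(self):
        rng = np.random.default_rng(6)
        df = _sim_data(rng, beta_depth=0.08)
        specs = build_candidate_set(
            ["depth_m"], "y", family="poisson",
            config=CandidateConfig(mandatory=(), complex_terms=()))
        _, rank = fit_and_rank(specs, df)
        null_delta = rank.loc[rank["terms"] == "(null)", "delta_aicc"].iloc[0]
        assert null_delta > 0

    def test_pseudo_r2_in_unit_interval(self):
        rng = np.random.default_rng(7)
        df = _sim_data(rng)
        specs = build_candidate_set(
            ["depth_m", "noise1"], "y", family="poisson",
            config=CandidateConfig(mandatory=(), complex_terms=()))
        _, rank = fit_and_rank(specs, df)
        assert ((rank["pseudo_r2"] >= 0) & (rank["pseudo_r2"] <= 1)).all()
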