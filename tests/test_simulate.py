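import numpy as np
import pandas as pd
import pytest

from infodur import (
    GeneratingModel,
    calibrate_generating_model,
    compute_bigram_stats,
    estimate_sample_predictors,
    resample_pair_counts,
    run_null_experiment,
    simulate_durations,
)
from infodur.models import ModelSpec
from infodur.simulate import _expand_tokens


class TestCalibrateGeneratingModel:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(-6, 0, 40)
        d = pd.DataFrame({"predictability": x, "duration_log": -1.5 - 0.07 * x,
                          "word": [f"w{i}" for i in range(40)]})
        gen = calibrate_generating_model(d)
        assert gen.b0 == pytest.approx(-1.5, abs=1e-10)
        assert gen.b_pred == pytest.approx(-0.07, abs=1e-10)

    def test_sigma_resid_is_residual_sd(self):
        rng = np.random.default_rng(5)
        x = rng.normal(-3, 1, 500)
        y = -2 + 0.1 * x + rng.normal(0, 0.3, 500)
        d = pd.DataFrame({"predictability": x, "duration_log": y,
                          "word": ["w"] * 500})
        gen = calibrate_generating_model(d)
        X = np.column_stack([np.ones(500), x])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert gen.sigma_resid == pytest.approx(float(np.std(resid)), abs=1e-10)

    def test_omitting_collinear_predictor_inflates_coefficient(self):
        # informativity ~ -predictability and both drive duration: the
        # single-predictor calibration absorbs informativity's share
        rng = np.random.default_rng(8)
        pred = rng.normal(-3, 1, 2000)
        info = -0.9 * pred + 0.2 * np.abs(rng.normal(0, 1, 2000))
        y = -2 - 0.05 * pred + 0.1 * info + rng.normal(0, 0.2, 2000)
        d = pd.DataFrame({"predictability": pred, "informativity": info,
                          "duration_log": y, "word": ["w"] * 2000})
        gen_single = calibrate_generating_model(d)
        from infodur import fit_duration_model
        both = fit_duration_model(
            d, ModelSpec(fixed_terms=["predictability", "informativity"]))
        assert abs(gen_single.b_pred) > abs(both.params["predictability"])


class TestResamplePairCounts:
    def test_certain_pair_always_full_count(self):
        t = pd.DataFrame({"word": ["b"] * 7, "context": ["a"] * 7})
        stats = compute_bigram_stats(t)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert resample_pair_counts(stats, rng)["k"].iloc[0] == 7

    def test_single_trial_context_gives_zero_or_one(self):
        # a context observed once: each replicate's sample probability is 0 or 1
        t = pd.DataFrame({"word": ["b", "c", "b"], "context": ["a", "x", "y"]})
        stats = compute_bigram_stats(t)
        rng = np.random.default_rng(0)
        ks = np.array([resample_pair_counts(stats, rng)["k"].to_numpy()
                       for _ in range(50)])
        assert set(np.unique(ks)) <= {0, 1}

    def test_binomial_moments(self):
        # p = 0.5, n_cx = 10: mean k within 3 SE of 5 over many replicates
        t = pd.DataFrame({"word": ["b"] * 5 + ["c"] * 5, "context": ["a"] * 10})
        stats = compute_bigram_stats(t)
        rng = np.random.default_rng(123)
        ks = [resample_pair_counts(stats, rng).set_index("word").loc["b", "k"]
              for _ in range(10_000)]
        se = np.sqrt(10 * 0.25 / 10_000)
        assert np.mean(ks) == pytest.approx(5.0, abs=3 * se)

    def test_multinomial_counts_sum_to_context_frequency(self, hand_tokens):
        stats = compute_bigram_stats(hand_tokens)
        rng = np.random.default_rng(1)
        pairs = resample_pair_counts(stats, rng, scheme="multinomial")
        sums = pairs.groupby("context")["k"].sum()
        ncx = stats.contexts.set_index("context")["n_cx"]
        assert (sums == ncx.loc[sums.index]).all()


class TestEstimateSamplePredictors:
    def test_full_count_gives_zero_predictability(self):
        rep = pd.DataFrame({"word": ["b"], "context": ["a"], "k": [4],
                            "context_freq": [4]})
        out = estimate_sample_predictors(rep)
        assert out["sample_predictability"].iloc[0] == 0.0
        assert out["sample_informativity"].iloc[0] == 0.0

    def test_resample_equal_to_original_reproduces_stats(self, hand_tokens):
        stats = compute_bigram_stats(hand_tokens)
        pairs = stats.pairs.copy()
        pairs["k"] = pairs["count"]  # replicate == original corpus
        rep = estimate_sample_predictors(_expand_tokens(pairs, stats))
        np.testing.assert_allclose(rep["sample_predictability"], rep["pred_true"])
        np.testing.assert_allclose(rep["sample_informativity"], rep["info_true"])

    def test_matches_brute_force_on_random_replicate(self, synth_corpus):
        tokens, _ = synth_corpus
        stats = compute_bigram_stats(tokens)
        rng = np.random.default_rng(9)
        rep = estimate_sample_predictors(
            _expand_tokens(resample_pair_counts(stats, rng), stats))
        # brute force: token-by-token python recomputation
        by_word: dict[str, list[float]] = {}
        for _, row in rep.iterrows():
            s = -np.log(row["k"] / row["context_freq"])
            by_word.setdefault(row["word"], []).append(s)
        expect = rep["word"].map(lambda w: float(np.mean(by_word[w])))
        np.testing.assert_allclose(rep["sample_informativity"], expect, atol=1e-12)


class TestSimulateDurations:
    def test_vanishing_noise_recovers_linear_mean(self):
        rep = pd.DataFrame({"word": ["u", "v"], "pred_true": [-2.0, -0.5],
                            "info_true": [1.0, 0.3]})
        gen = GeneratingModel(b0=-1.0, b_pred=-0.1, sigma_resid=1e-12)
        out = simulate_durations(rep, gen, np.random.default_rng(0))
        np.testing.assert_allclose(
            out["duration_log"], -1.0 - 0.1 * rep["pred_true"], atol=1e-9)

    def test_moment_oracle_on_large_replicate(self):
        n = 40_000
        rep = pd.DataFrame({"word": ["w"] * n, "pred_true": np.full(n, -2.0),
                            "info_true": np.zeros(n)})
        gen = GeneratingModel(b0=-1.0, b_pred=-0.1, sigma_resid=0.4)
        out = simulate_durations(rep, gen, np.random.default_rng(3))
        mu = -1.0 + 0.2
        assert out["duration_log"].mean() == pytest.approx(mu, abs=3 * 0.4 / np.sqrt(n))
        assert out["duration_log"].std() == pytest.approx(0.4, rel=0.02)

    def test_missing_word_effect_rejected(self):
        rep = pd.DataFrame({"word": ["u"], "pred_true": [-1.0], "info_true": [0.5]})
        gen = GeneratingModel(b0=0.0, b_pred=-0.1, sigma_resid=0.1,
                              word_effects={"other": 0.2})
        with pytest.raises(KeyError, match="u"):
            simulate_durations(rep, gen, np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_setup(synth_corpus):
    tokens, _ = synth_corpus
    gen = GeneratingModel(b0=-2.0, b_pred=-0.08, sigma_resid=0.35)
    spec = ModelSpec(fixed_terms=["predictability", "informativity"])
    return tokens, gen, spec


class TestRunNullExperiment:
    def test_same_master_seed_is_bit_identical(self, small_setup):
        tokens, gen, spec = small_setup
        s1 = run_null_experiment(tokens, gen, spec, 5, 77)
        s2 = run_null_experiment(tokens, gen, spec, 5, 77)
        pd.testing.assert_frame_equal(s1.results, s2.results)

    def test_different_seeds_differ(self, small_setup):
        tokens, gen, spec = small_setup
        s1 = run_null_experiment(tokens, gen, spec, 3, 77)
        s2 = run_null_experiment(tokens, gen, spec, 3, 78)
        assert not np.allclose(s1.estimates("informativity"),
                               s2.estimates("informativity"))

    def test_true_predictors_under_zero_effects_centre_on_zero(self, small_setup):
        # with b_pred = b_info = 0 durations are pure noise: informativity
        # estimates scatter around zero
        tokens, _, spec = small_setup
        gen = GeneratingModel(b0=-2.0, b_pred=0.0, sigma_resid=0.35)
        s = run_null_experiment(tokens, gen, spec, 30, 5, predictor_source="true")
        est = s.estimates("informativity")
        assert abs(est.mean()) < 4 * est.std() / np.sqrt(len(est))

    def test_sample_predictability_correlates_below_one_with_truth(self, small_setup):
        # the resampling noise that drives the whole diagnostic
        tokens, gen, spec = small_setup
        stats = compute_bigram_stats(tokens)
        rng = np.random.default_rng(4)
        rep = estimate_sample_predictors(
            _expand_tokens(resample_pair_counts(stats, rng), stats))
        r = np.corrcoef(rep["pred_true"], rep["sample_predictability"])[0, 1]
        assert 0.8 < r < 1.0
        # scaling every context frequency x10 makes estimates more reliable
        big = stats.pairs.copy()
        big["count"] *= 10
        big["n_cx"] *= 10
        tokens10 = big.loc[big.index.repeat(big["count"])]
        stats10 = compute_bigram_stats(
            tokens10[["word", "context"]].reset_index(drop=True))
        rep10 = estimate_sample_predictors(
            _expand_tokens(resample_pair_counts(stats10, rng), stats10))
        r10 = np.corrcoef(rep10["pred_true"], rep10["sample_predictability"])[0, 1]
        assert r10 > r

    def test_unknown_predictor_source_rejected(self, small_setup):
        tokens, gen, spec = small_setup
        with pytest.raises(ValueError):
            run_null_experiment(tokens, gen, spec, 1, 0, predictor_source="oracle")
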