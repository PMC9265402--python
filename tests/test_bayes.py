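"""Bayesian index regression: sampler contracts, Geweke diagnostic,
posterior summaries, and index application."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import aceindex as ai
from aceindex.bayes import PosteriorSummary, geweke_z, summarize_posterior


def simulate_index_data(seed, n=300, C=4, beta0=-1.0, beta1=0.8,
                        w=(0.4, 0.3, 0.2, 0.1)):
    rng = np.random.default_rng(seed)
    Q = rng.integers(0, 10, size=(n, C))
    w = np.asarray(w, dtype=float)
    y = rng.binomial(1, expit(beta0 + beta1 * (Q @ w))).astype(float)
    return Q, y, w


SHORT = ai.McmcSettings(n_iter=600, n_burnin=300, n_adapt=200, seed=11)


class TestFitBayesIndex:
    def test_same_seed_identical_chains(self):
        Q, y, _ = simulate_index_data(1)
        _, c1 = ai.fit_bayes_index(Q, y, SHORT)
        _, c2 = ai.fit_bayes_index(Q, y, SHORT)
        pd.testing.assert_frame_equal(c1, c2)

    def test_every_draw_on_simplex(self):
        Q, y, _ = simulate_index_data(2)
        _, chains = ai.fit_bayes_index(Q, y, SHORT)
        W = chains[[c for c in chains.columns if c.startswith("w_")]].to_numpy()
        assert W.min() >= 0.0 and W.max() <= 1.0
        assert np.abs(W.sum(axis=1) - 1.0).max() <= 1e-10

    def test_weight_median_sum_near_one(self):
        Q, y, _ = simulate_index_data(3)
        summary, _ = ai.fit_bayes_index(Q, y, SHORT)
        assert 0.9 <= summary.weight_medians.sum() <= 1.1

    def test_single_class_outcome_rejected(self):
        Q, _, _ = simulate_index_data(4)
        with pytest.raises(ValueError, match="single class"):
            ai.fit_bayes_index(Q, np.ones(len(Q)), SHORT)

    def test_non_integer_scores_rejected(self):
        Q, y, _ = simulate_index_data(5)
        with pytest.raises(ValueError, match="integer"):
            ai.fit_bayes_index(Q + 0.5, y, SHORT)

    def test_unit_odds_shift_per_decile(self):
        """Model identity: adding 1 to every decile score shifts the linear
        predictor by exactly beta1 for any draw (weights sum to 1)."""
        Q, y, _ = simulate_index_data(6)
        _, chains = ai.fit_bayes_index(Q, y, SHORT)
        draw = chains.iloc[-1]
        w = draw[[c for c in chains.columns if c.startswith("w_")]].to_numpy()
        eta0 = draw["beta0"] + draw["beta1"] * (Q @ w)
        eta1 = draw["beta0"] + draw["beta1"] * ((Q + 1) @ w)
        np.testing.assert_allclose(eta1 - eta0, draw["beta1"], atol=1e-10)

    def test_multi_chain_pools_draws(self):
        Q, y, _ = simulate_index_data(7)
        st = ai.McmcSettings(n_iter=300, n_burnin=150, n_adapt=100, seed=5, n_chains=3)
        summary, chains = ai.fit_bayes_index(Q, y, st)
        assert chains["chain"].value_counts().to_dict() == {0: 300, 1: 300, 2: 300}
        assert len(summary.weight_medians) == Q.shape[1]

    def test_posterior_mode_matches_direct_maximization(self):
        """With weights and the beta1 prior SD clamped, the sampler's highest
        log-posterior draw sits at the brute-force optimum of the exact log
        posterior."""
        rng = np.random.default_rng(9)
        n, C = 50, 3
        Q = rng.integers(0, 10, size=(n, C))
        w = np.array([0.5, 0.3, 0.2])
        y = rng.binomial(1, expit(-1.0 + 0.8 * (Q @ w))).astype(float)
        s = Q @ w
        sig = 10.0

        def neg_lp(theta):
            b0, b1 = theta
            eta = b0 + b1 * s
            ll = y @ eta - np.logaddexp(0, eta).sum()
            return -(ll - 0.5 * (b0 / 100) ** 2 - np.log(sig) - 0.5 * (b1 / sig) ** 2)

        opt = minimize(neg_lp, [0.0, 0.0], method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-12))
        st = ai.McmcSettings(n_iter=20000, n_burnin=2000, n_adapt=1000, seed=4)
        _, chains = ai.fit_bayes_index(Q, y, st, fixed_weights=w, fixed_sigma1=sig)
        best = chains.loc[chains["lp"].idxmax()]
        assert abs(best["beta0"] - opt.x[0]) < 0.05
        assert abs(best["beta1"] - opt.x[1]) < 0.05


class TestGeweke:
    def test_repeated_pattern_is_symmetric(self):
        chain = np.tile([0.0, 1.0, 2.0, 3.0], 500)
        assert abs(geweke_z(chain)) < 1e-6

    def test_iid_chain_usually_converged(self):
        hits = 0
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(5000)
            hits += abs(geweke_z(x)) < 2
        assert hits >= 180  # >= 90% of seeds

    def test_drifting_chain_flagged(self):
        rng = np.random.default_rng(0)
        chain = np.linspace(0, 10, 5000) + rng.standard_normal(5000)
        assert abs(geweke_z(chain)) >= 2

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            geweke_z(np.ones(500))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="short"):
            geweke_z(np.arange(50.0))


def make_chains(beta1_draws, n=1000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "beta0": rng.standard_normal(n),
            "beta1": beta1_draws,
            "sigma1": rng.uniform(1, 5, n),
            "w_a": np.full(n, 0.6),
            "w_b": np.full(n, 0.4),
        }
    )


class TestSummarizePosterior:
    def test_degenerate_odds_ratio_point_mass(self):
        chains = make_chains(np.full(1000, np.log(1.24)))
        summary = summarize_posterior(chains)
        med, lo, hi = summary.odds_ratio
        assert med == pytest.approx(1.24)
        assert lo == pytest.approx(1.24) and hi == pytest.approx(1.24)
        assert summary.significant

    def test_symmetric_null_not_significant(self):
        rng = np.random.default_rng(1)
        chains = make_chains(0.3 * rng.standard_normal(1000))
        summary = summarize_posterior(chains)
        _, lo, hi = summary.odds_ratio
        assert lo < 1.0 < hi
        assert not summary.significant

    def test_percentiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(2)
        draws = rng.gamma(2.0, 1.5, 1000)
        chains = make_chains(draws)
        summary = summarize_posterior(chains)
        # order-statistics oracle with linear interpolation
        srt = np.sort(draws)

        def q(p):
            h = (len(srt) - 1) * p
            lo_i = int(np.floor(h))
            return srt[lo_i] + (h - lo_i) * (srt[min(lo_i + 1, len(srt) - 1)] - srt[lo_i])

        row = summary.params.loc["beta1"]
        assert row["median"] == pytest.approx(q(0.5), abs=1e-12)
        assert row["cri_2.5"] == pytest.approx(q(0.025), abs=1e-12)
        assert row["cri_97.5"] == pytest.approx(q(0.975), abs=1e-12)

    def test_interval_brackets_median(self):
        rng = np.random.default_rng(3)
        chains = make_chains(rng.standard_normal(1000))
        summary = summarize_posterior(chains)
        p = summary.params
        assert ((p["cri_2.5"] <= p["median"]) & (p["median"] <= p["cri_97.5"])).all()

    def test_constant_parameter_gets_nan_geweke(self):
        chains = make_chains(np.full(1000, 0.2))
        summary = summarize_posterior(chains)
        assert np.isnan(summary.geweke["w_a"])


def make_summary(weights: dict[str, float]) -> PosteriorSummary:
    return PosteriorSummary(
        params=pd.DataFrame(
            {"median": [0.0], "cri_2.5": [0.0], "cri_97.5": [0.0]}, index=["beta0"]
        ),
        odds_ratio=(1.0, 0.9, 1.1),
        significant=False,
        geweke={},
        converged=True,
        weight_medians=pd.Series(weights),
        variable_names=list(weights),
    )


class TestApplyBayesIndex:
    def test_weighted_decile_sum(self):
        summary = make_summary({"a": 0.5, "b": 0.3, "c": 0.2})
        data = pd.DataFrame({"a": [2], "b": [0], "c": [5]})
        assert ai.apply_bayes_index(summary, data).iloc[0] == pytest.approx(2.0)

    def test_equal_weights_give_scaled_mean(self, rng):
        C = 25
        w = {f"v{i}": 1.0 / C for i in range(C)}
        assert w["v0"] == 0.04  # the equal-weight reference for 25 variables
        data = pd.DataFrame(
            rng.integers(0, 10, size=(8, C)), columns=list(w)
        )
        scores = ai.apply_bayes_index(make_summary(w), data)
        np.testing.assert_allclose(scores, data.to_numpy().sum(axis=1) / C, atol=1e-12)

    def test_zero_scores_give_zero(self):
        summary = make_summary({"a": 0.5, "b": 0.5})
        data = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        assert ai.apply_bayes_index(summary, data).tolist() == [0.0, 0.0]

    def test_column_mismatch_rejected(self):
        summary = make_summary({"a": 0.5, "b": 0.5})
        with pytest.raises(ValueError, match="mismatch"):
            ai.apply_bayes_index(summary, pd.DataFrame({"a": [1]}))

    def test_raw_mode_accepts_continuous_values(self):
        summary = make_summary({"a": 0.5, "b": 0.5})
        data = pd.DataFrame({"a": [1.5], "b": [2.5]})
        with pytest.raises(ValueError):
            ai.apply_bayes_index(summary, data, mode="quantile")
        assert ai.apply_bayes_index(summary, data, mode="raw").iloc[0] == pytest.approx(2.0)
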