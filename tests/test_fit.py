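"""Posterior sampling, DIC computation and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survpool.fit import McmcConfig, compute_dic, sample_posterior, select_model
from survpool.reconstruct import PooledData
from survpool.validation import make_two_arm_pooled

from conftest import make_fixed_fit


def _pooled(times, events, treatments, reference="sorafenib"):
    data = pd.DataFrame(
        {
            "time_months": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "treatment": list(treatments),
        }
    )
    non_ref = tuple(sorted(set(treatments) - {reference}))
    return PooledData(data=data, reference=reference, treatments=non_ref)


@pytest.fixture(scope="module")
def small_exponential_pooled():
    rng = np.random.default_rng(21)
    n = 400
    t = rng.exponential(12.0, n)
    return _pooled(t, np.ones(n), ["sorafenib"] * n)


class TestSamplePosterior:
    def test_seeded_reproducibility(self, small_exponential_pooled):
        cfg = McmcConfig(chains=2, iterations=300, warmup=150, seed=42)
        a = sample_posterior(small_exponential_pooled, "exponential", cfg)
        b = sample_posterior(small_exponential_pooled, "exponential", cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.dic == b.dic

    def test_draw_count_contract(self, small_exponential_pooled):
        cfg = McmcConfig(chains=3, iterations=400, warmup=150, seed=1)
        fit = sample_posterior(small_exponential_pooled, "exponential", cfg)
        assert fit.draws.shape == (3, 250, 1)
        assert fit.n_draws == 750

    def test_conjugate_gamma_limit(self, small_exponential_pooled):
        """With no censoring the exponential-rate posterior is Gamma(d, T)
        up to the (negligible) width of the near-flat location prior."""
        cfg = McmcConfig(chains=3, iterations=2000, warmup=500, seed=7)
        fit = sample_posterior(small_exponential_pooled, "exponential", cfg)
        lam = np.exp(-fit.flat_draws[:, 0])
        d = small_exponential_pooled.data["event"].sum()
        T = small_exponential_pooled.data["time_months"].sum()
        # flat prior on -log(rate) implies p(rate) ~ 1/rate -> Gamma(d, T)
        assert lam.mean() == pytest.approx(d / T, rel=0.02)
        assert lam.std() == pytest.approx(np.sqrt(d) / T, rel=0.12)

    def test_posterior_mean_near_mle_two_arms(self):
        """Two-arm exponential data: posterior log-rate within 3 posterior
        SDs of the maximum-likelihood estimate in each arm."""
        pooled = make_two_arm_pooled(
            3,
            family="exponential",
            beta0=np.log(14.0),
            delta=0.3,
            ancillary=None,
            n_per_arm=2000,
            censor_month=1e9,
            accrual_months=0.0,
        )
        cfg = McmcConfig(chains=3, iterations=800, warmup=400, seed=5)
        fit = sample_posterior(pooled, "exponential", cfg)
        df = pooled.data
        for trt, col in ((pooled.reference, None), ("combo", "combo")):
            sub = df[df["treatment"] == trt]
            mle = np.log(sub["time_months"].sum() / sub["event"].sum())
            loc = fit.location_draws(trt)
            assert abs(loc.mean() - mle) < 3 * loc.std()

    def test_empty_or_eventless_data_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(
                _pooled([], [], []), "exponential", McmcConfig(2, 200, 100)
            )
        with pytest.raises(ValueError, match="no events"):
            sample_posterior(
                _pooled([1.0, 2.0], [1, 0], ["sorafenib", "x"]),
                "exponential",
                McmcConfig(2, 200, 100),
            )


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        fit = make_fixed_fit(jitter=0.0, n_draws=200)
        rng = np.random.default_rng(5)
        pooled = _pooled(
            rng.lognormal(2.5, 0.8, 30),
            np.ones(30),
            ["sorafenib"] * 15 + ["combo"] * 15,
        )
        dic, p_d = compute_dic(fit, pooled)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        # DIC reduces to the deviance at the fixed parameter point
        from survpool.families import loglik_censored

        d0 = -2.0 * loglik_censored(pooled.data, fit.posterior_mean_params())
        assert dic == pytest.approx(d0, rel=1e-12)

    def test_matches_brute_force_on_discrete_pseudo_posterior(self):
        """Three-point pseudo-posterior on 20 records: DIC equals a direct
        evaluation of mean deviance + pD with scipy likelihoods."""
        rng = np.random.default_rng(9)
        times = rng.lognormal(2.2, 0.7, 20)
        events = rng.integers(0, 2, 20)
        events[:5] = 1
        trts = ["sorafenib"] * 10 + ["combo"] * 10
        pooled = _pooled(times, events, trts)
        points = np.array(
            [[2.3, 0.2, np.log(0.7)], [2.5, 0.4, np.log(0.9)], [2.1, 0.3, np.log(0.8)]]
        )
        draws = np.tile(points, (34, 1))[:102]  # >=100 draws, 3 support points
        fit = make_fixed_fit(n_draws=4)
        fit.draws = draws.reshape(2, 51, 3)

        def loglik(theta):
            total = 0.0
            for t, e, trt in zip(times, events, trts):
                mu = theta[0] + (theta[1] if trt == "combo" else 0.0)
                d = stats.lognorm(np.exp(theta[2]), scale=np.exp(mu))
                total += np.log(d.pdf(t)) if e else np.log(d.sf(t))
            return total

        dev = np.array([-2 * loglik(th) for th in draws])
        theta_bar = draws.mean(axis=0)
        pd_expected = dev.mean() - (-2 * loglik(theta_bar))
        dic_expected = dev.mean() + pd_expected

        dic, p_d = compute_dic(fit, pooled)
        assert dic == pytest.approx(dic_expected, rel=1e-9)
        assert p_d == pytest.approx(pd_expected, rel=1e-6)

    def test_invariant_to_draw_permutation(self):
        rng = np.random.default_rng(2)
        fit = make_fixed_fit(jitter=0.05, n_draws=200)
        pooled = _pooled(
            rng.lognormal(2.5, 0.8, 40),
            np.ones(40),
            ["sorafenib"] * 20 + ["combo"] * 20,
        )
        dic1, pd1 = compute_dic(fit, pooled)
        perm = rng.permutation(200)
        fit.draws = fit.flat_draws[perm].reshape(fit.draws.shape)
        dic2, pd2 = compute_dic(fit, pooled)
        assert dic2 == pytest.approx(dic1, rel=1e-12)
        assert pd2 == pytest.approx(pd1, rel=1e-9)

    def test_requires_enough_draws(self):
        fit = make_fixed_fit(n_draws=40)
        pooled = _pooled([5.0], [1], ["sorafenib"])
        with pytest.raises(ValueError, match="100 draws"):
            compute_dic(fit, pooled)

    def test_monte_carlo_stability_under_doubling(self):
        """Doubling post-warmup draws moves DIC by well under 0.5%."""
        pooled = make_two_arm_pooled(17, n_per_arm=150)
        f1 = sample_posterior(
            pooled, "lognormal", McmcConfig(chains=3, iterations=1500, warmup=750, seed=3)
        )
        f2 = sample_posterior(
            pooled, "lognormal", McmcConfig(chains=3, iterations=2250, warmup=750, seed=3)
        )
        assert abs(f1.dic - f2.dic) / abs(f1.dic) < 0.005


class TestSelectModel:
    def test_argmin_by_dic(self):
        a = make_fixed_fit(family="weibull")
        b = make_fixed_fit(family="lognormal")
        a.dic, b.dic = 105.2, 98.1
        sel = select_model([a, b])
        assert sel.family == "lognormal"
        assert not sel.tie
        assert set(sel.table["family"]) == {"weibull", "lognormal"}

    def test_tie_breaks_to_canonical_order_with_flag(self):
        a = make_fixed_fit(family="lognormal")
        b = make_fixed_fit(family="weibull")
        a.dic = b.dic = 100.0
        sel = select_model([a, b])
        assert sel.family == "weibull"  # weibull precedes lognormal canonically
        assert sel.tie

    def test_mixed_endpoints_rejected(self):
        a = make_fixed_fit(family="weibull")
        b = make_fixed_fit(family="lognormal")
        b.endpoint = "PFS"
        with pytest.raises(ValueError, match="endpoint"):
            select_model([a, b])
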