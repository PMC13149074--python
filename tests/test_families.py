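"""Closed-form and cross-library checks of the five parametric families."""

import numpy as np
import pytest
from scipy import stats

from survpool.families import (
    FAMILIES,
    ParamVector,
    hazard,
    loglik_censored,
    quantile,
    survival,
)

from conftest import ipd_frame


def _params(family, loc=2.3, anc=1.4, beta=None):
    return ParamVector(
        family,
        beta0=loc,
        beta=beta or {},
        ancillary=None if family == "exponential" else anc,
    )


def _scipy_dist(family, loc, anc):
    """Independent reference distribution for each parameterization."""
    if family == "exponential":
        return stats.expon(scale=np.exp(loc))
    if family == "weibull":
        return stats.weibull_min(anc, scale=np.exp(loc))
    if family == "gamma":
        return stats.gamma(anc, scale=np.exp(loc))
    if family == "loglogistic":
        return stats.fisk(anc, scale=np.exp(loc))
    return stats.lognorm(anc, scale=np.exp(loc))


class TestSurvival:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_boundary_at_zero(self, family):
        assert survival(family, _params(family), None, 0.0) == 1.0

    def test_lognormal_median_symmetry(self):
        p = ParamVector("lognormal", beta0=2.5, beta={"a": 0.3}, ancillary=0.8)
        assert survival("lognormal", p, "a", np.exp(2.8)) == pytest.approx(0.5)

    def test_lognormal_closed_form_value(self):
        # 1 - Phi((ln 20 - 2.5)/0.8)
        p = ParamVector("lognormal", beta0=2.5, ancillary=0.8)
        expected = 1.0 - stats.norm.cdf((np.log(20.0) - 2.5) / 0.8)
        assert survival("lognormal", p, None, 20.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.268, abs=5e-4)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_scipy_sf(self, family):
        p = _params(family)
        d = _scipy_dist(family, p.beta0, p.ancillary)
        t = np.array([0.5, 3.0, 11.0, 40.0])
        np.testing.assert_allclose(
            survival(family, p, None, t), d.sf(t), rtol=1e-10
        )

    @pytest.mark.parametrize("family", FAMILIES)
    def test_non_increasing(self, family):
        t = np.linspace(0.0, 80.0, 400)
        s = survival(family, _params(family), None, t)
        assert np.all(np.diff(s) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival("weibull", _params("weibull"), None, -1.0)


class TestHazard:
    def test_exponential_constant(self):
        p = ParamVector("exponential", beta0=np.log(10.0))
        t = np.array([0.5, 5.0, 50.0])
        np.testing.assert_allclose(hazard("exponential", p, None, t), 0.1)

    def test_weibull_closed_form(self):
        # shape 2, scale 10: h(5) = (2/10)(5/10)^1 = 0.1
        p = ParamVector("weibull", beta0=np.log(10.0), ancillary=2.0)
        assert hazard("weibull", p, None, 5.0) == pytest.approx(0.1)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_neg_dlog_sf(self, family):
        """h(t) agrees with the central finite difference of -log S."""
        p = _params(family)
        t = np.linspace(1.0, 40.0, 25)
        eps = 1e-5
        fd = (
            np.log(survival(family, p, None, t - eps))
            - np.log(survival(family, p, None, t + eps))
        ) / (2 * eps)
        np.testing.assert_allclose(hazard(family, p, None, t), fd, rtol=1e-4)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_cumulative_hazard_identity(self, family):
        """Trapezoid integral of h equals -log S on a fine grid."""
        p = _params(family)
        t = np.linspace(1e-4, 30.0, 20000)
        h = hazard(family, p, None, t)
        cumh = np.concatenate([[0.0], np.cumsum(np.diff(t) * (h[1:] + h[:-1]) / 2)])
        target = -np.log(survival(family, p, None, t)) + np.log(
            survival(family, p, None, t[0])
        )
        np.testing.assert_allclose(cumh, target, atol=1e-3)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            hazard("lognormal", _params("lognormal"), None, 0.0)


class TestQuantile:
    def test_lognormal_median(self):
        p = ParamVector("lognormal", beta0=2.5, beta={"a": 0.3}, ancillary=0.8)
        assert quantile("lognormal", p, "a", 0.5) == pytest.approx(np.exp(2.8))

    def test_exponential_mean_scale(self):
        lam = 0.25
        p = ParamVector("exponential", beta0=np.log(1 / lam))
        assert quantile("exponential", p, None, 1 - np.exp(-1)) == pytest.approx(
            1 / lam
        )

    def test_inverse_round_trip(self):
        """survival(quantile(p)) = 1 - p for 100 random (family, params, p)."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            family = FAMILIES[rng.integers(5)]
            p = _params(
                family,
                loc=rng.uniform(0.5, 3.5),
                anc=rng.uniform(0.5, 3.0),
            )
            prob = rng.uniform(0.01, 0.99)
            t = quantile(family, p, None, prob)
            assert survival(family, p, None, t) == pytest.approx(
                1 - prob, abs=1e-8
            )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_probability_domain(self, bad):
        with pytest.raises(ValueError):
            quantile("weibull", _params("weibull"), None, bad)


class TestAftStructure:
    @pytest.mark.parametrize("family", ["lognormal", "loglogistic"])
    def test_effect_scales_median(self, family):
        """Adding delta to the location multiplies the median by e^delta."""
        delta = 0.45
        base = _params(family, anc=1.1)
        shifted = _params(family, anc=1.1, beta={"a": delta})
        m0 = quantile(family, base, None, 0.5)
        m1 = quantile(family, shifted, "a", 0.5)
        assert m1 / m0 == pytest.approx(np.exp(delta), rel=1e-10)

    def test_exponential_nests_in_weibull_and_gamma(self):
        """With shape pinned at 1, all three likelihoods coincide."""
        rng = np.random.default_rng(3)
        data = ipd_frame(rng.exponential(12.0, 40), rng.integers(0, 2, 40))
        loc = 2.4
        ll_exp = loglik_censored(data, ParamVector("exponential", beta0=loc))
        ll_wei = loglik_censored(
            data, ParamVector("weibull", beta0=loc, ancillary=1.0)
        )
        ll_gam = loglik_censored(
            data, ParamVector("gamma", beta0=loc, ancillary=1.0)
        )
        assert ll_exp == pytest.approx(ll_wei, rel=1e-12)
        assert ll_exp == pytest.approx(ll_gam, rel=1e-10)


class TestLoglik:
    def test_empty_data(self):
        assert loglik_censored(ipd_frame([], []), _params("weibull")) == 0.0

    def test_single_exponential_event(self):
        lam, t = 0.2, 7.0
        p = ParamVector("exponential", beta0=-np.log(lam))
        assert loglik_censored(ipd_frame([t], [1]), p) == pytest.approx(
            np.log(lam) - lam * t
        )

    @pytest.mark.parametrize("family", FAMILIES)
    def test_brute_force_sum_and_permutation(self, family):
        """Equals the per-record scipy sum and is order-invariant."""
        rng = np.random.default_rng(11)
        n = 50
        times = rng.uniform(0.5, 40.0, n)
        events = rng.integers(0, 2, n)
        trts = rng.choice(["ref", "a", "b"], n)
        p = ParamVector(
            family,
            beta0=2.2,
            beta={"a": 0.3, "b": -0.2},
            ancillary=None if family == "exponential" else 1.3,
        )
        df = ipd_frame(times, events)
        df["treatment"] = trts
        expected = 0.0
        for t, e, trt in zip(times, events, trts):
            d = _scipy_dist(family, p.location(trt), p.ancillary)
            expected += np.log(d.pdf(t)) if e else np.log(d.sf(t))
        assert loglik_censored(df, p) == pytest.approx(expected, rel=1e-9)
        shuffled = df.sample(frac=1, random_state=5).reset_index(drop=True)
        assert loglik_censored(shuffled, p) == pytest.approx(
            loglik_censored(df, p), rel=1e-12
        )

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ParamVector("gompertz", beta0=1.0, ancillary=1.0)
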