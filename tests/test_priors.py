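import math

import numpy as np
import pytest
from scipy import integrate, stats

from bcnma.priors import (
    IPDPriors,
    LassoPrior,
    PriorConfig,
    SSVSPrior,
    conditional_laplace_logdensity,
    indicator_full_conditional,
    laplace_logdensity,
    spike_slab_logdensity,
)


class TestSpikeSlab:
    def test_spike_at_mode(self):
        # N(0, 0.1^2) log-density at 0
        expected = math.log(1.0 / (0.1 * math.sqrt(2 * math.pi)))
        assert spike_slab_logdensity(0.0, 0, eta=0.1, g=100) == pytest.approx(
            expected, abs=1e-12
        )

    def test_slab_at_mode(self):
        # slab sd = g * eta = 10
        expected = math.log(1.0 / (10.0 * math.sqrt(2 * math.pi)))
        assert spike_slab_logdensity(0.0, 1, eta=0.1, g=100) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("indicator,sd", [(0, 0.1), (1, 10.0)])
    def test_matches_scipy_normal(self, indicator, sd):
        d = np.linspace(-3, 3, 41)
        ours = spike_slab_logdensity(d, indicator, eta=0.1, g=100)
        assert np.allclose(ours, stats.norm.logpdf(d, scale=sd), atol=1e-10)

    @pytest.mark.parametrize("indicator", [0, 1])
    def test_integrates_to_one(self, indicator):
        val, _ = integrate.quad(
            lambda d: math.exp(spike_slab_logdensity(d, indicator, eta=0.1, g=100)),
            -np.inf,
            np.inf,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mixture_arithmetic(self):
        # marginal density at 0 with P(I=1)=0.5 from the two closed forms
        spike = math.exp(spike_slab_logdensity(0.0, 0, eta=0.1, g=100))
        slab = math.exp(spike_slab_logdensity(0.0, 1, eta=0.1, g=100))
        mix = 0.5 * spike + 0.5 * slab
        assert math.log(mix) == pytest.approx(math.log(0.5 * 3.98942 + 0.5 * 0.03989),
                                              abs=1e-4)

    def test_g_to_one_collapses_mixture(self):
        d = np.linspace(-2, 2, 21)
        lo = spike_slab_logdensity(d, 0, eta=0.3, g=1 + 1e-12)
        hi = spike_slab_logdensity(d, 1, eta=0.3, g=1 + 1e-12)
        assert np.allclose(lo, hi, atol=1e-9)

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            spike_slab_logdensity(0.0, 0, eta=-1.0, g=100)


class TestIndicatorConditional:
    def test_density_ratio_formula(self):
        # at d=0 the spike dominates: 0.03989/(0.03989+3.98942)
        got = indicator_full_conditional(0.0, eta=0.1, g=100, prior_p=0.5)
        num = stats.norm.pdf(0, scale=10.0) * 0.5
        den = num + stats.norm.pdf(0, scale=0.1) * 0.5
        assert got == pytest.approx(num / den, abs=1e-12)
        assert got == pytest.approx(0.0099, abs=1e-4)

    def test_large_effect_goes_to_slab(self):
        assert indicator_full_conditional(50.0, eta=0.1, g=100, prior_p=0.5) > 1 - 1e-9

    def test_monotone_in_prior_and_effect(self):
        lo = indicator_full_conditional(0.0, eta=0.1, g=100, prior_p=0.5)
        hi = indicator_full_conditional(0.0, eta=0.1, g=100, prior_p=0.8)
        assert hi > lo
        d = np.linspace(0, 5, 50)
        vals = indicator_full_conditional(d, eta=0.1, g=100, prior_p=0.5)
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            indicator_full_conditional(0.0, eta=0.1, g=100, prior_p=1.0)


class TestLaplace:
    def test_closed_form_values(self):
        assert laplace_logdensity(0.0, lam=2.0) == pytest.approx(0.0, abs=1e-14)
        assert laplace_logdensity(1.0, lam=2.0) == pytest.approx(-2.0, abs=1e-12)

    def test_matches_scipy(self):
        d = np.linspace(-4, 4, 33)
        ours = laplace_logdensity(d, lam=0.7)
        assert np.allclose(ours, stats.laplace.logpdf(d, scale=1 / 0.7), atol=1e-10)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda d: math.exp(laplace_logdensity(d, 0.7)), -np.inf, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            laplace_logdensity(0.0, lam=0.0)


class TestConditionalLaplace:
    def test_zero_coefficients(self):
        lam, sigma = 1.3, 0.8
        got = conditional_laplace_logdensity(np.zeros(2), lam, sigma)
        assert got == pytest.approx(2 * math.log(lam / (2 * sigma)), abs=1e-12)

    def test_exponent_scaling(self):
        lam, sigma = 2.0, 1.5
        g = np.array([0.7])
        d1 = conditional_laplace_logdensity(g, lam, sigma)
        d2 = conditional_laplace_logdensity(2 * g, lam, sigma)
        assert d2 - d1 == pytest.approx(-lam * abs(g[0]) / sigma**2, abs=1e-12)

    def test_park_casella_convention_normalizes(self):
        lam, sigma = 1.7, 0.9
        val, _ = integrate.quad(
            lambda g: math.exp(
                conditional_laplace_logdensity([g], lam, sigma, "park-casella")
            ),
            -np.inf,
            np.inf,
        )
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_sigma_squared_convention_integrates_to_sigma(self):
        # the default exponent convention is not normalized: its one-coordinate
        # integral equals sigma, documented behaviour
        lam, sigma = 1.7, 0.9
        val, _ = integrate.quad(
            lambda g: math.exp(
                conditional_laplace_logdensity([g], lam, sigma, "sigma-squared")
            ),
            -np.inf,
            np.inf,
        )
        assert val == pytest.approx(sigma, abs=1e-10)

    def test_requires_common_sigma_mode(self):
        with pytest.raises(ValueError, match="common sigma"):
            IPDPriors(gamma_shrinkage="conditional-laplace", common_sigma=False)


class TestPriorConfig:
    def test_tau_lognormal_density_integrates_to_one(self):
        cfg = PriorConfig()
        val, _ = integrate.quad(
            lambda t: math.exp(cfg.log_tau_prior(t)), 1e-9, 50.0
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_lasso_inverse_uniform_support(self):
        lp = LassoPrior()
        assert lp.log_prior(0.1) == -np.inf  # 1/lambda > 5 excluded
        assert np.isfinite(lp.log_prior(1.0))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SSVSPrior(g=0.5)
        with pytest.raises(ValueError):
            PriorConfig(d_sd=-1)
        with pytest.raises(ValueError):
            PriorConfig(tau_prior="beta")

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text(
            "d_sd: 5\ntau_prior: half-normal\nssvs:\n  g: 50\nlasso:\n"
            "  inv_uniform_upper: 3\n"
        )
        cfg = PriorConfig.from_yaml(p)
        assert cfg.d_sd == 5
        assert cfg.tau_prior == "half-normal"
        assert cfg.ssvs.g == 50
        assert cfg.lasso.inv_uniform_upper == 3
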