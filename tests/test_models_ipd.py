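import numpy as np
import pytest

from bcnma.datamodel import ComponentCatalog, DataError, TreatmentCombination
from bcnma.mcmc import MCMCSettings
from bcnma.models_ipd import (
    IPDModelSpec,
    ad_metaregression_mean,
    fit_joint,
    loglik_ipd_patient,
    mix_imputation_draws,
)


def combo(*cs):
    return TreatmentCombination(frozenset(cs))


@pytest.fixture
def cat():
    return ComponentCatalog(("c1", "c2", "c3", "c4"))


@pytest.fixture
def global_params():
    # gamma rows follow catalog order c1..c4, one covariate column
    return {
        "beta": np.array([0.5]),
        "gamma": np.array([[0.2], [0.1], [-0.3], [0.4]]),
    }


class TestPatientLoglik:
    def test_zero_covariates_reduce_to_alpha(self, cat, global_params):
        spec = IPDModelSpec()
        ref = combo("c1", "c2")
        sp = {"alpha": 1.5, "delta": {}, "sigma": 1.0}
        ll = loglik_ipd_patient(
            (1.5, ref, np.zeros(1)), sp, global_params, spec, ref, cat
        )
        # y == mean == alpha: maximal normal log-density
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_gamma_zero_is_plain_additive(self, cat):
        spec = IPDModelSpec()
        ref = combo("c1")
        other = combo("c3", "c4")
        gp = {"beta": np.array([0.5]), "gamma": np.zeros((4, 1))}
        x = np.array([2.0])
        sp = {"alpha": 0.3, "delta": {other.canonical(cat): 0.7}, "sigma": 1.0}
        y = 0.3 + 0.5 * 2.0 + 0.7  # alpha + beta x + delta
        ll = loglik_ipd_patient((y, other, x), sp, gp, spec, ref, cat)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_same_combination_arms_cancel_gamma(self, cat, global_params):
        # patient in the reference arm: gamma contrast is identically zero
        spec = IPDModelSpec()
        ref = combo("c1", "c3")
        x = np.array([1.7])
        sp = {"alpha": 0.0, "delta": {}, "sigma": 1.0}
        y = 0.5 * 1.7
        ll = loglik_ipd_patient((y, ref, x), sp, global_params, spec, ref, cat)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_effect_modification_enters_contrast(self, cat, global_params):
        spec = IPDModelSpec()
        ref = combo("c1")
        arm = combo("c3")
        x = np.array([1.0])
        delta = 0.4
        sp = {"alpha": 0.0, "delta": {arm.canonical(cat): delta}, "sigma": 1.0}
        # mean = beta x + (gamma_3 - gamma_1) x + delta
        mean = 0.5 + (-0.3 - 0.2) + delta
        ll = loglik_ipd_patient((mean, arm, x), sp, global_params, spec, ref, cat)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_covariate_mismatch_rejected(self, cat, global_params):
        spec = IPDModelSpec()
        ref = combo("c1")
        sp = {"alpha": 0.0, "delta": {}, "sigma": 1.0}
        with pytest.raises(DataError, match="mismatch"):
            loglik_ipd_patient(
                (0.0, ref, np.zeros(3)), sp, global_params, spec, ref, cat
            )


class TestADMetaRegression:
    def test_zero_covariate_means_unadjusted(self):
        assert ad_metaregression_mean(0.7, [1.0, -1.0], [0.0, 0.0]) == pytest.approx(0.7)

    def test_cancelling_shift(self):
        got = ad_metaregression_mean(0.7, [1.0, -1.0], [0.5, 0.5])
        assert got == pytest.approx(0.7)

    def test_flag_off_ignores_xbar(self):
        got = ad_metaregression_mean(0.7, [1.0], [5.0], enabled=False)
        assert got == pytest.approx(0.7)

    def test_missing_xbar_with_flag_on(self):
        with pytest.raises(DataError, match="covariate"):
            ad_metaregression_mean(0.7, [1.0], None)


class TestSpecValidation:
    def test_conditional_laplace_needs_common_sigma(self):
        with pytest.raises(DataError, match="common sigma"):
            IPDModelSpec(gamma_shrinkage="conditional-laplace", sigma_mode="per-study")

    def test_interactions_need_component_level(self):
        with pytest.raises(DataError, match="component-level"):
            IPDModelSpec(component_level=False, interaction_mode="ssvs")


class TestMixImputationDraws:
    def _fit(self, ds_ipd, seed):
        return fit_joint(
            ds_ipd,
            IPDModelSpec(),
            MCMCSettings(seed=seed, chains=1, iterations=100, burnin=50),
        )

    def test_draw_counts_concatenate(self, ds_ipd):
        fits = [self._fit(ds_ipd, s) for s in (1, 2, 3)]
        mixed = mix_imputation_draws(fits)
        assert mixed.params["d"].shape[0] == 3  # chains stacked
        assert mixed.params["d"].shape[0] * mixed.params["d"].shape[1] == 300
        assert mixed.meta["n_imputations"] == 3

    def test_identity_for_single_fit(self, ds_ipd):
        fit = self._fit(ds_ipd, 1)
        assert mix_imputation_draws([fit]) is fit

    def test_mixed_mean_is_average_of_fit_means(self, ds_ipd):
        fits = [self._fit(ds_ipd, s) for s in (1, 2)]
        mixed = mix_imputation_draws(fits)
        per_fit = np.array([f.stacked("tau").mean() for f in fits])
        assert mixed.stacked("tau").mean() == pytest.approx(per_fit.mean(), abs=1e-12)

    def test_block_mismatch_rejected(self, ds_ipd):
        f1 = self._fit(ds_ipd, 1)
        f2 = self._fit(ds_ipd, 2)
        f2 = mix_imputation_draws([f2])  # identity, still same blocks
        del f2.params["tau"]
        with pytest.raises(DataError, match="disagree"):
            mix_imputation_draws([f1, f2])


class TestFitJoint:
    def test_ad_only_component_fit_matches_fit_ad(self, ds_additive):
        """With no IPD studies the joint model reduces to the AD model."""
        from bcnma.models_ad import ADModelSpec, fit_ad
        from bcnma.summaries import relative_effect

        m = MCMCSettings(seed=11, chains=1, iterations=800, burnin=400)
        dj = fit_joint(ds_additive, IPDModelSpec(), m)
        da = fit_ad(ds_additive, ADModelSpec(), m)
        e1 = relative_effect(dj, "a + b", "c")
        e2 = relative_effect(da, "a + b", "c")
        # same model, different sampling routes (latent vs marginalized deltas)
        assert e1.mean == pytest.approx(e2.mean, abs=0.1)

    def test_binary_outcome_runs_and_recovers_sign(self, truth_ipd):
        """Bernoulli-logit IPD likelihood: strong effect has the right sign."""
        import numpy as np
        from bcnma.datamodel import IPDStudy, NetworkDataset

        rng = np.random.default_rng(5)
        cat = ComponentCatalog(("a", "b"))
        A, B = combo("a"), combo("b")
        studies = []
        for i in range(3):
            patients = []
            for arm, c, lp in ((0, A, 0.0), (1, B, 1.5)):
                for _ in range(80):
                    y = float(rng.uniform() < 1 / (1 + np.exp(-lp)))
                    patients.append((y, c, np.zeros(0)))
            studies.append(IPDStudy(f"s{i}", patients))
        ds = NetworkDataset(catalog=cat, ipd=studies)
        draws = fit_joint(
            ds,
            IPDModelSpec(outcome="binary"),
            MCMCSettings(seed=3, chains=1, iterations=400, burnin=300),
        )
        eff = draws.stacked("d")[:, 1] - draws.stacked("d")[:, 0]
        assert eff.mean() > 0.5
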