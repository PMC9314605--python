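import numpy as np
import pytest

from bcnma.datamodel import ComponentCatalog, DataError, NetworkDataset, \
    ADContrastStudy, TreatmentCombination
from bcnma.design import all_pairs, build_design
from bcnma.mcmc import PosteriorDraws, split_rhat
from bcnma.summaries import prediction_table, relative_effect, summarize


def combo(*cs):
    return TreatmentCombination(frozenset(cs))


def _draws_from_d(d_draws: np.ndarray, catalog, design, **extra) -> PosteriorDraws:
    params = {"d": d_draws[None]}  # one chain
    coords = {"d": list(catalog.codes)}
    for name, arr in extra.items():
        params[name] = arr[None]
        if name == "gamma":
            coords["gamma"] = [f"{c}:x1" for c in catalog.codes]
        if name == "d_pairs":
            coords["d_pairs"] = [f"{p}.{q}" for p, q in design.interactions.pairs]
    return PosteriorDraws(params=params, coords=coords, design=design, scale="MD")


@pytest.fixture
def toy_design():
    cat = ComponentCatalog(("c1", "c2", "c3"))
    studies = [
        ADContrastStudy("s1", [(combo("c1"), None, None), (combo("c2"), 0.1, 0.2)]),
        ADContrastStudy("s2", [(combo("c2"), None, None), (combo("c3"), 0.1, 0.2)]),
        ADContrastStudy(
            "s3", [(combo("c1"), None, None), (combo("c1", "c2"), 0.1, 0.2)]
        ),
    ]
    ds = NetworkDataset(catalog=cat, ad_contrast=studies)
    return cat, build_design(ds)


class TestSummarize:
    def test_degenerate_draws(self, toy_design):
        cat, design = toy_design
        d = np.full((50, 3), 2.5)
        tab = summarize(_draws_from_d(d, cat, design))
        row = tab[tab.parameter == "d[c1]"].iloc[0]
        assert row["mean"] == row["median"] == 2.5
        assert row.ci_low == row.ci_high == 2.5

    def test_standard_normal_quantiles(self, toy_design):
        cat, design = toy_design
        rng = np.random.default_rng(0)
        d = rng.standard_normal((200_000, 3))
        tab = summarize(_draws_from_d(d, cat, design))
        row = tab[tab.parameter == "d[c2]"].iloc[0]
        assert row.ci_low == pytest.approx(-1.96, abs=0.03)
        assert row.ci_high == pytest.approx(1.96, abs=0.03)

    def test_rhat_of_identical_chains_is_one(self):
        # identical chains contribute no between-chain variance, so split-Rhat
        # reduces to the within-chain half-split statistic, ~1 for a
        # well-mixed series and exactly 1 for a degenerate one
        chain = np.random.default_rng(1).standard_normal(400)
        draws = np.stack([chain, chain])
        assert split_rhat(draws) == pytest.approx(1.0, abs=0.01)
        assert split_rhat(np.full((2, 100), 3.14)) == 1.0


class TestRelativeEffect:
    def test_self_comparison_is_exactly_zero(self, toy_design):
        cat, design = toy_design
        d = np.random.default_rng(2).standard_normal((100, 3))
        est = relative_effect(_draws_from_d(d, cat, design), "c1 + c2", "c1 + c2")
        assert est.mean == est.median == 0.0
        assert est.ci_low == est.ci_high == 0.0

    def test_single_draw_arithmetic(self, toy_design):
        cat, design = toy_design
        d = np.array([[1.0, 2.0, 0.0]])
        est = relative_effect(_draws_from_d(d, cat, design), "c1 + c2", "c1")
        assert est.mean == pytest.approx(2.0, abs=1e-12)

    def test_antisymmetry_draw_by_draw(self, toy_design):
        cat, design = toy_design
        d = np.random.default_rng(3).standard_normal((500, 3))
        draws = _draws_from_d(d, cat, design)
        ab = relative_effect(draws, "c1", "c2")
        ba = relative_effect(draws, "c2", "c1")
        assert ab.mean == pytest.approx(-ba.mean, abs=1e-12)
        assert ab.ci_low == pytest.approx(-ba.ci_high, abs=1e-12)

    def test_transitivity_on_linear_scale(self, toy_design):
        cat, design = toy_design
        d = np.random.default_rng(4).standard_normal((500, 3))
        draws = _draws_from_d(d, cat, design)
        ac = relative_effect(draws, "c1", "c3").mean
        ab = relative_effect(draws, "c1", "c2").mean
        bc = relative_effect(draws, "c2", "c3").mean
        assert ac == pytest.approx(ab + bc, abs=1e-12)

    def test_common_component_never_changes_estimate(self, toy_design):
        cat, design = toy_design
        d = np.random.default_rng(5).standard_normal((500, 3))
        draws = _draws_from_d(d, cat, design)
        plain = relative_effect(draws, "c1", "c2")
        augmented = relative_effect(draws, "c1 + c3", "c2 + c3")
        assert plain.mean == pytest.approx(augmented.mean, abs=1e-12)

    def test_unknown_component_rejected(self, toy_design):
        cat, design = toy_design
        d = np.zeros((10, 3))
        with pytest.raises(DataError, match="unknown"):
            relative_effect(_draws_from_d(d, cat, design), "zz", "c1")

    def test_or_scale_requires_log_odds_fit(self, toy_design):
        cat, design = toy_design
        d = np.zeros((10, 3))
        with pytest.raises(DataError, match="scale"):
            relative_effect(_draws_from_d(d, cat, design), "c1", "c2", scale="OR")

    def test_or_scale_exponentiates(self, toy_design):
        cat, design = toy_design
        d = np.array([[1.0, 2.0, 0.0]])
        draws = _draws_from_d(d, cat, design)
        draws.scale = "logOR"
        est = relative_effect(draws, "c2", "c1", scale="OR")
        assert est.mean == pytest.approx(np.e, abs=1e-12)
        assert est.scale == "OR"

    def test_covariate_profile_uses_gamma_and_centering(self, toy_design):
        cat, design = toy_design
        d = np.zeros((1, 3))
        gamma = np.array([[0.0, 1.0, 0.0]])  # c2 modifies effect by 1 per unit x1
        draws = _draws_from_d(d, cat, design, gamma=gamma)
        draws.covariate_names = ("x1",)
        draws.covariate_means = np.array([10.0])
        est = relative_effect(draws, "c2", "c1", covariate_profile={"x1": 12.0})
        # gamma contrast (c2 - c1) . centered x = 1 * (12 - 10)
        assert est.mean == pytest.approx(2.0, abs=1e-12)

    def test_profile_at_means_matches_unconditional(self, toy_design):
        cat, design = toy_design
        rng = np.random.default_rng(6)
        d = rng.standard_normal((200, 3))
        gamma = rng.standard_normal((200, 3))
        draws = _draws_from_d(d, cat, design, gamma=gamma)
        draws.covariate_names = ("x1",)
        draws.covariate_means = np.array([3.0])
        at_mean = relative_effect(draws, "c2", "c1", covariate_profile={"x1": 3.0})
        plain = relative_effect(draws, "c2", "c1")
        assert at_mean.mean == pytest.approx(plain.mean, abs=1e-12)

    def test_inestimable_contrast_flagged(self):
        # c3 never appears in any study: contrasts involving it are prior-driven
        cat = ComponentCatalog(("c1", "c2", "c3"))
        studies = [
            ADContrastStudy("s1", [(combo("c1"), None, None), (combo("c2"), 0.1, 0.2)])
        ]
        design = build_design(NetworkDataset(catalog=cat, ad_contrast=studies))
        d = np.zeros((10, 3))
        est = relative_effect(_draws_from_d(d, cat, design), "c3", "c1")
        assert not est.estimable
        assert "prior" in est.warning


class TestPredictionTable:
    def test_cross_product_shape(self, toy_design):
        cat, design = toy_design
        d = np.random.default_rng(7).standard_normal((50, 3))
        draws = _draws_from_d(d, cat, design)
        tab = prediction_table(
            draws, [None, None], [("c1", "c2"), ("c2", "c3"), ("c1", "c3")]
        )
        assert len(tab) == 6

    def test_empty_comparisons(self, toy_design):
        cat, design = toy_design
        d = np.zeros((10, 3))
        tab = prediction_table(_draws_from_d(d, cat, design), [None], [])
        assert len(tab) == 0
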