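import numpy as np
import pytest

from bcnma.datamodel import (
    ADArmStudy,
    ADContrastStudy,
    ComponentCatalog,
    DataError,
    IPDStudy,
    NetworkDataset,
    TreatmentCombination,
    parse_combination,
    read_dataset,
    validate_network,
    write_dataset,
)


@pytest.fixture
def panic_catalog():
    return ComponentCatalog(
        ("wl", "pl", "ftf", "pe", "ps", "br", "mr", "ive", "ine", "vre", "cr", "w3")
    )


class TestParseCombination:
    def test_multi_component_label(self, panic_catalog):
        combo = parse_combination("pl + ftf + pe + ps + ive", panic_catalog)
        assert combo.members == {"pl", "ftf", "pe", "ps", "ive"}

    def test_singleton(self, panic_catalog):
        assert parse_combination("wl", panic_catalog).members == {"wl"}

    @pytest.mark.parametrize(
        "label,err",
        [
            ("pl+pl", "duplicate"),
            ("pl + xx", "unknown"),
            ("", "empty"),
            ("pl + + ftf", "malformed"),
        ],
    )
    def test_rejections(self, panic_catalog, label, err):
        with pytest.raises(DataError, match=err):
            parse_combination(label, panic_catalog)

    def test_case_and_whitespace_insensitive(self, panic_catalog):
        a = parse_combination("PL+ftf", panic_catalog)
        b = parse_combination(" pl +  FTF ", panic_catalog)
        assert a.members == b.members == {"pl", "ftf"}

    def test_canonical_order_is_catalog_order(self, panic_catalog):
        combo = parse_combination("ive + pl + wl", panic_catalog)
        assert combo.canonical(panic_catalog) == "wl + pl + ive"


class TestCatalog:
    def test_duplicate_codes_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            ComponentCatalog(("a", "b", "A"))

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            ComponentCatalog(())


class TestStudyValidation:
    def test_invalid_event_count(self, panic_catalog):
        wl = parse_combination("wl", panic_catalog)
        pl = parse_combination("pl", panic_catalog)
        with pytest.raises(DataError, match="invalid event count"):
            ADArmStudy("s1", [(wl, 5, 10), (pl, 12, 10)], binary=True)

    def test_nonpositive_se(self, panic_catalog):
        wl = parse_combination("wl", panic_catalog)
        pl = parse_combination("pl", panic_catalog)
        with pytest.raises(DataError, match="se"):
            ADContrastStudy("s1", [(wl, None, None), (pl, 0.5, 0.0)])

    def test_single_arm_ipd_rejected(self, panic_catalog):
        wl = parse_combination("wl", panic_catalog)
        with pytest.raises(DataError, match="distinct combinations"):
            IPDStudy("s1", [(0.1, wl, np.zeros(2)), (0.2, wl, np.zeros(2))])

    def test_missing_covariates_rejected(self, panic_catalog):
        wl = parse_combination("wl", panic_catalog)
        pl = parse_combination("pl", panic_catalog)
        with pytest.raises(DataError, match="missing covariate"):
            IPDStudy(
                "s1",
                [(0.1, wl, np.array([np.nan])), (0.2, pl, np.array([0.5]))],
            )


class TestRoundTrip:
    def test_ad_round_trip(self, tmp_path, ds_interaction):
        paths = write_dataset(ds_interaction, tmp_path)
        back = read_dataset(paths["catalog"], ad_contrast=paths["ad_contrast"])
        assert back.catalog.codes == ds_interaction.catalog.codes
        assert len(back.ad_contrast) == len(ds_interaction.ad_contrast)
        for a, b in zip(ds_interaction.ad_contrast, back.ad_contrast):
            assert a.study_id == b.study_id
            for (ca, ya, sa), (cb, yb, sb) in zip(a.arms, b.arms):
                assert ca.members == cb.members
                if ya is not None:
                    assert yb == pytest.approx(ya)
                    assert sb == pytest.approx(sa)

    def test_ipd_round_trip_and_centering(self, tmp_path, ds_ipd):
        paths = write_dataset(ds_ipd, tmp_path)
        back = read_dataset(
            paths["catalog"], ad_contrast=paths.get("ad_contrast"), ipd=paths["ipd"]
        )
        xs = np.array([p[2] for st in back.ipd for p in st.patients])
        # stored covariates are already centered; reloading re-centers them,
        # which is a no-op on centered data
        assert np.allclose(xs.mean(axis=0), 0.0, atol=1e-9)
        orig = np.array([p[2] for st in ds_ipd.ipd for p in st.patients])
        assert np.allclose(np.sort(xs, axis=0), np.sort(orig, axis=0), atol=1e-9)

    def test_centering_pool_is_ipd_patients(self, ds_ipd):
        xs = np.array([p[2] for st in ds_ipd.ipd for p in st.patients])
        assert np.allclose(xs.mean(axis=0), 0.0, atol=1e-9)
        assert ds_ipd.covariate_means is not None


class TestReadErrors:
    def test_r_greater_than_n_rejected(self, tmp_path):
        (tmp_path / "catalog.csv").write_text("code\na\nb\n")
        (tmp_path / "ad_arm.csv").write_text(
            "study_id,arm_label,r,n\ns1,a,5,10\ns1,b,12,10\n"
        )
        with pytest.raises(DataError, match="invalid event count"):
            read_dataset(tmp_path / "catalog.csv", ad_arm=tmp_path / "ad_arm.csv")

    def test_empty_dataset_rejected(self, tmp_path):
        (tmp_path / "catalog.csv").write_text("code\na\n")
        with pytest.raises(DataError, match="no studies"):
            read_dataset(tmp_path / "catalog.csv")


class TestValidateNetwork:
    def test_connected_simple_network(self):
        cat = ComponentCatalog(("a", "b"))
        A = TreatmentCombination(frozenset(["a"]))
        B = TreatmentCombination(frozenset(["b"]))
        st = ADContrastStudy("s1", [(A, None, None), (B, 0.3, 0.2)])
        rep = validate_network(NetworkDataset(catalog=cat, ad_contrast=[st]))
        assert rep.connected
        assert rep.never_varies == []

    def test_disconnected_subnetworks_share_components(self):
        cat = ComponentCatalog(("a", "b", "c"))

        def combo(*cs):
            return TreatmentCombination(frozenset(cs))

        s1 = ADContrastStudy("s1", [(combo("a"), None, None), (combo("b"), 0.1, 0.2)])
        s2 = ADContrastStudy(
            "s2", [(combo("a", "c"), None, None), (combo("b", "c"), 0.2, 0.2)]
        )
        rep = validate_network(NetworkDataset(catalog=cat, ad_contrast=[s1, s2]))
        assert len(rep.subnetworks) == 2  # treatment-level disconnection
        assert rep.component_usage["a"] == 2  # but components are shared

    def test_component_never_varying_within_study_is_flagged(self):
        # "c" is present in all arms of every study that has it
        cat = ComponentCatalog(("a", "b", "c"))

        def combo(*cs):
            return TreatmentCombination(frozenset(cs))

        s1 = ADContrastStudy(
            "s1", [(combo("a", "c"), None, None), (combo("b", "c"), 0.1, 0.2)]
        )
        s2 = ADContrastStudy("s2", [(combo("a"), None, None), (combo("b"), 0.2, 0.2)])
        rep = validate_network(NetworkDataset(catalog=cat, ad_contrast=[s1, s2]))
        assert rep.never_varies == ["c"]
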