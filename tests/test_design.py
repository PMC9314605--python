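import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcnma.datamodel import (
    ADContrastStudy,
    ComponentCatalog,
    DataError,
    NetworkDataset,
    TreatmentCombination,
)
from bcnma.design import (
    InteractionSet,
    all_pairs,
    build_design,
    contrast_design_row,
    estimability,
)

from ._oracles import exact_rank


@pytest.fixture
def cat4():
    return ComponentCatalog(("c1", "c2", "c3", "c4"))


def combo(*cs):
    return TreatmentCombination(frozenset(cs))


class TestContrastDesignRow:
    def test_disjoint_combinations(self, cat4):
        row = contrast_design_row(combo("c1", "c2"), combo("c3", "c4"), cat4)
        assert row.tolist() == [-1, -1, 1, 1]

    def test_self_comparison_is_zero(self, cat4):
        row = contrast_design_row(combo("c1", "c2"), combo("c1", "c2"), cat4)
        assert not row.any()

    def test_shared_component_cancels_pair_appears(self, cat4):
        inter = InteractionSet(pairs=(("c1", "c2"),))
        row = contrast_design_row(combo("c1"), combo("c1", "c2"), cat4, inter)
        assert row[:4].tolist() == [0, 1, 0, 0]
        assert row[4:].tolist() == [1]  # pair present in Y only

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.sets(st.sampled_from(["c1", "c2", "c3", "c4"]), min_size=1),
        y=st.sets(st.sampled_from(["c1", "c2", "c3", "c4"]), min_size=1),
        z=st.sets(st.sampled_from(["c1", "c2", "c3", "c4"]), min_size=1),
    )
    def test_antisymmetry_and_transitivity(self, x, y, z):
        cat = ComponentCatalog(("c1", "c2", "c3", "c4"))
        inter = all_pairs(cat)
        X, Y, Z = combo(*x), combo(*y), combo(*z)
        rxy = contrast_design_row(X, Y, cat, inter)
        ryx = contrast_design_row(Y, X, cat, inter)
        assert np.array_equal(rxy, -ryx)
        rxz = contrast_design_row(X, Z, cat, inter)
        ryz = contrast_design_row(Y, Z, cat, inter)
        assert np.array_equal(rxz, rxy + ryz)


class TestInteractionSet:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            InteractionSet(pairs=(("a", "b"), ("b", "a")))

    def test_self_pair_rejected(self):
        with pytest.raises(DataError, match="repeats"):
            InteractionSet(pairs=(("a", "a"),))

    def test_inclusion_probability_lookup(self):
        s = InteractionSet(
            pairs=(("a", "b"), ("c", "d")), prior_inclusion={("b", "a"): 0.8}
        )
        assert s.inclusion_prob(("a", "b")) == 0.8
        assert s.inclusion_prob(("c", "d")) == 0.5


class TestBuildDesign:
    def test_dimensions(self, ds_interaction, truth_default):
        inter = all_pairs(truth_default.catalog)
        design = build_design(ds_interaction, inter)
        n_contrasts = sum(st.n_arms - 1 for st in ds_interaction.ad_contrast)
        assert design.contrast_rows.shape == (n_contrasts, 6 + 15)

    def test_two_arm_study_gives_one_row(self):
        cat = ComponentCatalog(("a", "b"))
        st = ADContrastStudy(
            "s1", [(combo("a"), None, None), (combo("b"), 0.1, 0.2)]
        )
        design = build_design(NetworkDataset(catalog=cat, ad_contrast=[st]))
        assert design.contrast_rows.shape == (1, 2)

    def test_never_cooccurring_pair_column_is_flagged(self):
        cat = ComponentCatalog(("a", "b"))
        st = ADContrastStudy("s1", [(combo("a"), None, None), (combo("b"), 0.1, 0.2)])
        inter = InteractionSet(pairs=(("a", "b"),))
        design = build_design(NetworkDataset(catalog=cat, ad_contrast=[st]), inter)
        assert design.zero_pairs == [("a", "b")]


class TestEstimability:
    def _dataset_from_comparisons(self, cat, comparisons):
        studies = []
        for i, (x, y) in enumerate(comparisons):
            studies.append(
                ADContrastStudy(f"s{i}", [(x, None, None), (y, 0.1, 0.2)])
            )
        return NetworkDataset(catalog=cat, ad_contrast=studies)

    def test_always_coadministered_components(self, cat4):
        # c1 and c2 only ever appear together: d1, d2 inestimable, d1+d2 estimable
        ds = self._dataset_from_comparisons(
            cat4,
            [(combo("c3"), combo("c1", "c2")), (combo("c3"), combo("c4"))],
        )
        design = build_design(ds)
        rep = estimability(
            design,
            queries=[
                (combo("c1", "c2"), combo("c3")),  # jointly: estimable
                (combo("c1"), combo("c3")),  # individually: not
            ],
        )
        assert rep.rank < rep.n_params
        flat = rep.flat_parameters()
        assert "c1" in flat and "c2" in flat
        assert rep.query_estimable == [True, False]

    def test_saturated_toy_network_full_rank(self):
        # all 4 subsets of {c1,c2} (incl. an explicit control) pairwise compared
        cat = ComponentCatalog(("c0", "c1", "c2"))
        subsets = [
            combo("c0"),
            combo("c0", "c1"),
            combo("c0", "c2"),
            combo("c0", "c1", "c2"),
        ]
        comparisons = list(itertools.combinations(subsets, 2))
        ds = self._dataset_from_comparisons(cat, comparisons)
        inter = InteractionSet(pairs=(("c1", "c2"),))
        design = build_design(ds, inter)
        rep = estimability(design)
        # c0 is in every arm, so its main effect cancels everywhere
        oracle = exact_rank(design.contrast_rows)
        assert rep.rank == oracle == 3  # c1, c2, c1.c2
        queries = [(a, b) for a, b in comparisons]
        rep2 = estimability(design, queries=queries)
        assert all(rep2.query_estimable)

    def test_within_study_comparisons_always_estimable(self, ds_interaction):
        design = build_design(ds_interaction)
        queries = []
        for st in ds_interaction.ad_contrast[:10]:
            queries.append((st.arms[1][0], st.arms[0][0]))
        rep = estimability(design, queries=queries)
        assert all(rep.query_estimable)

    def test_rank_matches_exact_oracle(self, ds_interaction, truth_default):
        inter = all_pairs(truth_default.catalog)
        design = build_design(ds_interaction, inter)
        assert estimability(design).rank == exact_rank(design.contrast_rows)
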