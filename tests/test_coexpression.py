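"""Tissue averaging, correlation, edge selection and network construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from xtissue.coexpression import (
    CorrelationMatrix,
    average_by_tissue,
    build_network,
    cross_tissue_correlation,
    select_edges,
    select_focal_edges,
    subset_correlation,
)
from xtissue.core import (
    ExpressionMatrix,
    GeneSetCatalog,
    SampleDesign,
    TissueProfile,
    XTissueError,
)

from _oracles import pearson


def make_catalog(classes):
    table = pd.DataFrame(
        {
            "family": ["F"] * len(classes),
            "gene_class": list(classes.values()),
            "adme_status": ["none"] * len(classes),
        },
        index=list(classes),
    )
    return GeneSetCatalog(table)


class TestAverageByTissue:
    def test_single_sample_tissues_pass_through(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        design = SampleDesign(
            pd.Series(["liver", "gut"], index=["s1", "s2"]), tissue_group_map={}
        )
        profile = average_by_tissue(ExpressionMatrix(df), design)
        assert profile.data.at["g1", "liver"] == 1.0
        assert profile.data.at["g2", "gut"] == 4.0

    def test_two_sample_mean(self):
        df = pd.DataFrame(
            [[2.0, 4.0], [1.0, 5.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        design = SampleDesign(
            pd.Series(["A", "A"], index=["s1", "s2"]), tissue_group_map={}
        )
        profile = average_by_tissue(ExpressionMatrix(df), design)
        assert profile.data.at["g1", "A"] == 3.0

    def test_matches_group_mean_oracle(self, random_expression):
        expr, design = random_expression
        profile = average_by_tissue(expr, design)
        for t in design.tissues:
            cols = design.tissue.index[design.tissue == t]
            expected = expr.data[cols].to_numpy().mean(axis=1)
            np.testing.assert_allclose(profile.data[t].to_numpy(), expected)


class TestCorrelation:
    def test_affine_examples(self):
        data = pd.DataFrame(
            {
                "t1": [1, 2, 4, 1],
                "t2": [2, 4, 3, 3],
                "t3": [3, 6, 2, 2],
                "t4": [4, 8, 1, 4],
            },
            index=["A", "B", "C", "D"],
            dtype=float,
        )
        corr = cross_tissue_correlation(TissueProfile(data))
        assert corr.data.at["A", "B"] == pytest.approx(1.0)
        assert corr.data.at["A", "C"] == pytest.approx(-1.0)
        # direct covariance/variance formula oracle for a non-affine pair
        assert corr.data.at["A", "D"] == pytest.approx(0.8)
        assert corr.data.at["A", "D"] == pytest.approx(
            pearson([1, 2, 3, 4], [1, 3, 2, 4])
        )

    def test_zero_variance_gene_flagged_undefined(self):
        data = pd.DataFrame(
            {"t1": [1.0, 5.0], "t2": [2.0, 5.0], "t3": [3.0, 5.0]},
            index=["g1", "flat"],
        )
        corr = cross_tissue_correlation(TissueProfile(data))
        assert corr.undefined == {"flat"}
        assert np.isnan(corr.data.at["g1", "flat"])

    def test_needs_three_tissues(self):
        data = pd.DataFrame({"t1": [1.0, 2.0], "t2": [2.0, 1.0]}, index=["a", "b"])
        with pytest.raises(XTissueError, match="3 tissues"):
            cross_tissue_correlation(TissueProfile(data))

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            float,
            (6, 5),
            elements=st.floats(0.1, 100, allow_nan=False),
        )
    )
    def test_symmetry_and_unit_diagonal(self, values):
        data = pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(6)],
            columns=[f"t{i}" for i in range(5)],
        )
        corr = cross_tissue_correlation(TissueProfile(data))
        m = corr.data.to_numpy()
        defined = ~np.isnan(m)
        assert np.allclose(m[defined], m.T[defined], atol=1e-12)
        for i, g in enumerate(corr.gene_ids):
            if g not in corr.undefined:
                assert m[i, i] == pytest.approx(1.0, abs=1e-12)
                assert np.all(np.abs(m[i][defined[i]]) <= 1 + 1e-12)


def random_corr(rng, n=10):
    profile = TissueProfile(
        pd.DataFrame(
            rng.gamma(2, 5, (n, 6)),
            index=[f"g{i:02d}" for i in range(n)],
            columns=[f"t{i}" for i in range(6)],
        )
    )
    return cross_tissue_correlation(profile)


class TestSelectEdges:
    def test_threshold_above_max_gives_empty(self, rng):
        corr = random_corr(rng)
        assert len(select_edges(corr, "threshold", 0.999999)) == 0

    def test_k_equals_all_pairs_returns_every_defined_pair(self, rng):
        corr = random_corr(rng, n=8)
        edges = select_edges(corr, "top_k", 28)
        assert len(edges) == 28

    def test_top_k_matches_full_sort_oracle(self, rng):
        corr = random_corr(rng, n=10)
        edges = select_edges(corr, "top_k", 7)
        ranked = sorted(
            (
                (corr.data.at[g1, g2], g1, g2)
                for g1, g2 in itertools.combinations(sorted(corr.gene_ids), 2)
            ),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        expected = [(g1, g2) for _, g1, g2 in ranked[:7]]
        assert list(zip(edges["gene1"], edges["gene2"])) == expected

    def test_invariant_to_gene_ordering(self, rng):
        corr = random_corr(rng, n=9)
        perm = list(rng.permutation(corr.gene_ids))
        shuffled = CorrelationMatrix(corr.data.loc[perm, perm], corr.undefined)
        a = select_edges(corr, "top_k", 5)
        b = select_edges(shuffled, "top_k", 5)
        pd.testing.assert_frame_equal(a, b)

    def test_boundary_ties_all_included(self):
        data = pd.DataFrame(
            np.array(
                [
                    [1.0, 0.9, 0.9, 0.2],
                    [0.9, 1.0, 0.9, 0.2],
                    [0.9, 0.9, 1.0, 0.2],
                    [0.2, 0.2, 0.2, 1.0],
                ]
            ),
            index=list("abcd"),
            columns=list("abcd"),
        )
        edges = select_edges(CorrelationMatrix(data), "top_k", 2)
        assert len(edges) == 3  # three pairs tied at 0.9 straddle the cut

    @pytest.mark.parametrize("mode,value", [("top_k", 0), ("threshold", 1.2)])
    def test_invalid_parameters(self, rng, mode, value):
        with pytest.raises(XTissueError):
            select_edges(random_corr(rng), mode, value)


class TestSubset:
    def test_all_classes_is_identity(self, rng):
        corr = random_corr(rng, n=6)
        catalog = make_catalog({g: "SLC" for g in corr.gene_ids})
        sub = subset_correlation(corr, catalog, {"SLC"})
        pd.testing.assert_frame_equal(sub.data, corr.data)

    def test_intersection_semantics(self, rng):
        corr = random_corr(rng, n=6)
        classes = {g: "other" for g in corr.gene_ids}
        for g in corr.gene_ids[:4]:
            classes[g] = "SLC"
        classes["absent_gene"] = "SLC"
        catalog = make_catalog(classes)
        sub = subset_correlation(corr, catalog, {"SLC"})
        assert sub.data.shape == (4, 4)

    def test_empty_result_is_an_error(self, rng):
        corr = random_corr(rng, n=4)
        catalog = make_catalog({g: "other" for g in corr.gene_ids})
        with pytest.raises(XTissueError):
            subset_correlation(corr, catalog, {"ABC"})

    def test_subset_then_correlate_commutes(self, rng):
        profile = TissueProfile(
            pd.DataFrame(
                rng.gamma(2, 5, (8, 5)),
                index=[f"g{i}" for i in range(8)],
                columns=[f"t{i}" for i in range(5)],
            )
        )
        keep = [f"g{i}" for i in range(4)]
        catalog = make_catalog(
            {f"g{i}": ("SLC" if i < 4 else "other") for i in range(8)}
        )
        a = subset_correlation(
            cross_tissue_correlation(profile), catalog, {"SLC"}
        )
        b = cross_tissue_correlation(profile, genes=keep)
        pd.testing.assert_frame_equal(a.data, b.data)


def test_subset_first_order_yields_at_least_as_many_edges(rng):
    corr = random_corr(rng, n=12)
    classes = {g: ("SLC" if i % 2 else "other") for i, g in enumerate(corr.gene_ids)}
    catalog = make_catalog(classes)
    a = select_focal_edges(corr, catalog, {"SLC"}, "top_k", 8, order="subset_first")
    b = select_focal_edges(corr, catalog, {"SLC"}, "top_k", 8, order="select_first")
    assert len(a) >= len(b)


class TestBuildNetwork:
    def test_empty_edge_list_gives_empty_network(self):
        edges = pd.DataFrame(columns=["gene1", "gene2", "r"])
        catalog = make_catalog({"a": "SLC"})
        net = build_network(edges, catalog)
        assert net.number_of_nodes() == 0

    def test_node_count_equals_distinct_endpoints(self, rng):
        genes = [f"g{i}" for i in range(12)]
        pairs = set()
        while len(pairs) < 9:
            a, b = rng.choice(genes, 2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        edges = pd.DataFrame(
            [(a, b, 0.5) for a, b in sorted(pairs)],
            columns=["gene1", "gene2", "r"],
        )
        catalog = make_catalog({g: "SLC" for g in genes})
        net = build_network(edges, catalog)
        expected_nodes = {g for p in pairs for g in p}
        assert set(net.nodes) == expected_nodes
        assert net.number_of_edges() == len(pairs)
        assert net.nodes[edges.at[0, "gene1"]]["gene_class"] == "SLC"
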