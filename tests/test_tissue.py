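"""Tissue assignment, proximity counting, dendrogram ordering, edge fractions."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from xtissue.coexpression import cross_tissue_correlation
from xtissue.core import TissueProfile, XTissueError
from xtissue.tissue import (
    UNDETERMINED,
    assign_edge_tissue,
    assign_gene_tissue,
    assign_tissues,
    cluster_proximity,
    control_fractions,
    focal_edge_fraction,
    hierarchical_order,
    proximity_total,
)

from _oracles import average_linkage_heights


class TestGeneAssignment:
    def test_single_tissue_expression(self, small_profile):
        assert assign_gene_tissue(small_profile, "g3") == "gut"

    def test_exact_tie_breaks_lexicographically(self, small_profile):
        # g2: kidney == liver == 7 -> kidney
        assert assign_gene_tissue(small_profile, "g2") == "kidney"

    def test_all_zero_gene_is_undetermined(self, small_profile):
        assert assign_gene_tissue(small_profile, "g5") == UNDETERMINED

    def test_matches_linear_scan_oracle(self, rng):
        data = pd.DataFrame(
            rng.gamma(2, 5, (20, 7)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"t{i}" for i in range(7)],
        )
        profile = TissueProfile(data)
        bulk = assign_tissues(profile)
        for g in data.index:
            best, best_t = -1.0, None
            for t in sorted(data.columns):
                if data.at[g, t] > best:
                    best, best_t = data.at[g, t], t
            assert assign_gene_tissue(profile, g) == best_t == bulk[g]


class TestEdgeAssignment:
    def test_pairwise_mean_argmax(self):
        data = pd.DataFrame(
            {"kidney": [0.0, 5.0], "liver": [10.0, 4.0]}, index=["s", "t"]
        )
        profile = TissueProfile(data)
        label, argmax = assign_edge_tissue(profile, ("s", "t"))
        assert (label, argmax) == ("liver", "liver")  # pair means (2.5, 7)

    def test_focus_restriction_maps_to_other(self, small_profile):
        label, argmax = assign_edge_tissue(
            small_profile, ("g4", "g5"), focus_tissues=("gut", "kidney")
        )
        assert label == "other" and argmax == "lung"

    def test_symmetric_in_endpoint_order(self, rng):
        data = pd.DataFrame(
            rng.gamma(2, 5, (6, 5)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"t{i}" for i in range(5)],
        )
        profile = TissueProfile(data)
        for g1, g2 in [("g0", "g3"), ("g2", "g5")]:
            assert assign_edge_tissue(profile, (g1, g2)) == assign_edge_tissue(
                profile, (g2, g1)
            )

    def test_matches_pairwise_mean_oracle(self, rng):
        data = pd.DataFrame(
            rng.gamma(2, 5, (8, 5)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"t{i}" for i in range(5)],
        )
        profile = TissueProfile(data)
        for g1, g2 in [("g0", "g1"), ("g3", "g7"), ("g4", "g6")]:
            mean = (data.loc[g1] + data.loc[g2]) / 2
            _, argmax = assign_edge_tissue(profile, (g1, g2))
            assert argmax == mean.idxmax()


class TestProximity:
    def test_direct_count_example(self):
        net = nx.Graph([("g1", "g2"), ("g1", "g3"), ("g3", "g4")])
        assignment = pd.Series(
            {"g1": "L", "g2": "L", "g3": "K", "g4": "G"}
        )
        prox = cluster_proximity(net, assignment)
        assert prox.at["L", "L"] == 1
        assert prox.at["K", "L"] == 1 == prox.at["L", "K"]
        assert prox.at["G", "K"] == 1
        assert proximity_total(prox) == 3

    def test_single_tissue_network(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        prox = cluster_proximity(net, pd.Series({"a": "L", "b": "L", "c": "L"}))
        assert prox.shape == (1, 1) and prox.at["L", "L"] == 2

    def test_conservation_on_random_network(self, rng):
        genes = [f"g{i}" for i in range(30)]
        net = nx.gnm_random_graph(30, 80, seed=1)
        net = nx.relabel_nodes(net, dict(enumerate(genes)))
        assignment = pd.Series(
            rng.choice(["A", "B", "C", "D"], size=30), index=genes
        )
        prox = cluster_proximity(net, assignment)
        assert proximity_total(prox) == net.number_of_edges()

    def test_fixed_universe_adds_zero_rows(self):
        net = nx.Graph([("a", "b")])
        assignment = pd.Series({"a": "L", "b": "L"})
        prox = cluster_proximity(net, assignment, tissues=["L", "K", "G"])
        assert list(prox.index) == ["G", "K", "L"]
        assert prox.at["K", "K"] == 0


class TestHierarchicalOrder:
    def test_two_tissues_single_merge(self):
        prox = pd.DataFrame(
            [[5, 1], [1, 7]], index=["gut", "liver"], columns=["gut", "liver"]
        )
        order = hierarchical_order(prox)
        assert sorted(order.tissues) == ["gut", "liver"]
        assert order.linkage.shape == (1, 4)

    def test_identical_rows_merge_first(self):
        prox = pd.DataFrame(
            [[4, 4, 1], [4, 4, 1], [1, 1, 9]],
            index=["gut", "liver", "testis"],
            columns=["gut", "liver", "testis"],
        )
        order = hierarchical_order(prox)
        first = {order.labels[int(order.linkage[0, 0])],
                 order.labels[int(order.linkage[0, 1])]}
        assert first == {"gut", "liver"}
        assert order.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_heights_match_naive_average_linkage(self, rng):
        n = 5
        prox = pd.DataFrame(
            rng.integers(0, 40, (n, n)),
            index=[f"t{i}" for i in range(n)],
            columns=[f"t{i}" for i in range(n)],
        )
        prox = prox + prox.T  # symmetrize
        order = hierarchical_order(prox)
        values = prox.to_numpy(dtype=float)
        corr = np.corrcoef(values)
        dist = np.clip(1 - corr, 0, 2)
        np.fill_diagonal(dist, 0)
        expected = average_linkage_heights(dist)
        np.testing.assert_allclose(
            sorted(order.linkage[:, 2]), expected, atol=1e-9
        )

    def test_constant_row_pinned_to_max_distance(self):
        prox = pd.DataFrame(
            [[3, 1, 0], [1, 5, 0], [0, 0, 0]],
            index=["gut", "liver", "heart"],
            columns=["gut", "liver", "heart"],
        )
        order = hierarchical_order(prox)
        assert order.linkage[-1, 2] == pytest.approx(2.0)


def profile_and_corr(data):
    profile = TissueProfile(data)
    return profile, cross_tissue_correlation(profile)


class TestEdgeFraction:
    def make_liver_profile(self, rng):
        # every gene maximal in liver, correlated pairs
        base = rng.gamma(2, 1, size=6)
        data = pd.DataFrame(
            {
                "gut": base * 0.1,
                "kidney": base * 0.2,
                "liver": base * 2.0,
                "lung": base * 0.15,
            },
            index=[f"g{i}" for i in range(6)],
        )
        return data

    def test_all_liver_genes_give_fraction_one(self, rng):
        profile, corr = profile_and_corr(self.make_liver_profile(rng))
        res = focal_edge_fraction(
            corr, list(profile.gene_ids), 5, profile, ("liver",)
        )
        assert res.fraction == 1.0

    def test_no_target_hits_gives_zero(self, rng):
        profile, corr = profile_and_corr(self.make_liver_profile(rng))
        res = focal_edge_fraction(
            corr, list(profile.gene_ids), 5, profile, ("gut",)
        )
        assert res.fraction == 0.0

    def test_control_single_rep_has_zero_sd(self, rng):
        profile, corr = profile_and_corr(self.make_liver_profile(rng))
        res = control_fractions(
            corr, list(profile.gene_ids), 4, 3, profile, ("liver",), reps=1
        )
        assert res.sd == 0.0

    def test_degenerate_pool_equals_focal_fraction(self, rng):
        profile, corr = profile_and_corr(self.make_liver_profile(rng))
        genes = list(profile.gene_ids)
        focal = focal_edge_fraction(corr, genes, 5, profile, ("liver",))
        ctrl = control_fractions(
            corr, genes, len(genes), 5, profile, ("liver",), reps=3
        )
        assert ctrl.mean == focal.fraction and ctrl.sd == 0.0

    def test_seeded_sampling_reproducible(self, rng):
        profile, corr = profile_and_corr(self.make_liver_profile(rng))
        kw = dict(reps=4, seed=9)
        a = control_fractions(
            corr, list(profile.gene_ids), 4, 3, profile, ("liver",), **kw
        )
        b = control_fractions(
            corr, list(profile.gene_ids), 4, 3, profile, ("liver",), **kw
        )
        assert a.samples == b.samples

    def test_oversized_sample_rejected(self, rng):
        profile, corr = profile_and_corr(self.make_liver_profile(rng))
        with pytest.raises(XTissueError):
            control_fractions(
                corr, list(profile.gene_ids), 99, 3, profile, ("liver",)
            )
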