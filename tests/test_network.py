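import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coinv import (
    DosageState,
    build_network,
    motif_census,
    motif_enrichment,
    pairwise_contrasts,
    replicated_g,
    replicated_g_from_crosses,
    sdv_interaction_summary,
    significant_subgraph,
)
from coinv.network import rewired_nulls

from _oracles import brute_force_motif_census


class TestMotifCensus:
    def test_triangle_graph(self):
        g = nx.complete_graph(3)
        c = motif_census(g)
        assert c["triangle"] == 1
        assert c["path_3"] == 0

    def test_three_leaf_star(self):
        g = nx.star_graph(3)  # hub + 3 leaves
        c = motif_census(g)
        assert c["path_3"] == 3
        assert c["triangle"] == 0
        assert c["star_4"] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        g = nx.gnp_random_graph(n, 0.35, seed=seed)
        assert motif_census(g) == brute_force_motif_census(g)

    def test_graph_smaller_than_motif_size(self):
        g = nx.path_graph(2)
        c = motif_census(g)
        assert all(v == 0 for v in c.values())


class TestRewiringNull:
    def test_degree_sequence_preserved_in_every_replicate(self):
        g = nx.gnp_random_graph(20, 0.25, seed=5)
        degrees = dict(g.degree)
        for h in rewired_nulls(g, R=25, swaps_per_edge=10, seed=1):
            assert dict(h.degree) == degrees

    def test_disjoint_triangles_enriched(self):
        g = nx.disjoint_union_all([nx.complete_graph(3) for _ in range(6)])
        df = motif_enrichment(g, R=200, min_count=1, seed=2).set_index("motif")
        assert df.loc["triangle", "Z"] > 3
        assert df.loc["triangle", "ratio"] > 1.5

    def test_random_graph_shows_no_enrichment(self):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        df = motif_enrichment(g, R=300, min_count=1, seed=8)
        adj = df["p_adj"].dropna()
        assert (adj >= 0.05).all()

    def test_min_count_filter_excludes_scarce_motifs(self):
        g = nx.path_graph(6)
        df = motif_enrichment(g, R=50, min_count=200, seed=0)
        assert not df["included"].any()
        assert df["p_adj"].isna().all()


class TestReplicatedG:
    def test_identical_proportional_tables_give_zero(self):
        t = np.array([[10.0, 20.0], [20.0, 40.0]])
        rg = replicated_g([t, t, t])
        assert rg.G_total == pytest.approx(0.0, abs=1e-9)
        assert rg.G_pooled == pytest.approx(0.0, abs=1e-9)
        assert rg.G_het == pytest.approx(0.0, abs=1e-9)

    @given(st.lists(st.tuples(*[st.integers(1, 30)] * 4), min_size=2, max_size=9))
    @settings(max_examples=60, deadline=None)
    def test_decomposition_identity(self, tables):
        ts = [np.array(t, dtype=float).reshape(2, 2) for t in tables]
        rg = replicated_g(ts)
        assert rg.G_total == pytest.approx(rg.G_pooled + rg.G_het, abs=1e-9)
        assert rg.df_total == rg.df_pooled + rg.df_het

    def test_degenerate_cross_contributes_zero_df(self):
        good = np.array([[10.0, 5.0], [5.0, 10.0]])
        empty_row = np.array([[8.0, 7.0], [0.0, 0.0]])
        rg = replicated_g([good, empty_row])
        assert rg.df_total == 1
        assert rg.per_cross[1] == (0.0, 0, 1.0)

    def test_opposite_associations_show_up_as_heterogeneity(self):
        a = np.array([[30.0, 10.0], [10.0, 30.0]])
        b = np.array([[10.0, 30.0], [30.0, 10.0]])
        rg = replicated_g([a, b])
        assert rg.G_pooled == pytest.approx(0.0, abs=1e-9)
        assert rg.p_het < 0.001

    def test_from_crosses_runs_on_synthetic_study(self):
        from coinv import simulate_study
        from coinv.io import HET, HOM_INV

        crosses, _, _ = simulate_study(seed=3, plant_effects=False)
        rg = replicated_g_from_crosses(
            crosses, DosageState("Inv_40", HET), DosageState("Inv_32", HOM_INV)
        )
        assert rg.df_total <= 9
        assert rg.G_total == pytest.approx(rg.G_pooled + rg.G_het, abs=1e-9)


@pytest.fixture(scope="module")
def planted_contrasts(repulsion_cross):
    pr = pairwise_contrasts(repulsion_cross, "Inv_1", "Inv_2", B=2000, seed=4)
    return pr.contrasts


class TestNetworkBuild:
    def test_planted_repulsion_edge_present_and_negative(self, planted_contrasts):
        g = build_network(planted_contrasts)
        assert ("Inv_1_2", "Inv_2_2") in g.edges
        d = g.edges["Inv_1_2", "Inv_2_2"]
        assert d["weight"] < 0
        assert d["sign"] == -1

    def test_significant_subgraph_is_edge_subset(self, planted_contrasts):
        g = build_network(planted_contrasts)
        sig = significant_subgraph(g)
        assert set(sig.edges) <= set(g.edges)
        assert all(d["significant"] for _, _, d in sig.edges(data=True))

    def test_centrality_invariant_under_relabeling(self, planted_contrasts):
        g = build_network(planted_contrasts)
        relabeled = nx.relabel_nodes(g, {n: f"x_{n}" for n in g.nodes})
        from coinv.network import _attach_centrality

        _attach_centrality(relabeled)
        for n in g.nodes:
            assert relabeled.nodes[f"x_{n}"]["centrality"] == pytest.approx(
                g.nodes[n]["centrality"], abs=1e-9
            )

    def test_empty_contrast_list_gives_empty_network(self):
        g = build_network([])
        assert g.number_of_nodes() == 0


class TestSdvInteraction:
    def test_perfect_rank_agreement(self):
        sd = pd.DataFrame({"locus": ["a", "b", "c", "d"], "SDV": [1.0, 2.0, 3.0, 4.0]})
        omnibus = pd.DataFrame(
            {
                "locus_a": ["a", "b", "c", "d"],
                "locus_b": ["x", "x", "x", "x"],
                "p": [0.8, 0.4, 0.2, 0.01],
            }
        )
        per_locus, corr = sdv_interaction_summary(sd, omnibus)
        assert corr["rho_meanp"] == pytest.approx(-1.0)
        assert len(per_locus) == 4

    def test_constant_sdv_leaves_correlation_undefined(self):
        sd = pd.DataFrame({"locus": list("abc"), "SDV": [1.0, 1.0, 1.0]})
        omnibus = pd.DataFrame(
            {"locus_a": list("abc"), "locus_b": ["x"] * 3, "p": [0.1, 0.5, 0.9]}
        )
        _, corr = sdv_interaction_summary(sd, omnibus)
        assert np.isnan(corr["rho_count"])

    def test_locus_without_pairs_excluded(self):
        sd = pd.DataFrame({"locus": ["a", "b"], "SDV": [1.0, 2.0]})
        omnibus = pd.DataFrame({"locus_a": ["a"], "locus_b": ["x"], "p": [0.2]})
        per_locus, _ = sdv_interaction_summary(sd, omnibus)
        assert per_locus["locus"].tolist() == ["a"]
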