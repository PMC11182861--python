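import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from volatilink import (
    EdgeSet,
    ValidationError,
    extract_clusters,
    holm_adjust,
    holm_adjust_matrix,
    select_significant_edges,
    spearman_all_pairs,
)


def frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestSpearman:
    def test_monotone_columns_hit_plus_minus_one(self):
        data = frame({"up": [1.0, 2, 3, 5, 9], "expup": np.exp([1.0, 2, 3, 5, 9]), "down": [9.0, 5, 3, 2, 1]})
        rho, p = spearman_all_pairs(data)
        assert rho.loc["up", "expup"] == pytest.approx(1.0)
        assert rho.loc["up", "down"] == pytest.approx(-1.0)
        assert p.loc["up", "expup"] < 1e-20

    def test_tied_ranks_match_hand_oracle(self):
        """Average-rank Pearson computed by hand for a tied vector."""
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0])  # hand-assigned average ranks
        ry = np.array([1.0, 2.0, 3.0, 4.0])
        num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
        den = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
        rho, _ = spearman_all_pairs(frame({"x": x, "y": y}))
        assert rho.loc["x", "y"] == pytest.approx(num / den, abs=1e-15)

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        data.iloc[0, 0] = data.iloc[1, 0]  # introduce a tie
        rho, p = spearman_all_pairs(data)
        ref_rho, ref_p = stats.spearmanr(data.to_numpy())
        np.testing.assert_allclose(rho.to_numpy(), ref_rho, atol=1e-12)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(p.to_numpy()[iu], ref_p[iu], atol=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        rho1, _ = spearman_all_pairs(data)
        transformed = data.copy()
        transformed["a"] = np.exp(transformed["a"])
        transformed["b"] = stats.rankdata(transformed["b"])
        rho2, _ = spearman_all_pairs(transformed)
        assert rho1.loc["a", "b"] == pytest.approx(rho2.loc["a", "b"], abs=1e-12)

    def test_constant_column_undefined_and_excluded_from_family(self):
        data = frame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [4.0, 3, 2, 1]})
        rho, p = spearman_all_pairs(data)
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(p.loc["a", "b"])
        adj = holm_adjust_matrix(p)
        assert np.isnan(adj.loc["a", "b"])
        # family has a single defined pair, so Holm leaves it unscaled
        assert adj.loc["a", "c"] == pytest.approx(p.loc["a", "c"])

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValidationError, match=">= 4 samples"):
            spearman_all_pairs(frame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]}))


class TestHolm:
    def test_worked_triples(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])
        np.testing.assert_allclose(holm_adjust([0.05, 0.05, 0.05]), [0.15, 0.15, 0.15])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.5])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 200))
    def test_dominates_raw_and_monotone(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


def edge_set(pairs, kinds):
    rows = []
    for a, b, rho in pairs:
        a, b = sorted((a, b))
        rows.append(
            {"compound_a": a, "compound_b": b, "rho": rho, "p_raw": 0.001, "p_adj": 0.01,
             "sign": "positive" if rho > 0 else "negative"}
        )
    edges = pd.DataFrame(rows, columns=["compound_a", "compound_b", "rho", "p_raw", "p_adj", "sign"])
    return EdgeSet(edges=edges, universe=list(kinds), kinds=pd.Series(kinds))


class TestEdgeSelection:
    def setup_method(self):
        cols = ["a", "b", "c"]
        self.kinds = {c: "metabolite" for c in cols}
        self.rho = pd.DataFrame(
            [[1.0, 0.71, -0.9], [0.71, 1.0, 0.69], [-0.9, 0.69, 1.0]], index=cols, columns=cols
        )
        self.p_adj = pd.DataFrame(
            [[np.nan, 0.04, 0.01], [0.04, np.nan, 0.001], [0.01, 0.001, np.nan]], index=cols, columns=cols
        )

    def test_threshold_rule(self):
        out = select_significant_edges(self.rho, self.p_adj, self.kinds)
        got = {(r.compound_a, r.compound_b): r.sign for r in out.edges.itertuples()}
        assert got == {("a", "b"): "positive", ("a", "c"): "negative"}  # b-c fails |rho|

    def test_p_threshold_respected(self):
        p = self.p_adj.copy()
        p.loc["a", "b"] = p.loc["b", "a"] = 0.06
        out = select_significant_edges(self.rho, p, self.kinds)
        assert len(out) == 1


class TestClusters:
    def test_complete_graph_six_forms_cluster(self):
        pairs = [(f"n{i}", f"n{j}", 0.9) for i in range(6) for j in range(i + 1, 6)]
        edges = edge_set(pairs, {f"n{i}": "metabolite" for i in range(6)})
        clusters = extract_clusters(edges, k=5)
        assert len(clusters) == 1
        assert clusters[0].size == 6
        assert all(d == 5 for d in clusters[0].within_degree.values())

    def test_complete_graph_five_is_below_threshold(self):
        pairs = [(f"n{i}", f"n{j}", 0.9) for i in range(5) for j in range(i + 1, 5)]
        edges = edge_set(pairs, {f"n{i}": "metabolite" for i in range(5)})
        assert extract_clusters(edges, k=5) == []

    def test_negative_edges_do_not_enter_clustering(self):
        pairs = [(f"n{i}", f"n{j}", -0.9) for i in range(6) for j in range(i + 1, 6)]
        edges = edge_set(pairs, {f"n{i}": "metabolite" for i in range(6)})
        assert extract_clusters(edges, k=5) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_k_core(self, seed):
        """Iterative low-degree removal oracle agrees with the implementation."""
        rng = np.random.default_rng(seed)
        n, k = 30, 4
        graph = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
        mapping = {i: f"v{i:02d}" for i in graph.nodes}
        graph = nx.relabel_nodes(graph, mapping)
        pairs = [(a, b, 0.9) for a, b in graph.edges]
        edges = edge_set(pairs, {f"v{i:02d}": "volatile" for i in range(n)})
        clusters = extract_clusters(edges, k=k)
        # brute force: remove any vertex with degree < k until fixed point
        g = graph.copy()
        changed = True
        while changed:
            low = [v for v in g if g.degree(v) < k]
            changed = bool(low)
            g.remove_nodes_from(low)
        expect = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(c.members) for c in clusters}
        assert got == expect
        for cluster in clusters:
            assert all(d >= k for d in cluster.within_degree.values())

    def test_removal_order_independence(self):
        rng = np.random.default_rng(12)
        graph = nx.gnp_random_graph(20, 0.3, seed=99)
        base = None
        for _ in range(5):
            nodes = list(graph.nodes)
            rng.shuffle(nodes)
            relabeled = nx.relabel_nodes(graph, {n: f"x{n:02d}" for n in nodes})
            # feed edges in shuffled order
            pairs = [(a, b, 0.8) for a, b in relabeled.edges]
            rng.shuffle(pairs)
            edges = edge_set(pairs, {f"x{n:02d}": "volatile" for n in range(20)})
            got = {frozenset(c.members) for c in extract_clusters(edges, k=4)}
            sizes = sorted(len(c) for c in got)
            if base is None:
                base = sizes
            assert sizes == base

    def test_hub_rank_orders_by_total_correlations(self):
        # K6 plus a pendant vertex attached to n0: n0 has highest total count
        pairs = [(f"n{i}", f"n{j}", 0.9) for i in range(6) for j in range(i + 1, 6)]
        pairs.append(("n0", "pend", 0.9))
        kinds = {f"n{i}": "metabolite" for i in range(6)}
        kinds["pend"] = "volatile"
        clusters = extract_clusters(edge_set(pairs, kinds), k=5)
        assert clusters[0].hub_rank[0] == ("n0", 6)


class TestPlantedBlockEdges:
    def test_within_block_pairs_pass_and_holm_controls_cross_block(self):
        """Planted correlation 0.95 at n=12: within-block pairs almost always
        clear |rho| > 0.7 (sample Spearman at n=12 dips below 0.7 for ~1% of
        pairs even at true 0.95), while Holm keeps the family-wise rate of
        false cross-block edges at the nominal level."""
        from volatilink import SimConfig, generate_paired_dataset
        from volatilink.pipeline import preprocess_dataset
        from volatilink.preprocess import PreprocessConfig

        passed = total = 0
        sims_with_false_edge = 0
        n_sim = 60
        for s in range(n_sim):
            cfg = SimConfig(
                n_volatiles=4, n_metabolites=12, n_pathways=2,
                frac_volatiles_in_blocks=0.0, frac_metabolites_in_blocks=1.0,
                planted_effects_volatile={}, planted_effects_metabolite={},
                detection_limit_volatile=-np.inf, frac_blank_contaminated=0.0,
                block_loading=0.95, noise_sd=0.1, seed=5000 + s,
            )
            study = generate_paired_dataset(cfg)
            _, lc = preprocess_dataset(
                study.metabolites, study.meta_metabolite, PreprocessConfig(), False, False
            )
            rho, p = spearman_all_pairs(lc.data)
            p_adj = holm_adjust_matrix(p)
            blocks = {c: study.truth.block_membership[c] for c in lc.compound_ids}
            cols = list(lc.compound_ids)
            any_false = False
            for i, a in enumerate(cols):
                for b in cols[i + 1 :]:
                    if blocks[a] == blocks[b]:
                        total += 1
                        passed += abs(rho.loc[a, b]) > 0.7
                    elif abs(rho.loc[a, b]) > 0.7 and p_adj.loc[a, b] < 0.05:
                        any_false = True
            sims_with_false_edge += any_false
        assert passed / total >= 0.97
        fwer_bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert sims_with_false_edge / n_sim <= fwer_bound
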