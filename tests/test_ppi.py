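"""Co-expression networks, LOI Z-scores, localization, complex extraction."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from mycolink.ppi import (
    CoexpressionNetwork,
    assign_localizations,
    compute_loi_table,
    extract_complexes,
    filter_candidate_edges,
    grvn_network,
)
from mycolink.stats import pearson_pvalue


def _block_matrix(seed=0, n_genes=10, n_samples=20):
    """Two planted co-expression blocks of five genes plus noise."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    x = rng.normal(size=(n_genes, n_samples))
    for block in (range(0, 5), range(5, 10)):
        factor = rng.normal(size=n_samples)
        for i in block:
            x[i] = 2.0 * factor + rng.normal(0, 0.7, size=n_samples)
    return pd.DataFrame(x, index=genes)


class TestGrvn:
    def test_duplicated_gene_pair_connected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        df = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=30)}).T
        net = grvn_network(df, neighborhood=1, alpha=0.01)
        assert ("a", "b") in net.edges
        assert net.edges[("a", "b")].r == pytest.approx(1.0)

    def test_single_gene_empty_network(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)),
                          index=["a", "b"])
        net = grvn_network(df, allowed=["a"])
        assert net.edges == {}

    def test_matches_exhaustive_all_pairs_oracle(self):
        """Edge set equals brute-force rank/threshold recomputation."""
        df = _block_matrix()
        net = grvn_network(df, neighborhood=5, alpha=0.01)

        genes = list(df.index)
        corr = np.corrcoef(df.to_numpy())
        expected = set()
        for i, g in enumerate(genes):
            ranked = sorted((j for j in range(len(genes)) if j != i),
                            key=lambda j: (-corr[i, j], genes[j]))
            for j in ranked[:5]:
                if pearson_pvalue(corr[i, j], df.shape[1]) < 0.01:
                    expected.add(tuple(sorted((g, genes[j]))))
        assert set(net.edges) == expected

    def test_edges_subset_of_significant_all_pairs_graph(self):
        df = _block_matrix(seed=4)
        net = grvn_network(df, neighborhood=3, alpha=0.01)
        corr = np.corrcoef(df.to_numpy())
        genes = list(df.index)
        for a, b in net.edges:
            i, j = genes.index(a), genes.index(b)
            assert pearson_pvalue(corr[i, j], df.shape[1]) < 0.01
        assert len(net.edges) <= 3 * len(genes)

    def test_constant_gene_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0] * 10,
                           "b": np.arange(10.0), "c": np.arange(10.0)}).T
        with pytest.warns(UserWarning, match="constant"):
            net = grvn_network(df, neighborhood=1)
        assert "a" not in net.nodes

    def test_mutual_mode_is_a_subset(self):
        df = _block_matrix(seed=5)
        union = grvn_network(df, neighborhood=2, alpha=0.05)
        mutual = grvn_network(df, neighborhood=2, alpha=0.05, mutual=True)
        assert set(mutual.edges) <= set(union.edges)


class TestLoi:
    def test_forced_direction_is_table_maximum(self):
        edges = [(f"a{i}", f"b{i}") for i in range(6)]
        ann = {p: {"alpha"} if p.startswith("a") else {"beta"} for p, _ in edges}
        ann.update({p: {"alpha"} if p.startswith("a") else {"beta"} for _, p in edges})
        loi = compute_loi_table(edges, ann, iterations=3000, seed=0)
        assert loi.z[("alpha", "beta")] > 0
        assert loi.z[("alpha", "beta")] == max(loi.z.values())

    def test_invariant_pair_gets_zero(self):
        edges = [("p1", "p2"), ("p3", "p4")]
        ann = {p: {"only"} for p in ("p1", "p2", "p3", "p4")}
        loi = compute_loi_table(edges, ann, iterations=500, seed=0)
        assert loi.z[("only", "only")] == 0.0  # null SD is zero by construction

    def test_matches_exhaustive_endpoint_permutation_oracle(self):
        """Monte-Carlo Z within 0.1 of full enumeration on a 6-protein toy."""
        edges = [("p1", "p2"), ("p3", "p4"), ("p5", "p6")]
        labels = {"p1": "a", "p2": "b", "p3": "a", "p4": "b", "p5": "a", "p6": "b"}
        ann = {p: {l} for p, l in labels.items()}

        stubs = [p for e in edges for p in e]
        pair_keys = [("a", "a"), ("a", "b"), ("b", "b")]
        counts = {k: [] for k in pair_keys}
        for perm in itertools.permutations(stubs):
            c = dict.fromkeys(pair_keys, 0)
            for i in range(0, 6, 2):
                key = tuple(sorted((labels[perm[i]], labels[perm[i + 1]])))
                c[key] += 1
            for k in pair_keys:
                counts[k].append(c[k])
        loi = compute_loi_table(edges, ann, iterations=10_000, seed=2)
        for k in pair_keys:
            mean = np.mean(counts[k])
            sd = np.std(counts[k])
            obs = loi.observed.get(k, 0.0)
            z_exact = 0.0 if sd == 0 else (obs - mean) / sd
            assert loi.z[k] == pytest.approx(z_exact, abs=0.1)

    def test_null_conserves_total_pair_count(self):
        edges = [("p1", "p2"), ("p3", "p4"), ("p1", "p3"), ("p2", "p4")]
        ann = {"p1": {"a"}, "p2": {"b"}, "p3": {"a"}, "p4": {"c"}}
        loi = compute_loi_table(edges, ann, iterations=2000, seed=1)
        assert sum(loi.null_mean.values()) == pytest.approx(len(edges), abs=1e-9)

    def test_table_is_symmetric_via_sorted_keys_and_score(self):
        edges = [("p1", "p2")]
        ann = {"p1": {"x"}, "p2": {"y"}}
        loi = compute_loi_table(edges, ann, iterations=200, seed=0)
        assert all(k == tuple(sorted(k)) for k in loi.z)
        assert loi.score({"x"}, {"y"}) == loi.score({"y"}, {"x"})

    def test_compound_labels_pre_split_in_scoring(self):
        edges = [("p1", "p2"), ("p3", "p4")]
        ann = {"p1": {"a"}, "p2": {"b"}, "p3": {"a"}, "p4": {"b"}}
        loi = compute_loi_table(edges, ann, iterations=500, seed=0)
        assert loi.score({"a:b"}, {"b"}) == max(
            loi.score({"a"}, {"b"}), loi.score({"b"}, {"b"})
        )

    def test_unannotated_protein_rejected_by_id(self):
        with pytest.raises(KeyError, match="p2"):
            compute_loi_table([("p1", "p2")], {"p1": {"a"}}, iterations=10)


class TestAssignLocalizations:
    def test_argmax(self):
        out = assign_localizations({"p": {"nuclear": 9.0, "cytoplasm": 3.0}})
        assert out["p"] == frozenset({"nuclear"})

    def test_tie_assigns_both(self):
        out = assign_localizations({"p": {"nuclear": 5.0, "plasma_membrane": 5.0}})
        assert out["p"] == frozenset({"nuclear", "plasma_membrane"})

    def test_compound_label_split(self):
        out = assign_localizations({"p": {"nuclear:cytoplasm": 8.0, "vacuole": 1.0}})
        assert out["p"] == frozenset({"nuclear", "cytoplasm"})

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_localizations({"p": {}})


def _toy_network_and_loi():
    edges = {}
    for pair in [("a", "b"), ("b", "c"), ("a", "c")]:
        key = tuple(sorted(pair))
        from mycolink.ppi import CoexpressionEdge
        edges[key] = CoexpressionEdge(key, 0.9, 1e-5, frozenset(key))
    net = CoexpressionNetwork(("a", "b", "c"), edges)
    from mycolink.ppi import LOITable
    loi = LOITable(
        z={("m", "m"): 2.0, ("m", "n"): 0.5, ("n", "n"): 1.5},
        observed={}, null_mean={}, null_sd={}, iterations=1,
    )
    return net, loi


class TestFilterAndComplexes:
    def test_low_loi_edge_removed(self):
        net, loi = _toy_network_and_loi()
        locs = {"a": {"m"}, "b": {"m"}, "c": {"n"}}
        flags = {"a": True, "b": True, "c": True}
        ann = {g: {"transmembrane_receptor"} for g in "abc"}
        out = filter_candidate_edges(net, loi, locs, flags,
                                     {"transmembrane_receptor"}, ann)
        assert set(out.edges) == {("a", "b")}  # (m,n)=0.5 edges fail the Z>1 bar

    def test_nonsignificant_protein_loses_all_edges(self):
        net, loi = _toy_network_and_loi()
        locs = {"a": {"m"}, "b": {"m"}, "c": {"m"}}
        flags = {"a": True, "b": False, "c": True}
        ann = {g: {"transmembrane_receptor"} for g in "abc"}
        out = filter_candidate_edges(net, loi, locs, flags,
                                     {"transmembrane_receptor"}, ann)
        assert set(out.edges) == {("a", "c")}

    def test_allowlist_required_on_both_ends(self):
        net, loi = _toy_network_and_loi()
        locs = {g: {"m"} for g in "abc"}
        flags = {g: True for g in "abc"}
        ann = {"a": {"transmembrane_receptor"}, "b": {"metabolism"},
               "c": {"transmembrane_receptor"}}
        out = filter_candidate_edges(net, loi, locs, flags,
                                     {"transmembrane_receptor"}, ann)
        assert set(out.edges) == {("a", "c")}

    def test_raising_threshold_is_monotone(self):
        net, loi = _toy_network_and_loi()
        locs = {"a": {"m"}, "b": {"m"}, "c": {"n"}}
        flags = {g: True for g in "abc"}
        ann = {g: {"transmembrane_receptor"} for g in "abc"}
        low = filter_candidate_edges(net, loi, locs, flags,
                                     {"transmembrane_receptor"}, ann, loi_threshold=0.1)
        high = filter_candidate_edges(net, loi, locs, flags,
                                      {"transmembrane_receptor"}, ann, loi_threshold=1.9)
        assert set(high.edges) <= set(low.edges)

    def test_empty_network_no_complexes(self):
        net = CoexpressionNetwork(("a", "b"), {})
        assert extract_complexes(net, {}) == []

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        pairs = set()
        while len(pairs) < 25:
            a, b = rng.choice(genes, 2, replace=False)
            pairs.add(tuple(sorted((a, b))))
        from mycolink.ppi import CoexpressionEdge
        net = CoexpressionNetwork(
            tuple(genes),
            {p: CoexpressionEdge(p, 0.9, 1e-4, frozenset(p)) for p in pairs},
        )
        found = extract_complexes(net, {})

        parent = {g: g for g in genes}

        def root(g):
            while parent[g] != g:
                parent[g] = parent[parent[g]]
                g = parent[g]
            return g

        for a, b in pairs:
            parent[root(a)] = root(b)
        comps = {}
        for g in genes:
            comps.setdefault(root(g), set()).add(g)
        expected = sorted(
            (sorted(c) for c in comps.values() if len(c) >= 2), key=lambda c: (-len(c), c[0])
        )
        assert [sorted(cx.nodes) for cx in found] == expected

    def test_role_typing_precedence(self):
        from mycolink.ppi import assign_role
        assert assign_role({"transmembrane_receptor", "transcription_factor"}) == "receptor"
        assert assign_role({"tf_class_HSF"}) == "transcription_factor"
        assert assign_role({"defense_response"}) == "defense"
        assert assign_role({"metabolism"}) == "cascade"


class TestEndToEndComplexRecovery:
    def test_planted_edges_retained_and_complexes_connected(self, world, result):
        truth_edges = {tuple(sorted(e))
                       for cx in world.ground_truth["complexes"] for e in cx["edges"]}
        assert truth_edges <= set(result.filtered_network.edges)
        found_sets = [set(cx.nodes) for cx in result.complexes]
        for cx in world.ground_truth["complexes"]:
            nodes = set(cx["roles"])
            best = max(len(nodes & f) / len(nodes | f) for f in found_sets)
            assert best >= 0.8
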