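"""Metabolite-cluster correlation, tail selection, and model assembly."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mycolink.cluster import GeneCluster
from mycolink.integrate import (
    CorrelationMatrix,
    MetaboliteLink,
    assemble,
    correlate,
    link_complexes_to_clusters,
    select_strong_links,
)
from mycolink.motifs import MotifEnrichment
from mycolink.ppi import SensorComplex


def _cluster(cid, members, profile, conditions):
    return GeneCluster(cid, tuple(members),
                       pd.Series(profile, index=list(conditions)))


CONDS = list("abcdefgh")


class TestCorrelate:
    def test_exact_negation_gives_minus_one(self):
        prof = [0, 1, 2, 1, 0, -1, -2, -1]
        scores = pd.DataFrame([[-v for v in prof]], index=["m"], columns=CONDS)
        cm = correlate(scores, [_cluster("C1", ["g"], prof, CONDS)], CONDS)
        assert cm.r.loc["m", "C1"] == pytest.approx(-1.0)

    def test_constant_profile_recorded_missing(self):
        scores = pd.DataFrame([[1, 2, 3, 4, 5, 6, 7, 8]], index=["m"], columns=CONDS)
        cm = correlate(scores, [_cluster("C1", ["g"], [2.0] * 8, CONDS)], CONDS)
        assert np.isnan(cm.r.loc["m", "C1"])

    def test_matches_independent_covariance_oracle(self):
        rng = np.random.default_rng(12)
        scores = pd.DataFrame(rng.normal(size=(4, 8)),
                              index=[f"m{i}" for i in range(4)], columns=CONDS)
        clusters = [_cluster(f"C{i}", [f"g{i}"], rng.normal(size=8), CONDS)
                    for i in range(3)]
        cm = correlate(scores, clusters, CONDS)
        for m in scores.index:
            for c in clusters:
                x = scores.loc[m].to_numpy()
                y = c.mean_profile.to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
                assert cm.r.loc[m, c.id] == pytest.approx(r, abs=1e-12)

    def test_needs_three_shared_conditions(self):
        scores = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=["a", "b"])
        with pytest.raises(ValueError):
            correlate(scores, [_cluster("C1", ["g"], [1.0, 2.0], ["a", "b"])], ["a", "b"])


class TestSelectStrongLinks:
    def test_all_equal_coefficients_select_nothing(self):
        r = pd.DataFrame(0.5, index=["m1", "m2"], columns=["C1", "C2"])
        with pytest.warns(UserWarning):
            links, _ = select_strong_links(CorrelationMatrix(r, 8), percentile=0.4)
        assert links == []

    def test_matches_full_sort_oracle_on_large_pool(self):
        rng = np.random.default_rng(13)
        r = pd.DataFrame(rng.uniform(-1, 1, size=(100, 100)),
                         index=[f"m{i}" for i in range(100)],
                         columns=[f"C{i}" for i in range(100)])
        cm = CorrelationMatrix(r, 8)
        links, (lower, upper) = select_strong_links(cm, percentile=0.001)
        pool = np.sort(r.to_numpy().ravel())
        expected = {v for v in pool if v <= lower or v >= upper}
        assert {l.r for l in links} == expected
        assert lower == pytest.approx(np.quantile(pool, 0.001))
        assert upper == pytest.approx(np.quantile(pool, 0.999))

    def test_small_pool_keeps_only_global_extremes(self):
        r = pd.DataFrame([[0.1, -0.7], [0.9, 0.2]],
                         index=["m1", "m2"], columns=["C1", "C2"])
        with pytest.warns(UserWarning, match="extremes"):
            links, _ = select_strong_links(CorrelationMatrix(r, 8), percentile=0.001)
        got = {(l.metabolite, l.cluster) for l in links}
        assert got == {("m2", "C1"), ("m1", "C2")}

    def test_negative_links_flagged_synthesis_coupled(self):
        r = pd.DataFrame([[0.99, -0.99]], index=["m"], columns=["C1", "C2"])
        with pytest.warns(UserWarning):
            links, _ = select_strong_links(CorrelationMatrix(r, 8), percentile=0.001)
        signs = {l.cluster: l.sign for l in links}
        assert signs == {"C1": 1, "C2": -1}


class TestComplexClusterLinks:
    def _complex(self, cid, nodes):
        return SensorComplex(cid, {n: "cascade" for n in nodes},
                             edges=[tuple(sorted(nodes[:2]))])

    def test_disjoint_complex_not_linked(self):
        cx = self._complex("X", ["p1", "p2"])
        cl = _cluster("C1", ["g1", "g2"], [0.0] * 8, CONDS)
        assert link_complexes_to_clusters([cx], [cl]) == []

    def test_shared_gene_links_to_every_overlapping_cluster(self):
        cx = self._complex("X", ["g1", "p2"])
        cls = [_cluster("C1", ["g1", "g9"], [0.0] * 8, CONDS),
               _cluster("C2", ["g1", "g8"], [0.0] * 8, CONDS)]
        out = link_complexes_to_clusters([cx], cls)
        assert [(c, cl, s) for c, cl, s in out] == [
            ("X", "C1", ("g1",)), ("X", "C2", ("g1",))]


class TestAssemble:
    def test_empty_inputs_empty_model(self):
        model = assemble([], [], [], [], {})
        assert model.graph.number_of_nodes() == 0

    def test_single_chain_carries_all_four_rules(self):
        links = [MetaboliteLink("met", "C1", -0.99, -1)]
        cx_links = [("A", "C1", ("g1",))]
        tf_rows = [("A", "C1", "HSE", 12)]
        enr = [MotifEnrichment("C1", "MYB1AT", 30, 20, 0.2, 1e-8, True)]
        model = assemble(links, cx_links, tf_rows, enr, {"C1": [("defense", 0.001, 9)]})
        rules = {d["rule"] for _, _, d in model.graph.edges(data=True)}
        assert rules == {1, 2, 3, 4}
        edge = model.graph.edges[("metabolite:met", "cluster:C1")]
        assert edge["via_complexes"] == ["A"] and not edge["dangling"]
        assert edge["coupling"] == "synthesis"

    def test_dangling_signal_edge_warned_not_dropped(self):
        links = [MetaboliteLink("met", "C9", 0.98, 1)]
        with pytest.warns(UserWarning, match="dangling"):
            model = assemble(links, [], [], [], {})
        edge = model.graph.edges[("metabolite:met", "cluster:C9")]
        assert edge["dangling"]

    def test_failed_enrichments_excluded(self):
        enr = [MotifEnrichment("C1", "M", 30, 3, 0.2, 0.4, False)]
        model = assemble([], [("A", "C1", ("g",))], [], enr, {})
        assert "motif:M" not in model.graph

    def test_assembly_is_order_independent(self):
        links = [MetaboliteLink("m1", "C1", 0.99, 1), MetaboliteLink("m2", "C2", -0.99, -1)]
        cx_links = [("A", "C1", ("g1",)), ("B", "C2", ("g2",))]
        tf_rows = [("A", "C1", "HSE", 3), ("B", "C2", "E2FCONSENSUS", 4)]
        enr = [MotifEnrichment("C1", "MYB1AT", 30, 20, 0.2, 1e-8, True)]
        terms = {"C1": [("t1", 0.01, 5)], "C2": [("t2", 0.02, 6)]}
        a = assemble(links, cx_links, tf_rows, enr, terms)
        b = assemble(links[::-1], cx_links[::-1], tf_rows[::-1], enr, terms)
        assert sorted(a.graph.nodes(data=True)) == sorted(b.graph.nodes(data=True))
        assert sorted(a.graph.edges(data=True)) == sorted(b.graph.edges(data=True))

    def test_every_edge_has_exactly_one_rule_and_evidence(self, result):
        for u, v, d in result.model.graph.edges(data=True):
            assert d["rule"] in (1, 2, 3, 4)
            if d["rule"] == 1:
                assert len(d["shared_genes"]) >= 1
            elif d["rule"] == 2:
                assert -1.0 <= d["r"] <= 1.0
            elif d["rule"] == 3:
                assert d["source"] in ("complex_tf", "enriched", "complex_tf+enriched")
            else:
                assert 0.0 <= d["p"] < 0.05

    def test_planted_chain_recovered_in_model(self, world, result):
        g = result.model.graph
        # complex-linked clusters: every rule-1 edge backed by shared genes
        rule1 = [(u, v) for u, v, d in g.edges(data=True) if d["rule"] == 1]
        assert len(rule1) >= 4
        # planted metabolites present as signal nodes
        mets = {n.split(":", 1)[1] for n in g if n.startswith("metabolite:")}
        planted = {l["metabolite"] for l in world.ground_truth["metabolite_links"]}
        assert planted <= mets


class TestGraphExports:
    def test_graphml_and_json_roundtrip_files(self, result, tmp_path):
        import json

        import networkx as nx
        path = tmp_path / "model.graphml"
        result.model.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == result.model.graph.number_of_nodes()
        payload = json.loads(result.model.to_json())
        assert len(payload["edges"]) == result.model.graph.number_of_edges()
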