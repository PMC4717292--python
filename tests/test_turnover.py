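"""Metabolic network construction, UEF abundances, PRMT scores."""

import numpy as np
import pandas as pd
import pytest

from mycolink.turnover import (
    ReactionRecord,
    build_network,
    prmt_scores,
    uef_abundance,
)


def rxn(ec, rid, reac, prod, pathway="map1"):
    return ReactionRecord(ec, rid, tuple(reac), tuple(prod), pathway)


class TestBuildNetwork:
    def test_sign_convention_consumption_positive(self):
        net = build_network([rxn("e1", "r1", ["A"], ["B"])], {"map1"})
        assert net.weights.loc["A", "e1"] == 1.0
        assert net.weights.loc["B", "e1"] == -1.0

    def test_metabolite_on_both_sides_nets_to_zero(self):
        net = build_network([rxn("e1", "r1", ["A", "X"], ["X", "B"])], {"map1"})
        assert net.weights.loc["X", "e1"] == 0.0

    def test_toy_incidence_matches_hand_accumulation(self):
        reactions = [
            rxn("e1", "r1", ["A"], ["B"]),
            rxn("e1", "r2", ["A", "C"], ["D"]),
            rxn("e2", "r3", ["B"], ["C"]),
            rxn("e3", "r4", ["D"], ["A"]),
        ]
        net = build_network(reactions, {"map1"}, normalize=True)
        # independent per-record accumulation, normalized by reactions per EC
        expected = {}
        per_ec = {}
        for r in reactions:
            per_ec[r.ec] = per_ec.get(r.ec, 0) + 1
        for r in reactions:
            for m in r.reactants:
                expected[(m, r.ec)] = expected.get((m, r.ec), 0) + 1
            for m in r.products:
                expected[(m, r.ec)] = expected.get((m, r.ec), 0) - 1
        for (m, ec), v in expected.items():
            assert net.weights.loc[m, ec] == pytest.approx(v / per_ec[ec])

    def test_pathway_restriction_and_ec_drop_warning(self):
        reactions = [rxn("e1", "r1", ["A"], ["B"], "mapX"),
                     rxn("e2", "r2", ["A"], ["C"], "map1")]
        with pytest.warns(UserWarning, match="e1"):
            net = build_network(reactions, {"map1"})
        assert "e1" not in net.weights.columns
        assert net.stats["n_reactions"] == 1

    def test_component_stats(self):
        reactions = [rxn("e1", "r1", ["A"], ["B"]),
                     rxn("e2", "r2", ["B"], ["C"]),
                     rxn("e3", "r3", ["X"], ["Y"])]
        net = build_network(reactions, {"map1"})
        assert net.stats["largest_component_metabolites"] == 3
        assert net.stats["largest_component_reactions"] == 2

    def test_empty_pathway_set_rejected(self):
        with pytest.raises(ValueError):
            build_network([rxn("e", "r", ["A"], ["B"])], set())


class TestUefAbundance:
    def test_single_gene_single_ec(self):
        expr = pd.DataFrame({"s1": [2.0], "s2": [3.0]}, index=["g1"])
        out = uef_abundance(expr, {"g1": {"e1"}})
        assert np.allclose(out.loc["e1"], [2.0, 3.0])

    def test_two_genes_sum_and_multi_ec_full_contribution(self):
        expr = pd.DataFrame({"s1": [1.0, 10.0]}, index=["g1", "g2"])
        out = uef_abundance(expr, {"g1": {"e1", "e2"}, "g2": {"e1"}})
        assert out.loc["e1", "s1"] == 11.0
        assert out.loc["e2", "s1"] == 1.0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(rng.uniform(0, 50, size=(30, 4)), index=genes,
                            columns=list("abcd"))
        ecs = [f"e{rng.integers(5)}" for _ in genes]
        ann = {g: {e} for g, e in zip(genes, ecs)}
        out = uef_abundance(expr, ann)
        oracle = expr.assign(ec=ecs).groupby("ec").sum()
        assert np.allclose(out.sort_index(), oracle.sort_index())


class TestPrmtScores:
    def _uef(self, rows, conditions=("c1", "c2")):
        return pd.DataFrame(rows, columns=list(conditions))

    def test_unit_consumption_case(self):
        """One enzyme consuming m, doubled in c2: score(m, c2) = +1."""
        net = build_network([rxn("e1", "r1", ["m"], ["w"])], {"map1"})
        uef = pd.DataFrame({"c1": [4.0], "c2": [8.0]}, index=["e1"])
        s = prmt_scores(uef, net).scores
        assert s.loc["m", "c2"] == pytest.approx(0.5)   # delta = +-0.5 around the mean
        assert s.loc["m", "c1"] == pytest.approx(-0.5)
        # against a free-living style reference baseline the jump is the full +1
        s_ref = prmt_scores(uef, net, baseline="c1").scores
        assert s_ref.loc["m", "c2"] == pytest.approx(1.0)

    def test_unit_production_flips_sign(self):
        net = build_network([rxn("e1", "r1", ["w"], ["m"])], {"map1"})
        uef = pd.DataFrame({"c1": [4.0], "c2": [8.0]}, index=["e1"])
        s = prmt_scores(uef, net, baseline="c1").scores
        assert s.loc["m", "c2"] == pytest.approx(-1.0)

    def test_matches_dense_incidence_product_oracle(self):
        reactions = [
            rxn("e1", "r1", ["m", "x"], ["y"]),
            rxn("e2", "r2", ["y"], ["m"]),
            rxn("e3", "r3", ["m"], ["x", "y"]),
        ]
        net = build_network(reactions, {"map1"})
        rng = np.random.default_rng(9)
        uef = pd.DataFrame(rng.uniform(1, 100, size=(3, 5)),
                           index=["e1", "e2", "e3"],
                           columns=[f"c{i}" for i in range(5)])
        out = prmt_scores(uef, net).scores

        logged = np.log2(uef.to_numpy())
        delta = logged - logged.mean(axis=1, keepdims=True)
        w = net.weights.loc[out.index, uef.index].to_numpy()
        n_m = (w != 0).sum(axis=1, keepdims=True)
        expected = (w @ delta) / n_m
        assert np.allclose(out.to_numpy(), expected, atol=1e-12)

    def test_linearity_in_deltas(self):
        net = build_network([rxn("e1", "r1", ["m"], ["w"])], {"map1"})
        uef = pd.DataFrame({"c1": [2.0], "c2": [8.0]}, index=["e1"])
        uef_sq = uef**2  # squares the ratio => doubles every log2 delta
        s1 = prmt_scores(uef, net).scores
        s2 = prmt_scores(uef_sq, net).scores
        assert np.allclose(s2.to_numpy(), 2 * s1.to_numpy())

    def test_reversing_reactions_negates_scores(self):
        fwd = [rxn("e1", "r1", ["m", "x"], ["y"]), rxn("e2", "r2", ["y"], ["m"])]
        rev = [rxn("e1", "r1", ["y"], ["m", "x"]), rxn("e2", "r2", ["m"], ["y"])]
        uef = pd.DataFrame(np.random.default_rng(10).uniform(1, 50, (2, 4)),
                           index=["e1", "e2"], columns=list("abcd"))
        s_f = prmt_scores(uef, build_network(fwd, {"map1"})).scores
        s_r = prmt_scores(uef, build_network(rev, {"map1"})).scores
        assert np.allclose(s_f.to_numpy(), -s_r.to_numpy())

    def test_scores_centered_over_conditions(self):
        reactions = [rxn("e1", "r1", ["m"], ["w"]), rxn("e2", "r2", ["w"], ["m"])]
        uef = pd.DataFrame(np.random.default_rng(11).uniform(1, 50, (2, 6)),
                           index=["e1", "e2"], columns=list("abcdef"))
        s = prmt_scores(uef, build_network(reactions, {"map1"})).scores
        assert np.allclose(s.mean(axis=1), 0.0, atol=1e-9)

    def test_untouched_metabolite_absent(self):
        net = build_network([rxn("e1", "r1", ["m"], ["w"])], {"map1"})
        uef = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["eZ"])  # e1 unexpressed
        s = prmt_scores(uef, net).scores
        assert s.empty

    def test_needs_two_conditions(self):
        net = build_network([rxn("e1", "r1", ["m"], ["w"])], {"map1"})
        with pytest.raises(ValueError):
            prmt_scores(pd.DataFrame({"c1": [1.0]}, index=["e1"]), net)
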