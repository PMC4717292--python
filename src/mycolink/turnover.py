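"""Predicted relative metabolic turnover (PRMT) from EC-annotated transcriptomes.

The fungal metabolome is not measured directly; it is inferred from the
transcriptome.  Each unique enzyme function (UEF, an EC annotation) is
quantified as the summed quantile-normalized RPKM of the gene models
carrying it.  KEGG-style enzyme reactions, restricted to the pathways of
the two organisms, give a signed enzyme x metabolite incidence: positive
weight where the enzyme consumes the metabolite (it appears as a
reactant), negative where it produces it.  Per condition, each UEF's
log2 deviation from its cross-condition mean is propagated through the
incidence and averaged over the enzymes touching each metabolite.  A
positive score predicts net consumption of the metabolite, a negative
score net synthesis.

PRMT assumes reaction rates follow enzyme abundance (not substrate
concentration) and a well-mixed metabolome; it is a turnover-potential
score, not a flux balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ReactionRecord",
    "MetabolicNetwork",
    "TurnoverScores",
    "build_network",
    "uef_abundance",
    "prmt_scores",
]


@dataclass(frozen=True)
class ReactionRecord:
    """One enzyme-catalysed transformation from a KEGG-style reaction table."""

    ec: str
    reaction_id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    pathway: str

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ValueError(f"reaction {self.reaction_id}: empty side")


@dataclass
class MetabolicNetwork:
    """Signed EC x metabolite incidence plus bipartite network statistics."""

    weights: pd.DataFrame  # metabolites x ECs, consumption positive
    n_reactions: int
    stats: dict = field(default_factory=dict)


def build_network(
    reactions: Sequence[ReactionRecord],
    allowed_pathways: Iterable[str],
    normalize: bool = True,
) -> MetabolicNetwork:
    """Pathway-restricted signed incidence between enzymes and metabolites.

    Only reactions whose pathway is in ``allowed_pathways`` are kept.
    ``weight(e, m)`` counts, over e's kept reactions, appearances of m as
    a reactant minus appearances as a product; with ``normalize`` the net
    count is divided by the enzyme's number of kept reactions so that an
    enzyme's influence does not grow with its reaction multiplicity.  A
    metabolite on both sides of one reaction nets to zero.  ECs with no
    kept reaction are dropped with a warning.
    """
    allowed = set(allowed_pathways)
    if not allowed:
        raise ValueError("allowed pathway set is empty")
    kept = [r for r in reactions if r.pathway in allowed]
    dropped_ecs = sorted({r.ec for r in reactions} - {r.ec for r in kept})
    if dropped_ecs:
        warnings.warn(
            f"{len(dropped_ecs)} EC(s) have no reaction in an allowed pathway "
            f"and were dropped (e.g. {dropped_ecs[:3]})",
            stacklevel=2,
        )

    raw: dict[str, dict[str, float]] = {}
    n_reactions_per_ec: dict[str, int] = {}
    for rec in kept:
        n_reactions_per_ec[rec.ec] = n_reactions_per_ec.get(rec.ec, 0) + 1
        w = raw.setdefault(rec.ec, {})
        for m in rec.reactants:
            w[m] = w.get(m, 0.0) + 1.0
        for m in rec.products:
            w[m] = w.get(m, 0.0) - 1.0

    ecs = sorted(raw)
    metabolites = sorted({m for w in raw.values() for m in w})
    mat = pd.DataFrame(0.0, index=metabolites, columns=ecs)
    for ec, w in raw.items():
        denom = n_reactions_per_ec[ec] if normalize else 1
        for m, v in w.items():
            mat.loc[m, ec] = v / denom

    # bipartite metabolite <-> reaction graph, for reporting connectivity
    g = nx.Graph()
    for rec in kept:
        rnode = ("rxn", rec.reaction_id)
        for m in set(rec.reactants) | set(rec.products):
            g.add_edge(("met", m), rnode)
    largest_mets = largest_rxns = 0
    if g.number_of_nodes():
        comp = max(nx.connected_components(g), key=len)
        largest_mets = sum(1 for kind, _ in comp if kind == "met")
        largest_rxns = sum(1 for kind, _ in comp if kind == "rxn")
    stats = {
        "n_metabolites": len(metabolites),
        "n_reactions": len(kept),
        "n_ecs": len(ecs),
        "largest_component_metabolites": largest_mets,
        "largest_component_reactions": largest_rxns,
    }
    return MetabolicNetwork(weights=mat, n_reactions=len(kept), stats=stats)


def uef_abundance(
    expr: pd.DataFrame,
    ec_annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Sum (quantile-normalized) expression of gene models per EC annotation.

    ``expr`` is gene x sample on the normalized RPKM scale.  A gene with
    k EC labels contributes its full row to each of the k ECs; ECs with
    no expressed gene are absent from the result.
    """
    rows: dict[str, np.ndarray] = {}
    for gene, ecs in ec_annotations.items():
        if gene not in expr.index:
            continue
        vec = expr.loc[gene].to_numpy(dtype=float)
        for ec in ecs:
            rows[ec] = rows.get(ec, 0.0) + vec
    out = pd.DataFrame(
        {ec: rows[ec] for ec in sorted(rows)}, index=expr.columns
    ).T
    out.index.name = "ec"
    return out


@dataclass
class TurnoverScores:
    """Metabolite x condition PRMT scores, positive = predicted consumption."""

    scores: pd.DataFrame
    stats: dict = field(default_factory=dict)


def prmt_scores(
    uef: pd.DataFrame,
    network: MetabolicNetwork,
    floor: float | None = None,
    per_metabolite_mean: bool = True,
    baseline: str = "mean",
) -> TurnoverScores:
    """PRMT turnover scores from UEF abundances and the signed incidence.

    Per EC, ``delta(c) = log2(abundance in c) - baseline`` where the
    baseline is the cross-condition mean of the log2 abundances (or a
    named reference condition).  ``score(m, c)`` is the weight-signed sum
    of the deltas over the ECs touching m, divided by the number of such
    expressed ECs (``per_metabolite_mean=False`` leaves the raw sum).
    The log floor defaults to half the smallest positive abundance.
    Metabolites touched by no expressed enzyme are absent.
    """
    if uef.shape[1] < 2:
        raise ValueError("PRMT needs >= 2 conditions")
    ecs = [e for e in network.weights.columns if e in uef.index]
    w = network.weights[ecs]
    w = w.loc[(w != 0).any(axis=1), :]
    touched = (w != 0).sum(axis=1)
    w = w.loc[touched > 0]

    arr = uef.loc[ecs].to_numpy(dtype=float)
    if floor is None:
        positive = arr[arr > 0]
        floor = 0.5 * positive.min() if positive.size else 1.0
    logged = np.log2(np.maximum(arr, floor))
    if baseline == "mean":
        delta = logged - logged.mean(axis=1, keepdims=True)
    else:
        if baseline not in uef.columns:
            raise KeyError(f"reference condition {baseline!r} not in abundance table")
        ref = logged[:, list(uef.columns).index(baseline)]
        delta = logged - ref[:, None]

    scores = w.to_numpy() @ delta
    if per_metabolite_mean:
        scores = scores / touched.loc[w.index].to_numpy()[:, None]
    scores_df = pd.DataFrame(scores, index=w.index, columns=uef.columns)
    stats = dict(network.stats)
    stats["n_expressed_uefs"] = len(ecs)
    stats["n_scored_metabolites"] = len(scores_df)
    return TurnoverScores(scores=scores_df, stats=stats)
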