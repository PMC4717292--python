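"""Assembly of the signal -> sensor -> motif -> cluster -> phenotype model.

The final integration step correlates the fungal metabolite turnover
profiles with the host gene-cluster expression profiles over the shared
condition axis and applies four assembly rules:

1. a sensor complex regulates a gene cluster when they share genes;
2. a metabolite signals a cluster when its turnover profile is in the
   extreme (top/bottom percentile) tail of all metabolite x cluster
   correlations -- routed through the cluster's sensor complex when one
   exists (a strong negative correlation means predicted *synthesis* of
   the metabolite tracks increased host expression);
3. binding motifs link a complex to its cluster either via the known
   motif of a complex transcription factor or via motif enrichment in
   the cluster;
4. a cluster's predicted phenotype is its set of enriched functional
   annotations.

Every edge of the assembled network carries its provenance rule and the
evidence (shared genes, r value, or p value) behind it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "MetaboliteLink",
    "IntegratedModel",
    "correlate",
    "select_strong_links",
    "link_complexes_to_clusters",
    "assemble",
]


@dataclass
class CorrelationMatrix:
    """Metabolite x cluster Pearson coefficients over the shared conditions."""

    r: pd.DataFrame
    n_conditions: int


@dataclass(frozen=True)
class MetaboliteLink:
    metabolite: str
    cluster: str
    r: float
    sign: int  # +1 consumption-coupled, -1 synthesis-coupled


def correlate(
    scores: pd.DataFrame,
    clusters: Sequence,
    conditions: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pearson r between each metabolite turnover profile and each cluster profile.

    Profiles are compared over the conditions present on both sides
    (>= 3 required).  Zero-variance profiles give an undefined r,
    recorded as missing.
    """
    cluster_profiles = pd.DataFrame({c.id: c.mean_profile for c in clusters}).T
    if conditions is None:
        conditions = [c for c in scores.columns if c in cluster_profiles.columns]
    conditions = list(conditions)
    if len(conditions) < 3:
        raise ValueError("need >= 3 shared conditions to correlate")
    s = scores[conditions].to_numpy(dtype=float)
    p = cluster_profiles[conditions].to_numpy(dtype=float)
    s_c = s - s.mean(axis=1, keepdims=True)
    p_c = p - p.mean(axis=1, keepdims=True)
    s_n = np.sqrt((s_c**2).sum(axis=1))
    p_n = np.sqrt((p_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s_c @ p_c.T) / np.outer(s_n, p_n)
    r[:, p_n == 0] = np.nan
    r[s_n == 0, :] = np.nan
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=scores.index, columns=cluster_profiles.index),
        n_conditions=len(conditions),
    )


def select_strong_links(
    corr: CorrelationMatrix,
    percentile: float = 0.001,
) -> tuple[list[MetaboliteLink], tuple[float, float]]:
    """Metabolite-cluster pairs in the extreme tails of the pooled r distribution.

    Cutoffs are the empirical ``percentile`` and ``1 - percentile``
    quantiles of *all* finite coefficients pooled together; pairs at or
    beyond either cutoff are kept.  Negative-r links are flagged
    synthesis-coupled (sign -1).  With fewer than ``1/percentile`` pairs
    the percentile is not resolvable and only the global extremes are
    kept, with a warning.
    """
    if not 0 < percentile < 0.5:
        raise ValueError("percentile must be in (0, 0.5)")
    flat = corr.r.stack(future_stack=True).dropna()
    if flat.empty:
        raise ValueError("empty correlation matrix")
    pool = flat.to_numpy(dtype=float)
    if len(pool) < 1.0 / percentile:
        warnings.warn(
            f"{len(pool)} coefficients cannot resolve the {percentile} percentile; "
            "keeping only the global extremes",
            stacklevel=2,
        )
        lower, upper = float(pool.min()), float(pool.max())
    else:
        lower = float(np.quantile(pool, percentile))
        upper = float(np.quantile(pool, 1.0 - percentile))
    if lower == upper:  # degenerate: no pair lies strictly in a tail
        warnings.warn("all correlation coefficients equal; no link selected", stacklevel=2)
        return [], (lower, upper)
    links = []
    for (met, cl), r in flat.items():
        if r <= lower or r >= upper:
            links.append(MetaboliteLink(met, cl, float(r), 1 if r > 0 else -1))
    links.sort(key=lambda l: (-abs(l.r), l.metabolite, l.cluster))
    return links, (lower, upper)


def link_complexes_to_clusters(
    complexes: Sequence,
    clusters: Sequence,
) -> list[tuple[str, str, tuple[str, ...]]]:
    """Rule-1 edges: (complex, cluster, shared genes) for every non-empty overlap."""
    out = []
    for cx in complexes:
        for cl in clusters:
            shared = tuple(sorted(set(cx.nodes) & set(cl.members)))
            if shared:
                out.append((cx.id, cl.id, shared))
    return out


@dataclass
class IntegratedModel:
    """Typed multi-omics network with per-edge provenance rules."""

    graph: nx.DiGraph
    thresholds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "thresholds": self.thresholds,
            "nodes": [
                {"id": n, **{k: v for k, v in d.items()}}
                for n, d in sorted(self.graph.nodes(data=True))
            ],
            "edges": [
                {"source": u, "target": v, **{k: v2 for k, v2 in d.items()}}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            for k, v in list(d.items()):
                if isinstance(v, (list, tuple)):
                    d[k] = ";".join(map(str, v))
        nx.write_graphml(g, path)


def assemble(
    metabolite_links: Sequence[MetaboliteLink],
    complex_links: Sequence[tuple[str, str, tuple[str, ...]]],
    complex_tf_motifs: Sequence[tuple[str, str, str, int]],
    motif_enrichments: Sequence,
    cluster_enrichments: Mapping[str, Sequence[tuple[str, float, int]]],
    thresholds: Mapping | None = None,
) -> IntegratedModel:
    """Apply the four assembly rules and emit the integrated network.

    Node ids are namespaced (``metabolite:``, ``complex:``, ``cluster:``,
    ``motif:``, ``phenotype:``).  Metabolite signals are routed through
    the sensor complex linked to the target cluster; a strongly
    correlated cluster without a complex keeps its signal edge but
    flagged dangling (the case is biologically open, not silently
    dropped).  Motif edges record their evidence channel: ``complex_tf``
    (known motif of a complex transcription factor) versus ``enriched``
    (statistical enrichment in the cluster).  Assembly is a pure
    function of its inputs: re-running it, in any input order, yields
    the same graph.
    """
    g = nx.DiGraph()
    cluster_complexes: dict[str, list[str]] = {}
    for cx_id, cl_id, shared in complex_links:
        cluster_complexes.setdefault(cl_id, []).append(cx_id)
        g.add_node(f"complex:{cx_id}", kind="complex")
        g.add_node(f"cluster:{cl_id}", kind="cluster")
        g.add_edge(
            f"complex:{cx_id}", f"cluster:{cl_id}",
            rule=1, relation="regulates", shared_genes=list(shared),
        )

    for link in metabolite_links:
        g.add_node(f"metabolite:{link.metabolite}", kind="metabolite")
        g.add_node(f"cluster:{link.cluster}", kind="cluster")
        via = sorted(cluster_complexes.get(link.cluster, []))
        if not via:
            warnings.warn(
                f"metabolite {link.metabolite} strongly correlates with "
                f"{link.cluster}, which has no linked sensor complex; "
                "emitting a dangling signal edge",
                stacklevel=2,
            )
        g.add_edge(
            f"metabolite:{link.metabolite}", f"cluster:{link.cluster}",
            rule=2, relation="signals", r=link.r,
            coupling="synthesis" if link.sign < 0 else "consumption",
            via_complexes=via, dangling=not via,
        )

    for cx_id, cl_id, motif, count in complex_tf_motifs:
        g.add_node(f"motif:{motif}", kind="motif")
        g.add_node(f"cluster:{cl_id}", kind="cluster")
        g.add_edge(
            f"motif:{motif}", f"cluster:{cl_id}",
            rule=3, relation="binds", source="complex_tf",
            complex=cx_id, gene_count=int(count),
        )
    for enr in motif_enrichments:
        if not enr.passes:
            continue
        key = (f"motif:{enr.motif}", f"cluster:{enr.cluster}")
        if g.has_edge(*key):  # both evidence channels: keep both labels
            g.edges[key]["source"] = "complex_tf+enriched"
            g.edges[key]["p"] = enr.p
            continue
        g.add_node(key[0], kind="motif")
        g.add_node(key[1], kind="cluster")
        g.add_edge(*key, rule=3, relation="binds", source="enriched",
                   p=enr.p, gene_count=enr.x)

    for cl_id, terms in sorted(cluster_enrichments.items()):
        if f"cluster:{cl_id}" not in g:
            continue
        for term, p, count in terms:
            g.add_node(f"phenotype:{term}", kind="phenotype")
            g.add_edge(
                f"cluster:{cl_id}", f"phenotype:{term}",
                rule=4, relation="phenotype", p=float(p), gene_count=int(count),
            )
    return IntegratedModel(graph=g, thresholds=dict(thresholds or {}))
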