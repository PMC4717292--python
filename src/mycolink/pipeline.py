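"""End-to-end orchestration of the multi-omics inference pipeline.

``run_pipeline`` executes every analysis stage on a (synthetic or
loaded) world: gene filtering, K-means co-expression clustering, term
and motif enrichment, sensor-complex prediction, metabolic turnover
scoring, and the four-rule model assembly.  ``evaluate_recovery``
scores a pipeline result against the world's planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cluster as mc
from . import integrate as mi
from . import motifs as mm
from . import ppi as mp
from . import quant as mq
from . import turnover as mt
from .synthetic import DEFAULT_ALLOWLIST, DEFAULT_TF_MOTIF_MAP, SyntheticWorld

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "evaluate_recovery"]


@dataclass
class PipelineParams:
    """Thresholds of every stage, defaulting to the published settings."""

    cv_threshold: float = 0.33
    k: int = 9
    n_restarts: int = 50
    term_alpha: float = 0.05
    motif_alpha: float = 0.01
    motif_min_genes: int = 10
    neighborhood: int = 5
    pcc_alpha: float = 0.01
    loi_iterations: int = 10_000
    loi_threshold: float = 1.0
    percentile: float = 0.001
    seed: int = 0
    both_strands: bool = False


@dataclass
class PipelineResult:
    filtered_genes: list[str]
    profiles: pd.DataFrame
    clusters: list[mc.GeneCluster]
    term_enrichments: dict[str, list[tuple[str, float, int]]]
    associations: list[mm.MotifAssociation]
    motif_enrichments: list[mm.MotifEnrichment]
    loi: mp.LOITable
    network: mp.CoexpressionNetwork
    filtered_network: mp.CoexpressionNetwork
    complexes: list[mp.SensorComplex]
    turnover: mt.TurnoverScores
    correlation: mi.CorrelationMatrix
    links: list[mi.MetaboliteLink]
    link_cutoffs: tuple[float, float]
    complex_links: list[tuple[str, str, tuple[str, ...]]]
    complex_tf_motifs: list[tuple[str, str, str, int]]
    model: mi.IntegratedModel


def run_pipeline(world: SyntheticWorld, params: PipelineParams | None = None) -> PipelineResult:
    params = params or PipelineParams()
    conditions = list(world.conditions)

    # ---- host: filter, profile, cluster, annotate ------------------------
    filtered = mc.filter_genes(world.expr_host, world.flags_host, params.cv_threshold)
    profiles = mc.condition_profiles(
        world.expr_host.loc[filtered], world.replicate_map, conditions
    )
    clusters = mc.kmeans_cluster(profiles, params.k, seed=params.seed,
                                 n_restarts=params.n_restarts)
    background_all = list(world.expr_host.index)
    term_enrichments = {
        c.id: mc.enrich_terms(c.members, world.annotations, background_all,
                              alpha=params.term_alpha)
        for c in clusters
    }
    for c in clusters:
        c.enriched_terms = term_enrichments[c.id]

    # ---- motifs over the differentially regulated background ------------
    library = world.motif_patterns()
    upstreams = {g: world.upstream_sequences[g] for g in filtered}
    associations = mm.build_associations(upstreams, library, filtered,
                                         both_strands=params.both_strands)
    motif_enrichments = []
    for c in clusters:
        motif_enrichments.extend(
            mm.enrich_motifs(c.id, c.members, associations,
                             alpha=params.motif_alpha, min_genes=params.motif_min_genes)
        )

    # ---- sensor complexes ------------------------------------------------
    loi = mp.compute_loi_table(world.reference_ppi, world.reference_localizations,
                               iterations=params.loi_iterations, seed=params.seed)
    localizations = mp.assign_localizations(world.loc_scores)
    expressed_everywhere = list(world.flags_host.index[world.flags_host.all(axis=1)])
    network = mp.grvn_network(world.compendium, allowed=expressed_everywhere,
                              neighborhood=params.neighborhood, alpha=params.pcc_alpha)
    filtered_network = mp.filter_candidate_edges(
        network, loi, localizations, world.flags_host,
        DEFAULT_ALLOWLIST, world.annotations, loi_threshold=params.loi_threshold,
    )
    complexes = mp.extract_complexes(filtered_network, world.annotations)

    # ---- symbiont metabolic turnover --------------------------------------
    qn = mq.quantile_normalize(world.expr_symbiont)
    uef = mt.uef_abundance(qn, world.ec_annotations)
    uef_cond = mq.average_replicates(uef, world.symbiont_replicate_map, conditions)
    mnet = mt.build_network(world.reaction_table, world.allowed_pathways)
    turnover = mt.prmt_scores(uef_cond, mnet)

    # ---- integration -----------------------------------------------------
    correlation = mi.correlate(turnover.scores, clusters, conditions)
    links, cutoffs = mi.select_strong_links(correlation, percentile=params.percentile)
    complex_links = mi.link_complexes_to_clusters(complexes, clusters)
    carriers = {a.motif: a.carriers for a in associations}
    tf_map = {t: mm.MotifPattern(name, dict(world.config.motif_library)[name])
              for t, name in DEFAULT_TF_MOTIF_MAP.items()}
    complex_tf_motifs = mm.motifs_for_complex_tfs(complexes, tf_map, clusters, carriers)
    model = mi.assemble(
        links, complex_links, complex_tf_motifs, motif_enrichments,
        term_enrichments,
        thresholds={
            "cv_threshold": params.cv_threshold, "k": params.k,
            "motif_alpha": params.motif_alpha, "motif_min_genes": params.motif_min_genes,
            "pcc_alpha": params.pcc_alpha, "loi_threshold": params.loi_threshold,
            "percentile": params.percentile, "seed": params.seed,
        },
    )
    return PipelineResult(
        filtered_genes=filtered, profiles=profiles, clusters=clusters,
        term_enrichments=term_enrichments, associations=associations,
        motif_enrichments=motif_enrichments, loi=loi, network=network,
        filtered_network=filtered_network, complexes=complexes,
        turnover=turnover, correlation=correlation, links=links,
        link_cutoffs=cutoffs, complex_links=complex_links,
        complex_tf_motifs=complex_tf_motifs, model=model,
    )


def _cluster_mapping(world: SyntheticWorld, clusters) -> dict[str, str]:
    """Predicted cluster id -> planted cluster label by majority overlap."""
    truth = world.ground_truth["clusters"]
    mapping = {}
    for c in clusters:
        best, best_n = None, 0
        for lab, info in truth.items():
            n = len(set(c.members) & set(info["members"]))
            if n > best_n:
                best, best_n = lab, n
        if best is not None:
            mapping[c.id] = best
    return mapping


def evaluate_recovery(world: SyntheticWorld, result: PipelineResult) -> dict:
    """Score a pipeline run against the planted truth.

    Returns cluster ARI, planted-motif enrichment recall, per-complex
    node Jaccard, and metabolite-link recall / false-link count.
    """
    truth = world.ground_truth

    # clustering: ARI over the filtered genes that belong to planted clusters
    true_label = {}
    for lab, info in truth["clusters"].items():
        for g in info["members"]:
            true_label[g] = lab
    pred_label = {}
    for c in result.clusters:
        for g in c.members:
            pred_label[g] = c.id
    common = [g for g in result.filtered_genes if g in true_label]
    ari = adjusted_rand_score(
        [true_label[g] for g in common], [pred_label[g] for g in common]
    ) if common else 0.0

    mapping = _cluster_mapping(world, result.clusters)
    reverse = {}
    for pred, lab in mapping.items():
        reverse.setdefault(lab, []).append(pred)

    # planted motif enrichments recovered among passing calls
    passing = {(e.cluster, e.motif) for e in result.motif_enrichments if e.passes}
    planted = [
        (lab, info["motif"]) for lab, info in truth["clusters"].items() if "motif" in info
    ]
    hit = sum(
        1 for lab, motif in planted
        if any((pred, motif) in passing for pred in reverse.get(lab, []))
    )
    motif_recall = hit / len(planted) if planted else float("nan")

    # complexes: best node Jaccard per planted complex
    found_sets = [set(cx.nodes) for cx in result.complexes]
    jaccards = []
    for cx in truth["complexes"]:
        nodes = set(cx["roles"])
        best = max(
            (len(nodes & f) / len(nodes | f) for f in found_sets), default=0.0
        )
        jaccards.append(best)

    # metabolite links: predicted (metabolite, planted cluster) pairs
    planted_links = {(l["metabolite"], l["cluster"]) for l in truth["metabolite_links"]}
    predicted = {(l.metabolite, mapping.get(l.cluster)) for l in result.links}
    tp = len(planted_links & predicted)
    link_recall = tp / len(planted_links) if planted_links else float("nan")
    false_links = len(predicted - planted_links)

    # sign agreement of recovered links
    sign_ok = 0
    truth_sign = {(l["metabolite"], l["cluster"]): l["sign"] for l in truth["metabolite_links"]}
    for l in result.links:
        key = (l.metabolite, mapping.get(l.cluster))
        if key in truth_sign and np.sign(l.r) == truth_sign[key]:
            sign_ok += 1

    return {
        "cluster_ari": float(ari),
        "motif_recall": float(motif_recall),
        "complex_jaccards": jaccards,
        "complex_jaccard_mean": float(np.mean(jaccards)) if jaccards else float("nan"),
        "link_recall": float(link_recall),
        "false_links": int(false_links),
        "link_sign_matches": int(sign_ok),
        "n_filtered_genes": len(result.filtered_genes),
        "n_complexes_found": len(result.complexes),
    }
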