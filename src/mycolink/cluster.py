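"""Co-expression clustering of condition-level fold-change profiles.

Genes significantly expressed in *every* sample and variable across
samples (coefficient of variation above a threshold on the untransformed
scale) are reduced to per-condition log2 fold-change profiles (replicates
averaged first) and grouped by K-means on Euclidean distance.  Clusters
are annotated by upper-tail binomial enrichment of functional terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .quant import average_replicates
from .stats import binomial_enrichment_pvalue

__all__ = [
    "GeneCluster",
    "coefficient_of_variation",
    "filter_genes",
    "condition_profiles",
    "kmeans_cluster",
    "enrich_terms",
]


@dataclass
class GeneCluster:
    """A co-regulated gene set with its mean fold-change profile."""

    id: str
    members: tuple[str, ...]
    mean_profile: pd.Series
    enriched_terms: list[tuple[str, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.id} has no members")


def coefficient_of_variation(values: pd.DataFrame) -> pd.Series:
    """Per-gene SD / mean over samples, on the untransformed scale (ddof=1)."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    return cv.where(mean != 0, 0.0)


def filter_genes(
    values: pd.DataFrame,
    flags: pd.DataFrame,
    cv_threshold: float = 0.33,
) -> list[str]:
    """Genes significant in every sample AND with CV above the threshold.

    ``values`` is untransformed expression (e.g. bootstrap mean RPKM),
    gene x sample; ``flags`` the aligned boolean significance calls.  An
    empty result is allowed.
    """
    if not flags.index.equals(values.index) or list(flags.columns) != list(values.columns):
        raise ValueError("significance flags not aligned with the expression matrix")
    keep = flags.all(axis=1) & (coefficient_of_variation(values) > cv_threshold)
    return list(values.index[keep])


def condition_profiles(
    values: pd.DataFrame,
    replicate_map: Mapping[str, str],
    conditions: list[str],
) -> pd.DataFrame:
    """Per-condition log2 fold-change profiles (gene x condition).

    Replicates are averaged per condition on the untransformed scale,
    then each gene's profile is ``log2(condition mean) - mean over
    conditions of log2(condition mean)``, i.e. deviation from the gene's
    (geometric-mean) baseline.  Profiles therefore average to zero across
    conditions by construction.
    """
    cond_means = average_replicates(values, replicate_map, conditions)
    with np.errstate(divide="ignore"):
        log2c = np.log2(cond_means)
    return log2c.sub(log2c.mean(axis=1), axis=0)


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
) -> list[GeneCluster]:
    """K-means on fold-change profiles; best of ``n_restarts`` by WCSS.

    Deterministic for a fixed seed.  Cluster ids are assigned in order of
    decreasing size (ties broken by smallest member id) as C1, C2, ...
    """
    if not 1 <= k <= len(profiles):
        raise ValueError(f"k={k} outside [1, {len(profiles)}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    groups: dict[int, list[str]] = {}
    for gene, lab in zip(profiles.index, labels):
        groups.setdefault(int(lab), []).append(gene)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    clusters = []
    for i, members in enumerate(ordered, start=1):
        members = tuple(sorted(members))
        clusters.append(
            GeneCluster(
                id=f"C{i}",
                members=members,
                mean_profile=profiles.loc[list(members)].mean(axis=0),
            )
        )
    return clusters


def enrich_terms(
    members: Iterable[str],
    annotations: Mapping[str, frozenset[str] | set[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> list[tuple[str, float, int]]:
    """Binomially enriched annotation terms in a gene set.

    For each term present in the background, ``p = P(X >= x)`` with
    ``X ~ Binomial(n, f)`` where n is the cluster size, x the member
    carrier count and f the term's background frequency.  Terms with
    ``p < alpha`` are returned as ``(term, p, carrier count)`` sorted by
    p.  Terms absent from the background are skipped.
    """
    members = sorted(set(members))
    background = sorted(set(background))
    if not set(members) <= set(background):
        raise ValueError("cluster members must be a subset of the background")
    n_bg = len(background)
    bg_count: dict[str, int] = {}
    for g in background:
        for t in annotations.get(g, ()):  # genes may be unannotated
            bg_count[t] = bg_count.get(t, 0) + 1
    out = []
    n = len(members)
    for term, bg in sorted(bg_count.items()):
        f = bg / n_bg
        x = sum(1 for g in members if term in annotations.get(g, ()))
        p = binomial_enrichment_pvalue(x, n, f)
        if p < alpha:
            out.append((term, p, x))
    out.sort(key=lambda r: (r[1], r[0]))
    return out
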