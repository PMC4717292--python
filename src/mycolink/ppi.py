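"""Sensor-complex prediction from co-expression and interaction likelihoods.

The chain is: (i) build a rank-based co-expression network over a large
expression compendium (each gene proposes its top-k correlated partners,
edges kept when the Pearson correlation is significant); (ii) score every
pair of subcellular-localization annotations by how often such pairs
interact in a reference protein-protein interaction set versus a
degree-preserving permutation null (likelihood-of-interaction, LOI,
Z-scores); (iii) retain co-expression edges whose endpoints are
expressed, carry sensing-relevant functions, and are localized
compatibly (edge LOI > threshold); (iv) read off connected components as
candidate sensor complexes with role-typed nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import pearson_pvalue

__all__ = [
    "CoexpressionEdge",
    "CoexpressionNetwork",
    "LOITable",
    "SensorComplex",
    "grvn_network",
    "compute_loi_table",
    "assign_localizations",
    "filter_candidate_edges",
    "extract_complexes",
    "DEFAULT_ROLE_TERMS",
]


@dataclass
class CoexpressionEdge:
    genes: tuple[str, str]  # lexicographically sorted
    r: float
    p: float
    proposed_by: frozenset[str]
    loi: float | None = None


@dataclass
class CoexpressionNetwork:
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], CoexpressionEdge]

    def __post_init__(self) -> None:
        for key in self.edges:
            if key[0] == key[1]:
                raise ValueError(f"self edge {key}")
            if key != tuple(sorted(key)):
                raise ValueError(f"edge key not sorted: {key}")


def grvn_network(
    values: pd.DataFrame,
    allowed: Iterable[str] | None = None,
    neighborhood: int = 5,
    alpha: float = 0.01,
    mutual: bool = False,
) -> CoexpressionNetwork:
    """Rank-based co-expression network ("value neighborhood" construction).

    Every allowed gene ranks all other allowed genes by Pearson
    correlation over the compendium samples and proposes its top
    ``neighborhood`` partners; a proposed edge is kept when the two-sided
    t-test on r (n-2 df) gives p < ``alpha``.  The edge set is the union
    of proposals (``mutual=True`` restricts to reciprocal proposals).
    Ties at the neighborhood boundary break lexicographically on gene id
    for determinism; constant-expression genes are excluded with a
    warning.
    """
    n_samples = values.shape[1]
    if n_samples < 4:
        raise ValueError("compendium needs >= 4 samples for correlation significance")
    genes = sorted(set(allowed)) if allowed is not None else sorted(values.index)
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"allowed genes absent from compendium: {missing[:5]}")
    sub = values.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    constant = list(sub.index[sd == 0])
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant-expression gene(s) from ranking",
            stacklevel=2,
        )
        genes = [g for g in genes if g not in set(constant)]
        sub = values.loc[genes]
    if len(genes) < 2:
        return CoexpressionNetwork(tuple(genes), {})

    corr = np.corrcoef(sub.to_numpy(dtype=float))
    proposals: dict[tuple[str, str], set[str]] = {}
    for i, g in enumerate(genes):
        order = sorted(
            (j for j in range(len(genes)) if j != i),
            key=lambda j: (-corr[i, j], genes[j]),
        )
        for j in order[:neighborhood]:
            if pearson_pvalue(corr[i, j], n_samples) < alpha:
                key = tuple(sorted((g, genes[j])))
                proposals.setdefault(key, set()).add(g)

    edges = {}
    for key, proposers in sorted(proposals.items()):
        if mutual and len(proposers) < 2:
            continue
        i, j = genes.index(key[0]), genes.index(key[1])
        edges[key] = CoexpressionEdge(
            genes=key,
            r=float(corr[i, j]),
            p=pearson_pvalue(corr[i, j], n_samples),
            proposed_by=frozenset(proposers),
        )
    return CoexpressionNetwork(tuple(genes), edges)


def _split_labels(labels: Iterable[str]) -> frozenset[str]:
    """Pre-split compound localization labels: 'nuclear:cytoplasm' -> both."""
    out = set()
    for lab in labels:
        out.update(part for part in lab.split(":") if part)
    return frozenset(out)


@dataclass
class LOITable:
    """Z-scores per unordered localization-annotation pair.

    ``z[(a, b)]`` (keys sorted) measures how over- or under-represented
    interactions between proteins annotated ``a`` and ``b`` are in the
    reference interaction set, against a degree-preserving permutation
    null; pairs whose null count never varies get Z = 0 by convention.
    """

    z: dict[tuple[str, str], float]
    observed: dict[tuple[str, str], float]
    null_mean: dict[tuple[str, str], float]
    null_sd: dict[tuple[str, str], float]
    iterations: int

    def score(self, labels_a: Iterable[str], labels_b: Iterable[str]) -> float:
        """Edge LOI: maximum Z over all label pairings of the two proteins.

        An interaction is deemed possible if *any* compatible localization
        pairing supports it.  Label pairs never seen in the reference
        vocabulary score 0.
        """
        la = _split_labels(labels_a)
        lb = _split_labels(labels_b)
        best = -np.inf
        for a in la:
            for b in lb:
                best = max(best, self.z.get(tuple(sorted((a, b))), 0.0))
        if not np.isfinite(best):
            raise ValueError("protein without localization labels")
        return best


def _pair_counts_observed(
    edges: Sequence[tuple[str, str]],
    label_sets: Mapping[str, frozenset[str]],
    label_index: Mapping[str, int],
    n_labels: int,
) -> np.ndarray:
    counts = np.zeros(n_labels * n_labels)
    for a, b in edges:
        for la in label_sets[a]:
            for lb in label_sets[b]:
                i, j = sorted((label_index[la], label_index[lb]))
                counts[i * n_labels + j] += 1
    return counts


def compute_loi_table(
    reference: Sequence[tuple[str, str]],
    annotations: Mapping[str, Iterable[str]],
    iterations: int = 10_000,
    seed: int = 0,
    batch_size: int = 500,
) -> LOITable:
    """Likelihood-of-interaction Z-scores from a reference PPI edge list.

    Observed counts: each reference edge contributes one count to every
    (label of endpoint 1, label of endpoint 2) pair; proteins with
    several labels (including pre-split compound labels) contribute each
    combination.  Null: configuration-model resampling -- the 2E endpoint
    slots of the edge list are randomly re-paired, preserving every
    protein's degree in every iteration.  Z = (observed - null mean) /
    null SD, with Z = 0 where the null SD is zero.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    proteins = sorted({p for e in reference for p in e})
    label_sets = {}
    for p in proteins:
        if p not in annotations:
            raise KeyError(f"reference protein without localization annotation: {p}")
        labs = _split_labels(annotations[p])
        if not labs:
            raise ValueError(f"reference protein with empty localization: {p}")
        label_sets[p] = labs
    labels = sorted({l for labs in label_sets.values() for l in labs})
    lab_idx = {l: i for i, l in enumerate(labels)}
    n_lab = len(labels)

    observed = _pair_counts_observed(reference, label_sets, lab_idx, n_lab)

    # Padded per-protein label matrix for vectorised null counting.
    max_k = max(len(l) for l in label_sets.values())
    padded = np.full((len(proteins), max_k), -1, dtype=np.int64)
    for pi, p in enumerate(proteins):
        for ki, l in enumerate(sorted(label_sets[p])):
            padded[pi, ki] = lab_idx[l]

    prot_idx = {p: i for i, p in enumerate(proteins)}
    stubs = np.array([prot_idx[p] for e in reference for p in e], dtype=np.int64)
    n_pairs_flat = n_lab * n_lab
    total = np.zeros(n_pairs_flat)
    total_sq = np.zeros(n_pairs_flat)
    rng = np.random.default_rng(seed)
    done = 0
    while done < iterations:
        b = min(batch_size, iterations - done)
        perms = rng.permuted(np.tile(stubs, (b, 1)), axis=1)  # (b, 2E)
        pa = perms[:, 0::2]  # (b, E)
        pb = perms[:, 1::2]
        la = padded[pa]  # (b, E, K)
        lb = padded[pb]
        ai = la[:, :, :, None]  # (b, E, K, 1)
        bi = lb[:, :, None, :]  # (b, E, 1, K)
        valid = (ai >= 0) & (bi >= 0)
        lo = np.minimum(ai, bi)
        hi = np.maximum(ai, bi)
        flat = np.where(valid, lo * n_lab + hi, 0)
        batch_offsets = (np.arange(b) * n_pairs_flat)[:, None, None, None]
        binned = np.bincount(
            (flat + batch_offsets).ravel(),
            weights=valid.astype(np.float64).ravel(),
            minlength=b * n_pairs_flat,
        ).reshape(b, n_pairs_flat)
        total += binned.sum(axis=0)
        total_sq += (binned * binned).sum(axis=0)
        done += b

    mean = total / iterations
    var = np.maximum(total_sq / iterations - mean * mean, 0.0)
    sd = np.sqrt(var)

    z, obs_d, mean_d, sd_d = {}, {}, {}, {}
    for i in range(n_lab):
        for j in range(i, n_lab):
            key = (labels[i], labels[j])
            flat_ij = i * n_lab + j
            o, mu, s = observed[flat_ij], mean[flat_ij], sd[flat_ij]
            z[key] = float((o - mu) / s) if s > 0 else 0.0
            obs_d[key] = float(o)
            mean_d[key] = float(mu)
            sd_d[key] = float(s)
    return LOITable(z=z, observed=obs_d, null_mean=mean_d, null_sd=sd_d, iterations=iterations)


def assign_localizations(
    scores: Mapping[str, Mapping[str, float]],
) -> dict[str, frozenset[str]]:
    """Top-scoring localization label(s) per protein (WoLF-PSORT style).

    The argmax annotation is assigned; tied top scores assign every tied
    label; compound labels split on ':' into their components.
    """
    out = {}
    for protein, smap in scores.items():
        if not smap:
            raise ValueError(f"protein {protein!r} has no localization scores")
        best = max(smap.values())
        winners = [lab for lab, s in smap.items() if s == best]
        out[protein] = _split_labels(winners)
    return out


def filter_candidate_edges(
    network: CoexpressionNetwork,
    loi: LOITable,
    localizations: Mapping[str, Iterable[str]],
    flags: pd.DataFrame | Mapping[str, bool],
    functional_allowlist: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    loi_threshold: float = 1.0,
) -> CoexpressionNetwork:
    """Retain edges whose endpoints can plausibly physically interact.

    An edge survives iff (i) both proteins are significantly expressed in
    every in-house sample, (ii) both carry at least one allow-listed
    (sensing/signalling-relevant) functional annotation, and (iii) the
    edge LOI score -- the maximum Z over the endpoints' localization
    label pairs -- exceeds ``loi_threshold``.  Raising the threshold can
    only remove edges.
    """
    if isinstance(flags, pd.DataFrame):
        sig_all = flags.all(axis=1).to_dict()
    else:
        sig_all = dict(flags)
    allow = set(functional_allowlist)

    def ok(gene: str) -> bool:
        if not sig_all.get(gene, False):
            return False
        return bool(set(annotations.get(gene, ())) & allow)

    edges = {}
    for key, edge in network.edges.items():
        a, b = key
        if not (ok(a) and ok(b)):
            continue
        score = loi.score(localizations[a], localizations[b])
        if score > loi_threshold:
            edges[key] = CoexpressionEdge(
                genes=key, r=edge.r, p=edge.p,
                proposed_by=edge.proposed_by, loi=score,
            )
    return CoexpressionNetwork(network.nodes, edges)


#: role precedence: first matching rule wins; anything else is a cascade protein.
DEFAULT_ROLE_TERMS: tuple[tuple[str, frozenset[str]], ...] = (
    ("receptor", frozenset({"transmembrane_receptor", "receptor", "receptor_kinase"})),
    ("transcription_factor", frozenset({"transcription_factor"})),
    ("defense", frozenset({"defense_response", "defense_response_to_pathogen"})),
)


def assign_role(
    terms: Iterable[str],
    role_terms: tuple[tuple[str, frozenset[str]], ...] = DEFAULT_ROLE_TERMS,
) -> str:
    terms = set(terms)
    for role, vocab in role_terms:
        if terms & vocab:
            return role
        if role == "transcription_factor" and any(t.startswith("tf_class_") for t in terms):
            return role
    return "cascade"


@dataclass
class SensorComplex:
    """A connected component of the filtered network, with role-typed nodes."""

    id: str
    nodes: dict[str, str]  # gene -> role
    edges: list[tuple[str, str]]
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    linked_clusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError(f"complex {self.id} smaller than 2 proteins")

    @property
    def size(self) -> int:
        return len(self.nodes)


def extract_complexes(
    network: CoexpressionNetwork,
    annotations: Mapping[str, Iterable[str]],
    role_terms: tuple[tuple[str, frozenset[str]], ...] = DEFAULT_ROLE_TERMS,
) -> list[SensorComplex]:
    """Connected components of the filtered network as candidate complexes.

    Components of size >= 2 are reported in order of decreasing size
    (ties by smallest member id); each node is role-typed from its
    functional annotations (receptor > transcription factor > defense >
    cascade).  Pair-only components are legitimate output -- most of the
    published subnetworks are pairs -- and can be screened downstream.
    """
    g = nx.Graph()
    g.add_nodes_from(n for key in network.edges for n in key)
    g.add_edges_from(network.edges)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) >= 2),
        key=lambda c: (-len(c), c[0]),
    )
    out = []
    for i, members in enumerate(comps, start=1):
        mset = set(members)
        out.append(
            SensorComplex(
                id=f"complex_{i}",
                nodes={m: assign_role(annotations.get(m, ()), role_terms) for m in members},
                edges=sorted(k for k in network.edges if k[0] in mset and k[1] in mset),
                annotations={m: frozenset(annotations.get(m, ())) for m in members},
            )
        )
    return out
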