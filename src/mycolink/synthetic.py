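"""Synthetic plant-root / fungus interaction worlds with planted ground truth.

The generator emulates the full study design of a pre-mycorrhizal
interaction experiment: a host (aspen-root-like) transcriptome and a
symbiont (ectomycorrhizal-fungus-like) transcriptome sampled over eight
conditions -- free-living (FL), six membrane-separated interaction time
points (6h..96h) and fully formed mycorrhizae (Myc) -- with two
replicates of the free-living and mycorrhizal states and one sample per
time point, exactly ten transcriptomes per organism.

Planted, recoverable structure:

* co-regulated host gene clusters, each following a distinct log2
  fold-change profile over the conditions (plus lognormal noise);
* IUPAC binding-motif instances inserted in the 1000 bp upstream regions
  of cluster genes at a configured carrier fraction, against a
  background insertion rate;
* sensor complexes -- small receptor / cascade / transcription-factor
  protein sets inside chosen clusters that co-express across an
  external compendium, carry sensing-relevant annotations, and are
  localized so that their interactions are compatible in a
  localization-structured reference PPI set;
* metabolite-cluster couplings on the symbiont side: dedicated enzymes
  consuming (or producing) a signal metabolite whose expression tracks
  (or anti-tracks) a host cluster's profile, embedded in a background
  reaction table;
* a silent-gene fraction so that roughly two thirds of host genes are
  called significantly expressed, as in real root transcriptomes.

Every stage of the pipeline can therefore be scored against
``world.ground_truth`` without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .motifs import IUPAC_CODES, MotifPattern
from .quant import AlignmentTable
from .turnover import ReactionRecord

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "generate_alignments",
    "export_world",
    "load_world",
    "worlds_equal",
    "DEFAULT_MOTIF_LIBRARY",
    "DEFAULT_TF_MOTIF_MAP",
    "DEFAULT_ALLOWLIST",
]

DEFAULT_CONDITIONS = ("FL", "6h", "12h", "24h", "48h", "72h", "96h", "Myc")
#: replicate counts per condition: 2 free-living, 1 per time point, 2 mycorrhizal
DEFAULT_REPLICATES = (2, 1, 1, 1, 1, 1, 1, 2)

#: PLACE-style motif library. The first nine are the planting defaults for the
#: nine clusters; the trailing short motifs are scanned but occur upstream of
#: nearly every gene by chance, so they can never be enriched -- deliberately
#: kept as realistic negative controls.
DEFAULT_MOTIF_LIBRARY: tuple[tuple[str, str], ...] = (
    ("MYB1AT", "WAACCA"),
    ("MARTBOX", "TTWTWTTWTT"),
    ("HSE", "CTNGAANNTTCNAG"),
    ("SURE1STPAT21", "AATAGAAAA"),
    ("CARGATCONSENSUS", "CCWWWWWWGG"),
    ("E2FCONSENSUS", "WTTSSCSS"),
    ("RBCSCONSENSUS", "AATCCAA"),
    ("WBOXNT", "TTTGACY"),
    ("GBOXEXT", "CACGTGGC"),
    ("CAATBOX1", "CAAT"),
    ("ARR1AT", "NGATT"),
    ("CACTFTPPCA1", "YACT"),
    ("BIHD1OS", "TGTCA"),
)
PLANTED_MOTIF_NAMES = tuple(name for name, _ in DEFAULT_MOTIF_LIBRARY[:9])

LOCALIZATIONS = (
    "plasma_membrane", "cytoplasm", "nuclear",
    "extracellular", "mitochondria", "vacuole",
)

#: relative interaction propensity per localization pair in the reference PPI
#: set; pairs not listed default to 0.05.  The structure is block-assortative:
#: the signalling route (membrane <-> cytoplasm <-> nucleus) interacts within
#: itself, organelle compartments interact within themselves, and the two
#: blocks barely mix.  Because the LOI null preserves degrees, a label pair is
#: only enriched when pairing is assortative *beyond* degree -- organelle
#: proteins must therefore carry real degree of their own for the signalling
#: pairs to score Z > 1.  Membrane-nucleus contact is explicitly disfavoured
#: (receptors do not touch transcription factors directly).
DEFAULT_PPI_PAIR_PREFERENCES: tuple[tuple[str, str, float], ...] = (
    ("plasma_membrane", "cytoplasm", 4.0),
    ("cytoplasm", "cytoplasm", 4.0),
    ("cytoplasm", "nuclear", 4.0),
    ("nuclear", "nuclear", 4.0),
    ("plasma_membrane", "plasma_membrane", 4.0),
    ("nuclear", "plasma_membrane", 0.05),
    ("extracellular", "extracellular", 4.0),
    ("extracellular", "mitochondria", 4.0),
    ("extracellular", "vacuole", 4.0),
    ("mitochondria", "mitochondria", 4.0),
    ("mitochondria", "vacuole", 4.0),
    ("vacuole", "vacuole", 4.0),
)
DEFAULT_PAIR_PREFERENCE = 0.05

#: sampling frequency of each localization label among reference proteins
DEFAULT_LOCALIZATION_PROBS = (0.15, 0.15, 0.15, 0.1834, 0.1833, 0.1833)

#: GO-biological-process-like terms; term i is planted in cluster i.
CLUSTER_TERMS = (
    "glucan_metabolism", "electron_transport", "lipid_metabolism",
    "oxidative_stress_response", "apoptosis", "cell_adhesion",
    "fatty_acid_biosynthesis", "defense_response_to_pathogen",
    "cell_wall_modification",
)
BACKGROUND_TERMS = (
    "carbohydrate_metabolism", "transport", "protein_phosphorylation",
    "metabolism",
)
SENSING_TERMS = ("transmembrane_receptor", "protein_kinase_cascade", "transcription_factor")
#: functions relevant to environmental sensing and signal transduction
#: (example vocabulary standing in for a curated annotation allow-list)
DEFAULT_ALLOWLIST = frozenset(SENSING_TERMS) | {"defense_signaling"}
#: TF class annotation -> known binding motif; classes like ERF have no
#: specific motif and are deliberately absent.
DEFAULT_TF_MOTIF_MAP = {
    "tf_class_HSF": "HSE",
    "tf_class_MADS": "CARGATCONSENSUS",
    "tf_class_E2F": "E2FCONSENSUS",
}

ALLOWED_PATHWAYS = ("map00510", "map01060", "map01061", "map01063", "map07070")
OTHER_PATHWAYS = ("map00190", "map00500")
CURRENCY_METS = ("ATP", "ADP", "H2O", "NADH")

#: planted sensor complexes: (id, 1-based cluster, receptors, cascades,
#: TF classes, defense proteins).  Sizes stay <= 6 so every member's
#: top-5 co-expression neighborhood covers all of its partners.
DEFAULT_COMPLEX_PLAN = (
    ("A", 2, 2, 2, ("tf_class_HSF", "tf_class_ERF"), 0),
    ("B", 5, 2, 3, ("tf_class_MADS",), 0),
    ("C", 7, 2, 2, ("tf_class_E2F",), 1),
    ("D", 9, 2, 4, (), 0),
)

#: planted signal couplings: metabolite, host cluster, sign (+1: symbiont
#: consumption tracks host expression; -1: symbiont synthesis tracks it).
DEFAULT_METABOLITE_LINKS = (
    ("pyruvate", "cluster_2", 1),
    ("dextrin", "cluster_5", 1),
    ("hexanoyl-CoA", "cluster_7", 1),
    ("salicylate", "cluster_9", -1),
    ("jasmonate", "cluster_1", -1),
    ("p-coumaroyl-CoA", "cluster_3", -1),
)


def _default_profiles(conditions: Sequence[str], k: int, a: float) -> list[np.ndarray]:
    """Nine distinguishable time-course shapes over the 8-condition design."""
    if len(conditions) != 8:
        raise ValueError("default profiles assume the 8-condition design; supply cluster_profiles")
    # No pair of shapes is a mirror of another (max off-target |r| ~ 0.77
    # after centering), so metabolite couplings resolve to a unique cluster.
    shapes = [
        [0, -a, -a, -a, -a, -a, -a, 0],  # down throughout interaction
        [0, +a, +a, +a, +a, +a, +a, +a],  # up in interaction, stays up in Myc
        [0, -a, -a, -a, 0, 0, 0, 0],      # down early
        [0, 0, 0, 0, -a, -a, -a, 0],      # down late
        [0, 0, -a, -a, -a, -a, 0, 0],     # transient down, mid
        [0, +a, +a, 0, 0, 0, 0, 0],       # sharp early induction
        [0, 0, 0, 0, 0, +a, +a, +a],      # late induction persisting in Myc
        [0, +a, +a, +a, +a, 0, 0, 0],     # early induction, decays
        [0, 0, 0, +a, +a, +a, +a, +a],    # delayed induction incl. Myc
    ]
    if k > len(shapes):
        raise ValueError(f"only {len(shapes)} default profiles; supply cluster_profiles for k={k}")
    return [np.array(s, dtype=float) for s in shapes[:k]]


@dataclass
class WorldConfig:
    """Everything the generator needs; defaults mirror the study design."""

    seed: int = 0
    n_host_genes: int = 600
    n_symbiont_genes: int = 1000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates: tuple[int, ...] = DEFAULT_REPLICATES
    n_clusters_planted: int = 9
    cluster_size: int = 30
    cluster_profiles: tuple[tuple[float, ...], ...] | None = None
    profile_amplitude: float = 2.0
    noise_sd: float = 0.25
    silent_fraction: float = 0.33
    base_log2_range: tuple[float, float] = (4.0, 8.0)
    motif_library: tuple[tuple[str, str], ...] = DEFAULT_MOTIF_LIBRARY
    planted_motif_enrichment: tuple[tuple[str, str, float], ...] | None = None
    background_motif_frequency: float = 0.05
    upstream_length: int = 1000
    localization_labels: tuple[str, ...] = LOCALIZATIONS
    ppi_pair_preferences: tuple[tuple[str, str, float], ...] = DEFAULT_PPI_PAIR_PREFERENCES
    n_reference_proteins: int = 200
    n_reference_ppis: int = 600
    reaction_table_size: tuple[int, int, int] = (150, 320, 250)  # ECs, reactions, metabolites
    planted_metabolite_links: tuple[tuple[str, str, int], ...] | None = None
    ecs_per_link: int = 3
    symbiont_condition_sd: float = 0.5
    reads_per_sample: int = 20_000
    multimap_fraction: float = 0.1
    compendium_samples: int = 60
    compendium_noise_sd: float = 0.5

    def validate(self) -> None:
        for name in ("silent_fraction", "background_motif_frequency", "multimap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if len(self.replicates) != len(self.conditions):
            raise ValueError("one replicate count per condition required")
        if any(r < 1 for r in self.replicates):
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sd < 0 or self.compendium_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        k = self.n_clusters_planted
        if self.cluster_profiles is not None:
            if len(self.cluster_profiles) != k:
                raise ValueError("one profile per planted cluster required")
            for p in self.cluster_profiles:
                if len(p) != len(self.conditions):
                    raise ValueError("profile length must equal the number of conditions")
        if k * self.cluster_size > self.n_host_genes:
            raise ValueError("planted clusters exceed the host gene count")
        lib = dict(self.motif_library)
        for cl, motif, frac in self.resolved_motif_planting():
            if motif not in lib:
                raise ValueError(f"planted motif {motif!r} not in library")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"carrier fraction {frac} outside [0, 1]")
            if frac < self.background_motif_frequency:
                raise ValueError(
                    f"planted enrichment {frac} for ({cl}, {motif}) below the "
                    f"background frequency {self.background_motif_frequency}"
                )
        for met, cl, sign in self.resolved_metabolite_links():
            if sign not in (1, -1):
                raise ValueError(f"link sign for {met} must be +1 or -1")
        n_ecs, n_rxn, n_mets = self.reaction_table_size
        if min(n_ecs, n_rxn, n_mets) < 1:
            raise ValueError("reaction table sizes must be positive")
        if n_mets <= len(self.resolved_metabolite_links()) + len(CURRENCY_METS):
            raise ValueError("metabolite pool too small for the planted links")

    # -- resolved defaults -------------------------------------------------
    def cluster_labels(self) -> list[str]:
        return [f"cluster_{i}" for i in range(1, self.n_clusters_planted + 1)]

    def resolved_profiles(self) -> dict[str, np.ndarray]:
        if self.cluster_profiles is not None:
            profs = [np.asarray(p, dtype=float) for p in self.cluster_profiles]
        else:
            profs = _default_profiles(self.conditions, self.n_clusters_planted,
                                      self.profile_amplitude)
        return dict(zip(self.cluster_labels(), profs))

    def resolved_motif_planting(self) -> tuple[tuple[str, str, float], ...]:
        if self.planted_motif_enrichment is not None:
            return tuple(tuple(t) for t in self.planted_motif_enrichment)
        labels = self.cluster_labels()
        if len(labels) > len(PLANTED_MOTIF_NAMES):
            raise ValueError("supply planted_motif_enrichment for > 9 clusters")
        return tuple((lab, PLANTED_MOTIF_NAMES[i], 0.8) for i, lab in enumerate(labels))

    def resolved_metabolite_links(self) -> tuple[tuple[str, str, int], ...]:
        links = (self.planted_metabolite_links
                 if self.planted_metabolite_links is not None
                 else DEFAULT_METABOLITE_LINKS)
        valid = set(self.cluster_labels())
        return tuple((m, c, s) for m, c, s in links if c in valid)

    def resolved_complex_plan(self):
        return tuple(p for p in DEFAULT_COMPLEX_PLAN if p[1] <= self.n_clusters_planted)

    def samples(self) -> list[tuple[str, str]]:
        """(sample name, condition) pairs, e.g. FL_1, FL_2, 6h_1, ..."""
        out = []
        for cond, reps in zip(self.conditions, self.replicates):
            for r in range(1, reps + 1):
                out.append((f"{cond}_{r}", cond))
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def norm(v):
            if isinstance(v, tuple):
                return [norm(x) for x in v]
            if isinstance(v, list):
                return [norm(x) for x in v]
            return v

        return {k: norm(v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        def tup(v):
            if isinstance(v, list):
                return tuple(tup(x) for x in v)
            return v

        return cls(**{k: tup(v) for k, v in d.items()})


@dataclass
class SyntheticWorld:
    """All pipeline inputs plus the planted truth needed to score recovery."""

    config: WorldConfig
    replicate_map: dict[str, str]
    symbiont_replicate_map: dict[str, str]
    upstream_sequences: dict[str, str]
    gene_lengths_host: dict[str, int]
    gene_lengths_symbiont: dict[str, int]
    expression_truth: pd.DataFrame        # host, gene x condition, latent log2
    expr_host: pd.DataFrame               # gene x sample, linear RPKM scale
    flags_host: pd.DataFrame              # boolean significance calls
    symbiont_truth: pd.DataFrame
    expr_symbiont: pd.DataFrame
    compendium: pd.DataFrame              # gene x external sample, log2 scale
    annotations: dict[str, frozenset[str]]
    ec_annotations: dict[str, frozenset[str]]
    loc_scores: dict[str, dict[str, float]]
    reference_ppi: list[tuple[str, str]]
    reference_localizations: dict[str, frozenset[str]]
    reaction_table: list[ReactionRecord]
    allowed_pathways: tuple[str, ...]
    ground_truth: dict
    alignments: dict[str, AlignmentTable] = field(default_factory=dict)

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.config.conditions

    @property
    def host_genes(self) -> list[str]:
        return list(self.expr_host.index)

    def motif_patterns(self) -> list[MotifPattern]:
        return [MotifPattern(n, p) for n, p in self.config.motif_library]


def _random_sequences(rng, genes, length) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(len(genes), length))]
    return {g: "".join(row) for g, row in zip(genes, mat)}


def _realize_iupac(rng, pattern: str) -> str:
    return "".join(IUPAC_CODES[s][rng.integers(len(IUPAC_CODES[s]))] for s in pattern)


def _insert_instance(rng, seq: str, instance: str, occupied: list[tuple[int, int]]):
    """Place an instance at a random offset avoiding previously planted ones."""
    span = len(instance)
    for _ in range(200):
        off = int(rng.integers(0, len(seq) - span + 1))
        if all(off + span <= s or off >= e for s, e in occupied):
            occupied.append((off, off + span))
            return seq[:off] + instance + seq[off + span:]
    return seq  # pathologically crowded; leave unchanged


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Deterministically generate a full synthetic world from a config."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(9)
    (ss_expr, ss_seq, ss_motif, ss_annot, ss_loc,
     ss_ppi, ss_react, ss_comp, ss_symb) = streams

    conditions = list(config.conditions)
    samples = config.samples()
    replicate_map = {s: c for s, c in samples}
    sample_names = [s for s, _ in samples]

    # ---- host genes, clusters, silent set --------------------------------
    host_genes = [f"PtG{i:04d}" for i in range(1, config.n_host_genes + 1)]
    labels = config.cluster_labels()
    members: dict[str, list[str]] = {}
    pos = 0
    for lab in labels:
        members[lab] = host_genes[pos:pos + config.cluster_size]
        pos += config.cluster_size
    background_genes = host_genes[pos:]
    rng_expr = np.random.default_rng(ss_expr)
    n_silent = int(round(config.silent_fraction * config.n_host_genes))
    if n_silent > len(background_genes):
        raise ValueError("silent fraction exceeds the non-clustered gene pool")
    silent = set(rng_expr.choice(background_genes, size=n_silent, replace=False))

    # ---- latent expression and per-sample matrices -----------------------
    lo, hi = config.base_log2_range
    base = rng_expr.uniform(lo, hi, size=config.n_host_genes)
    profiles = config.resolved_profiles()
    latent = np.tile(base[:, None], (1, len(conditions)))
    gene_pos = {g: i for i, g in enumerate(host_genes)}
    for lab in labels:
        for g in members[lab]:
            latent[gene_pos[g]] += profiles[lab]
    for g in silent:
        latent[gene_pos[g]] = rng_expr.uniform(-2.0, 0.0)
    expression_truth = pd.DataFrame(latent, index=host_genes, columns=conditions)

    cond_idx = {c: i for i, c in enumerate(conditions)}
    noise = rng_expr.normal(0.0, config.noise_sd, size=(config.n_host_genes, len(sample_names)))
    expr_vals = np.empty_like(noise)
    for j, s in enumerate(sample_names):
        expr_vals[:, j] = 2.0 ** (latent[:, cond_idx[replicate_map[s]]] + noise[:, j])
    expr_host = pd.DataFrame(expr_vals, index=host_genes, columns=sample_names)
    flag_vec = np.array([g not in silent for g in host_genes])
    flags_host = pd.DataFrame(
        np.tile(flag_vec[:, None], (1, len(sample_names))),
        index=host_genes, columns=sample_names,
    )

    # ---- gene lengths ----------------------------------------------------
    gene_lengths_host = {
        g: int(l) for g, l in zip(host_genes, rng_expr.integers(600, 3001, config.n_host_genes))
    }

    # ---- upstream sequences with planted motif instances -----------------
    rng_seq = np.random.default_rng(ss_seq)
    upstream = _random_sequences(rng_seq, host_genes, config.upstream_length)
    rng_motif = np.random.default_rng(ss_motif)
    lib = dict(config.motif_library)
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in host_genes}
    motif_truth: dict[str, dict] = {}
    for lab, motif_name, frac in config.resolved_motif_planting():
        target = set(members[lab])
        carriers = []
        for g in host_genes:
            p = frac if g in target else config.background_motif_frequency
            if p > 0 and rng_motif.random() < p:
                inst = _realize_iupac(rng_motif, lib[motif_name])
                upstream[g] = _insert_instance(rng_motif, upstream[g], inst, occupied[g])
                if g in target:
                    carriers.append(g)
        motif_truth[lab] = {
            "motif": motif_name, "fraction": frac, "carriers": sorted(carriers),
        }

    # ---- functional annotations -----------------------------------------
    rng_annot = np.random.default_rng(ss_annot)
    annotations: dict[str, set[str]] = {g: set() for g in host_genes}
    for g in host_genes:
        n_terms = 1 + int(rng_annot.random() < 0.5)
        for t in rng_annot.choice(BACKGROUND_TERMS, size=n_terms, replace=False):
            annotations[g].add(str(t))
    for i, lab in enumerate(labels):
        term = CLUSTER_TERMS[i % len(CLUSTER_TERMS)]
        target = set(members[lab])
        for g in host_genes:
            p = 0.55 if g in target else 0.1
            if rng_annot.random() < p:
                annotations[g].add(term)

    # ---- planted sensor complexes ----------------------------------------
    plan = config.resolved_complex_plan()
    complexes_truth = []
    complex_members: dict[str, str] = {}  # gene -> role
    rng_loc = np.random.default_rng(ss_loc)
    loc_scores: dict[str, dict[str, float]] = {}
    for cx_id, cl_num, n_rec, n_casc, tf_classes, n_def in plan:
        lab = f"cluster_{cl_num}"
        pool = members[lab]
        size = n_rec + n_casc + len(tf_classes) + n_def
        nodes = pool[:size]
        roles = {}
        idx = 0
        receptors = nodes[idx:idx + n_rec]; idx += n_rec
        cascades = nodes[idx:idx + n_casc]; idx += n_casc
        tfs = nodes[idx:idx + len(tf_classes)]; idx += len(tf_classes)
        defense = nodes[idx:idx + n_def]
        for g in receptors:
            roles[g] = "receptor"
            annotations[g].add("transmembrane_receptor")
            loc_scores[g] = {"plasma_membrane": 9.0, "cytoplasm": 3.0, "vacuole": 1.0}
        for ci, g in enumerate(cascades):
            roles[g] = "cascade"
            annotations[g].add("protein_kinase_cascade")
            if ci == 0:  # exercises compound-label splitting downstream
                loc_scores[g] = {"nuclear:cytoplasm": 9.0, "mitochondria": 2.0}
            else:
                loc_scores[g] = {"cytoplasm": 9.0, "nuclear": 3.0, "vacuole": 1.0}
        for g, tf_class in zip(tfs, tf_classes):
            roles[g] = "transcription_factor"
            annotations[g].update({"transcription_factor", tf_class})
            loc_scores[g] = {"nuclear": 9.0, "cytoplasm": 3.0}
        for g in defense:
            roles[g] = "defense"
            annotations[g].update({"defense_signaling", "defense_response_to_pathogen"})
            loc_scores[g] = {"cytoplasm": 9.0, "extracellular": 2.0}
        edges = []
        for g in receptors:
            edges.append(tuple(sorted((g, cascades[0]))))
        for a, b in zip(cascades, cascades[1:]):
            edges.append(tuple(sorted((a, b))))
        for g in list(tfs) + list(defense):
            edges.append(tuple(sorted((g, cascades[-1]))))
        complexes_truth.append(
            {"id": cx_id, "cluster": lab, "roles": roles,
             "edges": [list(e) for e in sorted(edges)]}
        )
        complex_members.update(roles)

    # sensing-term noise on non-complex genes (false-edge material)
    for g in host_genes:
        if g in complex_members:
            continue
        if rng_annot.random() < 0.05:
            annotations[g].add(str(rng_annot.choice(SENSING_TERMS)))

    # ---- localization scores for the remaining host proteins -------------
    labels_loc = list(config.localization_labels)
    for g in host_genes:
        if g in loc_scores:
            continue
        picks = rng_loc.choice(labels_loc, size=2, replace=False)
        if rng_loc.random() < 0.02:  # tied top scores: both labels assigned
            loc_scores[g] = {str(picks[0]): 6.0, str(picks[1]): 6.0}
        else:
            loc_scores[g] = {str(picks[0]): 7.0, str(picks[1]): 3.0}

    # ---- reference PPI set (localization-structured) ----------------------
    rng_ppi = np.random.default_rng(ss_ppi)
    ref_proteins = [f"At{i:04d}" for i in range(1, config.n_reference_proteins + 1)]
    loc_probs = np.array(DEFAULT_LOCALIZATION_PROBS[:len(labels_loc)], dtype=float)
    loc_probs = loc_probs / loc_probs.sum()
    ref_loc: dict[str, frozenset[str]] = {}
    for p in ref_proteins:
        if rng_ppi.random() < 0.05:
            ref_loc[p] = frozenset({"nuclear:cytoplasm"})
        else:
            ref_loc[p] = frozenset({str(rng_ppi.choice(labels_loc, p=loc_probs))})
    prefs: dict[tuple[str, str], float] = {}
    for a, b, w in config.ppi_pair_preferences:
        prefs[tuple(sorted((a, b)))] = float(w)
    max_pref = max(prefs.values()) if prefs else 1.0

    def pair_pref(pa: str, pb: str) -> float:
        best = 0.0
        for la in ref_loc[pa]:
            for a_part in la.split(":"):
                for lb in ref_loc[pb]:
                    for b_part in lb.split(":"):
                        best = max(
                            best,
                            prefs.get(tuple(sorted((a_part, b_part))), DEFAULT_PAIR_PREFERENCE),
                        )
        return best

    edges_set: set[tuple[str, str]] = set()
    tries = 0
    limit = config.n_reference_ppis * 2000
    while len(edges_set) < config.n_reference_ppis and tries < limit:
        tries += 1
        i, j = rng_ppi.integers(0, len(ref_proteins), size=2)
        if i == j:
            continue
        pa, pb = sorted((ref_proteins[i], ref_proteins[j]))
        if (pa, pb) in edges_set:
            continue
        if rng_ppi.random() < pair_pref(pa, pb) / max_pref:
            edges_set.add((pa, pb))
    reference_ppi = sorted(edges_set)

    # ---- symbiont: reaction table, EC annotations, expression -------------
    rng_react = np.random.default_rng(ss_react)
    n_bg_ecs, n_bg_rxn, n_mets = config.reaction_table_size
    links = config.resolved_metabolite_links()
    n_bg_mets = n_mets - len(links) - len(CURRENCY_METS)
    bg_mets = [f"met_{i:03d}" for i in range(1, n_bg_mets + 1)]
    bg_met_pool = bg_mets + list(CURRENCY_METS)

    reactions: list[ReactionRecord] = []
    link_truth = []
    planted_ec_of_link: dict[int, list[str]] = {}
    for li, (met, lab, sign) in enumerate(links):
        ecs = []
        for j in range(config.ecs_per_link):
            ec = f"1.14.{li + 1}.{j + 1}"
            currency = CURRENCY_METS[(li + j) % len(CURRENCY_METS)]
            if sign > 0:
                reactants, products = (met,), (currency,)
            else:
                reactants, products = (currency,), (met,)
            reactions.append(ReactionRecord(
                ec=ec, reaction_id=f"R9{li:02d}{j:02d}",
                reactants=reactants, products=products,
                pathway=ALLOWED_PATHWAYS[li % len(ALLOWED_PATHWAYS)],
            ))
            ecs.append(ec)
        planted_ec_of_link[li] = ecs
        link_truth.append({"metabolite": met, "cluster": lab, "sign": sign, "ecs": ecs})

    bg_ecs = [f"2.7.1.{i}" for i in range(1, n_bg_ecs + 1)]
    for ri in range(n_bg_rxn):
        ec = bg_ecs[int(rng_react.integers(0, n_bg_ecs))]
        n_r = 1 + int(rng_react.random() < 0.4)
        n_p = 1 + int(rng_react.random() < 0.4)
        mets = rng_react.choice(bg_met_pool, size=n_r + n_p, replace=False)
        pathway = (ALLOWED_PATHWAYS[int(rng_react.integers(0, len(ALLOWED_PATHWAYS)))]
                   if rng_react.random() < 0.8
                   else OTHER_PATHWAYS[int(rng_react.integers(0, len(OTHER_PATHWAYS)))])
        reactions.append(ReactionRecord(
            ec=ec, reaction_id=f"R{ri + 1:05d}",
            reactants=tuple(str(m) for m in mets[:n_r]),
            products=tuple(str(m) for m in mets[n_r:]),
            pathway=pathway,
        ))

    rng_symb = np.random.default_rng(ss_symb)
    symb_genes = [f"LbG{i:04d}" for i in range(1, config.n_symbiont_genes + 1)]
    gene_lengths_symbiont = {
        g: int(l) for g, l in zip(symb_genes, rng_symb.integers(600, 3001, config.n_symbiont_genes))
    }
    ec_annotations: dict[str, set[str]] = {}
    symb_base = rng_symb.uniform(5.0, 8.0, size=config.n_symbiont_genes)
    symb_latent = np.tile(symb_base[:, None], (1, len(conditions)))
    gi = 0
    for li, (met, lab, sign) in enumerate(links):
        for ec in planted_ec_of_link[li]:
            # enzyme expression tracks the host cluster's profile; the link
            # sign is carried by the reaction direction (consume vs produce)
            for _ in range(2):
                g = symb_genes[gi]; gi += 1
                ec_annotations.setdefault(g, set()).add(ec)
                symb_latent[gi - 1] += profiles[lab]
    # background symbiont genes carry idiosyncratic per-condition biological
    # variation (not just replicate noise); without it, quantile
    # normalization would leave a shared rank-shift component as the only
    # condition-to-condition signal in every unplanted enzyme
    n_bg_genes = config.n_symbiont_genes - gi
    if n_bg_genes > 0 and config.symbiont_condition_sd > 0:
        symb_latent[gi:] += rng_symb.normal(
            0.0, config.symbiont_condition_sd, size=(n_bg_genes, len(conditions))
        )
    remaining = list(symb_genes[gi:])
    rng_symb.shuffle(remaining)
    ri = 0
    for ec in bg_ecs:
        take = 1 + int(rng_symb.random() < 0.5)
        for _ in range(take):
            if ri >= len(remaining):
                break
            ec_annotations.setdefault(remaining[ri], set()).add(ec)
            ri += 1
    symbiont_truth = pd.DataFrame(symb_latent, index=symb_genes, columns=conditions)
    symb_noise = rng_symb.normal(0.0, config.noise_sd,
                                 size=(config.n_symbiont_genes, len(sample_names)))
    symb_vals = np.empty_like(symb_noise)
    for j, s in enumerate(sample_names):
        symb_vals[:, j] = 2.0 ** (symb_latent[:, cond_idx[replicate_map[s]]] + symb_noise[:, j])
    expr_symbiont = pd.DataFrame(symb_vals, index=symb_genes, columns=sample_names)

    # ---- external expression compendium -----------------------------------
    rng_comp = np.random.default_rng(ss_comp)
    comp_cols = [f"comp_s{i:03d}" for i in range(1, config.compendium_samples + 1)]
    comp = rng_comp.normal(0.0, 1.0, size=(config.n_host_genes, config.compendium_samples))
    for cx in complexes_truth:
        factor = rng_comp.normal(0.0, 1.0, size=config.compendium_samples)
        for g in cx["roles"]:
            comp[gene_pos[g]] = 1.5 * factor + rng_comp.normal(
                0.0, config.compendium_noise_sd, size=config.compendium_samples
            )
    compendium = pd.DataFrame(comp, index=host_genes, columns=comp_cols)

    ground_truth = {
        "clusters": {
            lab: {
                "members": members[lab],
                "profile": [float(v) for v in profiles[lab]],
                "term": CLUSTER_TERMS[i % len(CLUSTER_TERMS)],
                **motif_truth.get(lab, {}),
            }
            for i, lab in enumerate(labels)
        },
        "complexes": complexes_truth,
        "metabolite_links": link_truth,
        "silent_genes": sorted(silent),
    }

    world = SyntheticWorld(
        config=config,
        replicate_map=replicate_map,
        symbiont_replicate_map=dict(replicate_map),
        upstream_sequences=upstream,
        gene_lengths_host=gene_lengths_host,
        gene_lengths_symbiont=gene_lengths_symbiont,
        expression_truth=expression_truth,
        expr_host=expr_host,
        flags_host=flags_host,
        symbiont_truth=symbiont_truth,
        expr_symbiont=expr_symbiont,
        compendium=compendium,
        annotations={g: frozenset(t) for g, t in annotations.items()},
        ec_annotations={g: frozenset(e) for g, e in ec_annotations.items()},
        loc_scores=loc_scores,
        reference_ppi=reference_ppi,
        reference_localizations=ref_loc,
        reaction_table=reactions,
        allowed_pathways=ALLOWED_PATHWAYS,
        ground_truth=ground_truth,
    )
    _check_world(world)
    return world


def _check_world(world: SyntheticWorld) -> None:
    L = world.config.upstream_length
    for g in world.expr_host.index:
        if len(world.upstream_sequences[g]) != L:
            raise AssertionError(f"upstream of {g} is not {L} bp")
    seen: set[str] = set()
    for info in world.ground_truth["clusters"].values():
        m = set(info["members"])
        if m & seen:
            raise AssertionError("planted clusters overlap")
        seen |= m
    for a, b in world.reference_ppi:
        if a == b:
            raise AssertionError("self edge in reference PPI")
    if len(set(world.reference_ppi)) != len(world.reference_ppi):
        raise AssertionError("duplicate reference PPI edge")


def generate_alignments(world: SyntheticWorld, sample: str, seed: int) -> AlignmentTable:
    """Simulate a read-to-gene alignment table for one sample.

    Reads are drawn multinomially with per-gene probability proportional
    to (linear) expression x gene length; a ``multimap_fraction`` of
    reads additionally lists one random second candidate gene, emulating
    an all-alignments aligner run on a gene family.
    """
    if sample not in world.expr_host.columns:
        raise KeyError(f"unknown sample {sample!r}")
    cfg = world.config
    genes = world.host_genes
    records: dict[str, tuple[str, ...]] = {}
    if cfg.reads_per_sample == 0:
        return AlignmentTable(records)
    rng = np.random.default_rng(seed)
    lengths = np.array([world.gene_lengths_host[g] for g in genes], dtype=float)
    weights = world.expr_host[sample].to_numpy(dtype=float) * lengths
    probs = weights / weights.sum()
    counts = rng.multinomial(cfg.reads_per_sample, probs)
    ridx = 0
    n = len(genes)
    for gi, c in enumerate(counts):
        for _ in range(c):
            ridx += 1
            read = f"{sample}_r{ridx:06d}"
            if cfg.multimap_fraction > 0 and rng.random() < cfg.multimap_fraction:
                other = int(rng.integers(0, n - 1))
                if other >= gi:
                    other += 1
                records[read] = (genes[gi], genes[other])
            else:
                records[read] = (genes[gi],)
    return AlignmentTable(records)


# ---------------------------------------------------------------------------
# export / import

def export_world(world: SyntheticWorld, directory) -> None:
    """Write every pipeline input as plain text; round-trips via load_world.

    Alignment tables are generated on demand (one per sample, seeds
    derived from the world seed) when ``reads_per_sample > 0``, and
    memoized on the world so that the exported and in-memory objects
    agree.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(world.upstream_sequences, d / "upstream.fasta")
    mio.write_matrix(world.expr_host, d / "expr_host.tsv")
    mio.write_flags(world.flags_host, d / "flags_host.tsv")
    mio.write_matrix(world.expression_truth, d / "latent_host.tsv")
    mio.write_matrix(world.expr_symbiont, d / "expr_symbiont.tsv")
    mio.write_matrix(world.symbiont_truth, d / "latent_symbiont.tsv")
    mio.write_matrix(world.compendium, d / "compendium.tsv")
    lengths = pd.DataFrame(
        [(g, l, "host") for g, l in world.gene_lengths_host.items()]
        + [(g, l, "symbiont") for g, l in world.gene_lengths_symbiont.items()],
        columns=["gene", "length", "organism"],
    )
    lengths.to_csv(d / "gene_lengths.tsv", sep="\t", index=False)
    samp = pd.DataFrame(
        [(s, c) for s, c in world.replicate_map.items()], columns=["sample", "condition"]
    )
    samp.to_csv(d / "samples.tsv", sep="\t", index=False)
    mio.write_motifs(world.config.motif_library, d / "motifs.tsv")
    mio.write_term_table(world.annotations, d / "annotations.tsv")
    mio.write_term_table(world.ec_annotations, d / "ec_annotations.tsv", value_label="ec")
    mio.write_scores_table(world.loc_scores, d / "localization.tsv")
    mio.write_edge_list(world.reference_ppi, d / "reference_ppi.tsv")
    mio.write_term_table(world.reference_localizations, d / "reference_localization.tsv",
                         key_label="protein", value_label="label")
    mio.write_reactions(world.reaction_table, d / "reactions.tsv")
    with open(d / "pathways.txt", "w") as fh:
        for p in world.allowed_pathways:
            fh.write(p + "\n")
    mio.write_json(world.config.to_dict(), d / "config.json")
    mio.write_json(world.ground_truth, d / "truth.json")
    if world.config.reads_per_sample > 0:
        (d / "alignments").mkdir(exist_ok=True)
        base = np.random.SeedSequence(world.config.seed).spawn(10)[-1]
        child_seeds = base.generate_state(len(world.expr_host.columns)) % (2**31)
        for s, cs in zip(world.expr_host.columns, child_seeds):
            if s not in world.alignments:
                world.alignments[s] = generate_alignments(world, s, int(cs))
            mio.write_alignments_tsv(world.alignments[s], d / "alignments" / f"{s}.tsv")


def load_world(directory) -> SyntheticWorld:
    """Read a world exported by :func:`export_world`."""
    d = Path(directory)
    config = WorldConfig.from_dict(mio.read_json(d / "config.json"))
    samp = pd.read_csv(d / "samples.tsv", sep="\t", dtype=str)
    replicate_map = dict(zip(samp["sample"], samp["condition"]))
    lengths = pd.read_csv(d / "gene_lengths.tsv", sep="\t")
    gl_host = {r["gene"]: int(r["length"]) for _, r in lengths.iterrows() if r["organism"] == "host"}
    gl_symb = {r["gene"]: int(r["length"]) for _, r in lengths.iterrows() if r["organism"] == "symbiont"}
    alignments = {}
    adir = d / "alignments"
    if adir.is_dir():
        for f in sorted(adir.glob("*.tsv")):
            alignments[f.stem] = mio.read_alignments_tsv(f)
    with open(d / "pathways.txt") as fh:
        pathways = tuple(line.strip() for line in fh if line.strip())
    return SyntheticWorld(
        config=config,
        replicate_map=replicate_map,
        symbiont_replicate_map=dict(replicate_map),
        upstream_sequences=mio.read_fasta(d / "upstream.fasta"),
        gene_lengths_host=gl_host,
        gene_lengths_symbiont=gl_symb,
        expression_truth=mio.read_matrix(d / "latent_host.tsv"),
        expr_host=mio.read_matrix(d / "expr_host.tsv"),
        flags_host=mio.read_flags(d / "flags_host.tsv"),
        symbiont_truth=mio.read_matrix(d / "latent_symbiont.tsv"),
        expr_symbiont=mio.read_matrix(d / "expr_symbiont.tsv"),
        compendium=mio.read_matrix(d / "compendium.tsv"),
        annotations=mio.read_term_table(d / "annotations.tsv"),
        ec_annotations=mio.read_term_table(d / "ec_annotations.tsv"),
        loc_scores=mio.read_scores_table(d / "localization.tsv"),
        reference_ppi=mio.read_edge_list(d / "reference_ppi.tsv"),
        reference_localizations=mio.read_term_table(d / "reference_localization.tsv"),
        reaction_table=mio.read_reactions(d / "reactions.tsv"),
        allowed_pathways=pathways,
        ground_truth=mio.read_json(d / "truth.json"),
        alignments=alignments,
    )


def worlds_equal(a: SyntheticWorld, b: SyntheticWorld) -> bool:
    """Structural equality of two worlds (used for round-trip checks)."""
    if a.config != b.config:
        return False
    for attr in ("expr_host", "flags_host", "expression_truth", "expr_symbiont",
                 "symbiont_truth", "compendium"):
        da, db = getattr(a, attr), getattr(b, attr)
        if not (da.index.equals(db.index) and list(da.columns) == list(db.columns)
                and np.array_equal(da.to_numpy(), db.to_numpy())):
            return False
    if (a.upstream_sequences != b.upstream_sequences
            or a.gene_lengths_host != b.gene_lengths_host
            or a.gene_lengths_symbiont != b.gene_lengths_symbiont
            or a.replicate_map != b.replicate_map
            or dict(a.annotations) != dict(b.annotations)
            or dict(a.ec_annotations) != dict(b.ec_annotations)
            or a.loc_scores != b.loc_scores
            or list(a.reference_ppi) != list(b.reference_ppi)
            or dict(a.reference_localizations) != dict(b.reference_localizations)
            or list(a.reaction_table) != list(b.reaction_table)
            or tuple(a.allowed_pathways) != tuple(b.allowed_pathways)
            or a.ground_truth != b.ground_truth):
        return False
    if set(a.alignments) != set(b.alignments):
        return False
    for s in a.alignments:
        if a.alignments[s].records != b.alignments[s].records:
            return False
    return True
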