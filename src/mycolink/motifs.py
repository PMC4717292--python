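"""IUPAC motif scanning of upstream regions and cluster enrichment.

Transcription-factor binding sites are represented as IUPAC degenerate
strings (PLACE-style).  Scanning is presence/absence only: a gene either
carries at least one upstream instance of a motif or it does not; match
multiplicity is deliberately ignored.  Enrichment of a motif in a
co-regulated gene cluster uses the upper-tail cumulative binomial with
the carrier frequency over the differentially regulated background set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .stats import binomial_enrichment_pvalue

__all__ = [
    "IUPAC_CODES",
    "MotifPattern",
    "MotifAssociation",
    "MotifEnrichment",
    "scan_upstream",
    "build_associations",
    "enrich_motifs",
    "motifs_for_complex_tfs",
    "reverse_complement",
]

#: IUPAC nucleotide codes -> the set of concrete bases each symbol accepts.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC pattern string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named transcription-factor binding motif as an IUPAC string."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r} has an empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"motif {self.name!r} contains non-IUPAC symbols {sorted(bad)}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def regex(self) -> re.Pattern[str]:
        # An N in the *sequence* is an unknown base: it must not satisfy any
        # determinate motif symbol, only the fully degenerate N.
        parts = []
        for sym in self.pattern:
            bases = IUPAC_CODES[sym]
            parts.append(f"[{bases}N]" if sym == "N" else f"[{bases}]")
        return re.compile("".join(parts))

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass
class MotifAssociation:
    """Genes carrying >=1 upstream instance of a motif, plus its background rate."""

    motif: str
    carriers: frozenset[str]
    background_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_frequency <= 1.0:
            raise ValueError("background frequency outside [0, 1]")


@dataclass
class MotifEnrichment:
    """Binomial enrichment of one motif in one gene cluster."""

    cluster: str
    motif: str
    n: int
    x: int
    f: float
    p: float
    passes: bool


def scan_upstream(sequence: str, motif: MotifPattern) -> bool:
    """True iff the motif matches at >=1 position of the upstream sequence.

    The scan is exhaustive over positions on the given (forward) strand;
    callers wanting both strands scan the reverse complement as well.
    A motif longer than the sequence cannot match.
    """
    seq = sequence.upper()
    if len(motif) > len(seq):
        return False
    return motif.regex().search(seq) is not None


def build_associations(
    upstreams: Mapping[str, str],
    library: Sequence[MotifPattern],
    background: Iterable[str],
    both_strands: bool = False,
) -> list[MotifAssociation]:
    """Scan every upstream region for every library motif.

    ``background`` is the gene set over which the carrier frequency f_M is
    computed -- by construction the differentially regulated gene set, not
    the whole genome.  All background genes must have an upstream sequence.
    """
    background = sorted(set(background))
    if not background:
        raise ValueError("empty background gene set")
    missing = [g for g in background if g not in upstreams]
    if missing:
        raise KeyError(f"background genes without upstream sequence: {missing[:5]}")

    out = []
    for motif in library:
        rx = motif.regex()
        rx_rc = MotifPattern(motif.name, reverse_complement(motif.pattern)).regex() if both_strands else None
        carriers = set()
        for gene, seq in upstreams.items():
            s = seq.upper()
            if len(motif) > len(s):
                continue
            if rx.search(s) is not None or (rx_rc is not None and rx_rc.search(s) is not None):
                carriers.add(gene)
        f = sum(1 for g in background if g in carriers) / len(background)
        out.append(MotifAssociation(motif.name, frozenset(carriers), f))
    return out


def enrich_motifs(
    cluster_id: str,
    members: Iterable[str],
    associations: Sequence[MotifAssociation],
    alpha: float = 0.01,
    min_genes: int = 10,
) -> list[MotifEnrichment]:
    """Upper-tail binomial enrichment of each motif in one cluster.

    A motif passes when p < ``alpha`` AND at least ``min_genes`` cluster
    members carry it; the carrier floor guards against motifs that merely
    co-occur with a shared biological function rather than co-regulation.
    """
    members = sorted(set(members))
    n = len(members)
    out = []
    for assoc in associations:
        x = sum(1 for g in members if g in assoc.carriers)
        if x > 0 and assoc.background_frequency == 0:
            raise AssertionError(
                f"motif {assoc.motif}: cluster carrier with zero background frequency"
            )
        p = binomial_enrichment_pvalue(x, n, assoc.background_frequency)
        out.append(
            MotifEnrichment(
                cluster=cluster_id, motif=assoc.motif, n=n, x=x,
                f=assoc.background_frequency, p=p,
                passes=(p < alpha and x >= min_genes),
            )
        )
    return out


def motifs_for_complex_tfs(
    complexes,
    tf_motif_map: Mapping[str, MotifPattern],
    clusters,
    carriers: Mapping[str, frozenset[str]],
) -> list[tuple[str, str, str, int]]:
    """Count cluster genes carrying the binding motif of a complex TF.

    For every transcription factor in a predicted sensor complex whose TF
    class maps to a known binding motif, and every gene cluster sharing at
    least one gene with that complex, report how many cluster genes carry
    the motif upstream.  TF classes without a known motif (e.g. IAA-AUX,
    ERF) contribute no rows, as do complexes without transcription factors.

    Parameters
    ----------
    complexes : iterable of :class:`~mycolink.ppi.SensorComplex`
    tf_motif_map : TF-class annotation term -> MotifPattern
    clusters : iterable of :class:`~mycolink.cluster.GeneCluster`
    carriers : motif name -> set of genes with >=1 upstream instance
        (from :func:`build_associations`).

    Returns
    -------
    rows of ``(complex_id, cluster_id, motif_name, carrier_count)``.
    """
    rows = []
    for cx in complexes:
        tf_terms = set()
        for gene, role in cx.nodes.items():
            if role == "transcription_factor":
                tf_terms |= set(cx.annotations.get(gene, ()))
        motifs = sorted(
            {tf_motif_map[t].name for t in tf_terms if t in tf_motif_map}
        )
        if not motifs:
            continue
        for cl in clusters:
            if not (set(cl.members) & set(cx.nodes)):
                continue
            for mname in motifs:
                count = sum(1 for g in cl.members if g in carriers.get(mname, frozenset()))
                rows.append((cx.id, cl.id, mname, count))
    return rows
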