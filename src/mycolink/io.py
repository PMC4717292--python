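"""Readers and writers for the pipeline's plain-text exchange formats.

Everything is tab-separated text, FASTA, or JSON so that worlds and
intermediate results diff cleanly and round-trip losslessly: floats are
written with pandas' shortest-repr formatting, and every writer emits a
deterministic row order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifPattern
from .quant import AlignmentTable
from .turnover import ReactionRecord

__all__ = [
    "write_matrix", "read_matrix", "write_flags", "read_flags",
    "write_fasta", "read_fasta",
    "write_motifs", "read_motifs",
    "write_term_table", "read_term_table",
    "write_scores_table", "read_scores_table",
    "write_edge_list", "read_edge_list",
    "write_reactions", "read_reactions",
    "write_alignments_tsv", "read_alignments_tsv",
    "write_alignments_sam", "read_alignments_sam",
    "write_json", "read_json",
]


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    # round_trip parsing: the default float reader can be 1 ulp off,
    # which would break lossless export/import cycles
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_flags(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_motifs(library: Iterable[MotifPattern | tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tpattern\n")
        for m in library:
            name, pattern = (m.name, m.pattern) if isinstance(m, MotifPattern) else m
            fh.write(f"{name}\t{pattern}\n")


def read_motifs(path) -> list[MotifPattern]:
    df = pd.read_csv(path, sep="\t")
    return [MotifPattern(r["name"], r["pattern"]) for _, r in df.iterrows()]


def write_term_table(annotations: Mapping[str, Iterable[str]], path,
                     key_label: str = "gene", value_label: str = "term") -> None:
    """Two-column long table: one (gene, term) row per annotation."""
    with open(path, "w") as fh:
        fh.write(f"{key_label}\t{value_label}\n")
        for key in sorted(annotations):
            for value in sorted(annotations[key]):
                fh.write(f"{key}\t{value}\n")


def read_term_table(path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for key, value in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(key, set()).add(value)
    return {k: frozenset(v) for k, v in out.items()}


def write_scores_table(scores: Mapping[str, Mapping[str, float]], path) -> None:
    """Localization score table: protein, label, score (WoLF-PSORT style)."""
    with open(path, "w") as fh:
        fh.write("protein\tlabel\tscore\n")
        for protein in sorted(scores):
            for label in sorted(scores[protein]):
                fh.write(f"{protein}\t{label}\t{scores[protein][label]}\n")


def read_scores_table(path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "label": str})
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["protein"], {})[row["label"]] = float(row["score"])
    return out


def write_edge_list(edges: Iterable[tuple[str, str]], path,
                    header: tuple[str, str] = ("protein_a", "protein_b")) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_reactions(records: Iterable[ReactionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("ec\treaction_id\treactants\tproducts\tpathway\n")
        for r in records:
            fh.write(
                f"{r.ec}\t{r.reaction_id}\t{';'.join(r.reactants)}\t"
                f"{';'.join(r.products)}\t{r.pathway}\n"
            )


def read_reactions(path) -> list[ReactionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ReactionRecord(
            ec=row["ec"], reaction_id=row["reaction_id"],
            reactants=tuple(row["reactants"].split(";")),
            products=tuple(row["products"].split(";")),
            pathway=row["pathway"],
        )
        for _, row in df.iterrows()
    ]


def write_alignments_tsv(table: AlignmentTable, path) -> None:
    """One row per (read, candidate gene); reads with several rows are multi-mapped."""
    with open(path, "w") as fh:
        fh.write("read\tgene\n")
        for read in table.records:
            for gene in table.records[read]:
                fh.write(f"{read}\t{gene}\n")


def read_alignments_tsv(path) -> AlignmentTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: dict[str, list[str]] = {}
    for read, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        records.setdefault(read, []).append(gene)
    return AlignmentTable({r: tuple(g) for r, g in records.items()})


def write_alignments_sam(table: AlignmentTable, gene_lengths: Mapping[str, int], path) -> None:
    """Minimal SAM: @SQ headers plus one unpaired record per candidate.

    Only QNAME and RNAME carry information (multi-mapped reads repeat the
    QNAME with flag 256 on secondary records); placement fields are
    dummies, matching the convention that the aligner's candidate list --
    not the placement -- is the unit of information.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for gene in sorted(gene_lengths):
            fh.write(f"@SQ\tSN:{gene}\tLN:{gene_lengths[gene]}\n")
        for read in table.records:
            for i, gene in enumerate(table.records[read]):
                flag = 0 if i == 0 else 256
                fh.write(f"{read}\t{flag}\t{gene}\t1\t0\t*\t*\t0\t0\t*\t*\n")


def read_alignments_sam(path) -> AlignmentTable:
    """Read the QNAME -> RNAME pairs of a SAM file; everything else is ignored."""
    records: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            qname, rname = fields[0], fields[2]
            if rname == "*":
                continue
            cands = records.setdefault(qname, [])
            if rname not in cands:
                cands.append(rname)
    return AlignmentTable({r: tuple(g) for r, g in records.items()})


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
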