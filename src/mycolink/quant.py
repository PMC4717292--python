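"""Bootstrap quantification of gene expression from read alignments.

Short reads aligned with an "all alignments" policy produce, per read, a
*set* of candidate gene models rather than a single placement.  The
bootstrap ("BowStrap"-style) resamples the aligned reads with
replacement; within each iteration every resampled multi-mapped read is
assigned to exactly one of its candidates uniformly at random.  Means
and standard deviations of RPKM over iterations quantify both counting
and mapping uncertainty, and a normal tail probability at zero provides
the significance-of-expression call.

RPKM here uses the number of aligned reads in the sample as its
denominator (library size is not recoverable from an alignment table).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .stats import normal_tail_at_zero

__all__ = [
    "AlignmentTable",
    "ExpressionEstimate",
    "ExpressionMatrix",
    "bowstrap_quantify",
    "bootstrap_counts",
    "quantile_normalize",
    "log2_transform",
    "average_replicates",
]


@dataclass
class AlignmentTable:
    """Read id -> duplicate-free tuple of candidate gene ids."""

    records: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for read, cands in self.records.items():
            if len(cands) == 0:
                raise ValueError(f"read {read!r} has no candidate gene")
            if len(set(cands)) != len(cands):
                raise ValueError(f"read {read!r} has duplicate candidates")

    @property
    def n_reads(self) -> int:
        return len(self.records)


@dataclass
class ExpressionEstimate:
    gene: str
    mean_rpkm: float
    sd_rpkm: float
    p_expressed: float
    significant: bool


@dataclass
class ExpressionMatrix:
    """A gene x sample expression table with optional per-cell significance flags."""

    values: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        if self.flags is not None and not self.flags.index.equals(self.values.index):
            raise ValueError("flags not aligned with values")


def _alignment_classes(alignments: AlignmentTable, gene_index: Mapping[str, int]):
    """Collapse reads into equivalence classes by candidate set.

    Resampling n reads uniformly with replacement is distributionally
    identical to drawing class counts from Multinomial(n, class sizes / n),
    which lets the whole bootstrap run as a handful of vectorised draws.
    """
    counter: Counter[tuple[int, ...]] = Counter()
    for read, cands in alignments.records.items():
        try:
            key = tuple(sorted(gene_index[g] for g in cands))
        except KeyError as exc:
            raise KeyError(f"read {read!r} aligned to unknown gene {exc}") from None
        counter[key] += 1
    classes = sorted(counter)
    sizes = np.array([counter[c] for c in classes], dtype=float)
    return classes, sizes


def bootstrap_counts(
    alignments: AlignmentTable,
    genes: list[str],
    iterations: int,
    seed: int,
    fractional: bool = False,
    batch_size: int = 2000,
) -> Iterator[np.ndarray]:
    """Yield batches of per-iteration gene count matrices (batch x genes).

    Each row is one bootstrap iteration: ``n_reads`` reads resampled with
    replacement, every multi-mapped read copy assigned uniformly at random
    to a single candidate (or split 1/k fractionally when ``fractional``).
    Row sums equal ``n_reads`` exactly -- reads are conserved.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    gene_index = {g: i for i, g in enumerate(genes)}
    classes, sizes = _alignment_classes(alignments, gene_index)
    n_reads = alignments.n_reads
    pvals = sizes / n_reads
    rng = np.random.default_rng(seed)
    done = 0
    while done < iterations:
        b = min(batch_size, iterations - done)
        m = rng.multinomial(n_reads, pvals, size=b)  # (b, n_classes)
        counts = np.zeros((b, len(genes)))
        for ci, cand in enumerate(classes):
            k = len(cand)
            if k == 1:
                counts[:, cand[0]] += m[:, ci]
            elif fractional:
                for g in cand:
                    counts[:, g] += m[:, ci] / k
            else:
                remaining = m[:, ci].copy()
                for j, g in enumerate(cand[:-1]):
                    draw = rng.binomial(remaining, 1.0 / (k - j))
                    counts[:, g] += draw
                    remaining -= draw
                counts[:, cand[-1]] += remaining
        done += b
        yield counts


def bowstrap_quantify(
    alignments: AlignmentTable,
    gene_lengths: Mapping[str, int],
    iterations: int = 10_000,
    seed: int = 0,
    alpha: float = 1e-4,
    fractional: bool = False,
) -> list[ExpressionEstimate]:
    """Bootstrap RPKM mean, SD and significance for every gene.

    Per iteration and gene, RPKM = 1e9 * count / (n_reads * length).
    ``p_expressed`` is the lower tail at zero of Normal(mean, SD); a gene
    is called significantly expressed when ``p_expressed < alpha``
    (default 1e-4, uncorrected).  An empty alignment table yields zero
    means and non-significant calls for every gene.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    genes = sorted(gene_lengths)
    lengths = np.array([gene_lengths[g] for g in genes], dtype=float)
    if (lengths <= 0).any():
        bad = [g for g, l in zip(genes, lengths) if l <= 0]
        raise ValueError(f"non-positive gene lengths: {bad[:5]}")

    if alignments.n_reads == 0:
        return [ExpressionEstimate(g, 0.0, 0.0, 1.0, False) for g in genes]

    n_reads = alignments.n_reads
    scale = 1e9 / (n_reads * lengths)
    total = np.zeros(len(genes))
    total_sq = np.zeros(len(genes))
    for counts in bootstrap_counts(alignments, genes, iterations, seed, fractional):
        rpkm = counts * scale
        total += rpkm.sum(axis=0)
        total_sq += (rpkm * rpkm).sum(axis=0)
    mean = total / iterations
    if iterations > 1:
        var = np.maximum(total_sq - iterations * mean * mean, 0.0) / (iterations - 1)
    else:
        var = np.zeros_like(mean)
    sd = np.sqrt(var)

    out = []
    for g, mu, s in zip(genes, mean, sd):
        p = normal_tail_at_zero(float(mu), float(s))
        out.append(ExpressionEstimate(g, float(mu), float(s), p, p < alpha))
    return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean distribution of order statistics.

    Each column's values are replaced by the cross-sample mean of the
    order statistics at their rank; ties receive the average of the target
    values over the tied ranks, so a constant column still normalizes.
    Within-sample ranks are preserved.
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    arr = values.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    ranks = values.rank(method="average").to_numpy()  # 1-based, fractional at ties
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(ranks[:, j] - 1.0, np.arange(n), target)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_transform(values: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Elementwise ``log2(max(value, floor))`` for a non-negative matrix."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if (values.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(values.clip(lower=floor))


def average_replicates(
    values: pd.DataFrame,
    replicate_map: Mapping[str, str],
    conditions: list[str],
) -> pd.DataFrame:
    """Average replicate sample columns per condition (on the given scale).

    Every column of ``values`` must be mapped to a condition; every
    condition must own at least one sample.
    """
    unmapped = [s for s in values.columns if s not in replicate_map]
    if unmapped:
        raise KeyError(f"samples without condition: {unmapped}")
    cols = {}
    for cond in conditions:
        samples = [s for s in values.columns if replicate_map[s] == cond]
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        cols[cond] = values[samples].mean(axis=1)
    return pd.DataFrame(cols, index=values.index)
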