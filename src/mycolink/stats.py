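"""Shared statistical kernels used across the pipeline.

Two small primitives recur in every stage: the upper-tail cumulative
binomial used for annotation and motif enrichment, and the two-sided
t-test on a Pearson correlation coefficient used to score co-expression
edges.  They live here so that every caller provably uses the same
numerics.
"""

from __future__ import annotations

import math

from scipy import special, stats as _stats

__all__ = ["binomial_enrichment_pvalue", "pearson_pvalue", "normal_tail_at_zero"]


def binomial_enrichment_pvalue(x: int, n: int, f: float) -> float:
    """Upper-tail cumulative binomial probability P(X >= x), X ~ Binomial(n, f).

    This is the enrichment statistic for observing ``x`` carriers of an
    annotation (or upstream motif) in a set of ``n`` genes when the
    background carrier frequency is ``f``.

    Parameters
    ----------
    x : observed carrier count, ``0 <= x <= n``.
    n : set size.
    f : background carrier frequency in ``[0, 1]``.
    """
    if n < 0:
        raise ValueError(f"set size must be non-negative, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"carrier count {x} outside [0, {n}]")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"background frequency {f} outside [0, 1]")
    if x == 0:
        return 1.0
    return float(_stats.binom.sf(x - 1, n, f))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided significance of a Pearson correlation over ``n`` samples.

    Uses the exact t transform ``t = r * sqrt((n - 2) / (1 - r^2))`` with
    ``n - 2`` degrees of freedom.  ``|r| == 1`` returns 0.
    """
    if n < 3:
        raise ValueError("correlation significance needs at least 3 samples")
    r = max(-1.0, min(1.0, float(r)))
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _stats.t.sf(abs(t), n - 2))


def normal_tail_at_zero(mean: float, sd: float) -> float:
    """Probability mass at or below zero of Normal(mean, sd).

    This is the significance call for a bootstrap expression estimate: the
    chance that the underlying expression is indistinguishable from zero.
    With ``sd == 0`` the distribution is degenerate: 0 if the mean is
    positive, 1 otherwise.
    """
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    if sd == 0:
        return 0.0 if mean > 0 else 1.0
    return float(special.ndtr(-mean / sd))
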