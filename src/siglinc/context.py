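"""Relating ranked link coefficients to per-edge annotations.

Links are ranked by a coefficient (rank 0% = highest value) and related
to edge-level annotations in three ways: cumulative annotation
proportions over the top-x% links, per-bin medians of a quantitative
attribute, and Fisher's exact test for enrichment of an annotation in
the top fraction.  All three are rank-based, hence invariant under any
strictly monotone transform of the coefficient; ties are broken by the
canonical edge key, stable and deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Edge = tuple[str, str]

__all__ = [
    "ranked_cumulative_proportion",
    "ranked_bin_median",
    "enrichment_in_top_fraction",
    "FisherEnrichment",
]


def _ranked_edges(coeff: Mapping[Edge, float],
                  keys: Sequence[Edge]) -> list[Edge]:
    return sorted(keys, key=lambda e: (-coeff[e], e))


def ranked_cumulative_proportion(
        coeff: Mapping[Edge, float],
        annotation: Mapping[Edge, bool],
        grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Annotation proportion among the top-x% highest-coefficient links.

    ``grid`` lists percentages (default 1..100 in 1% steps).  At each x
    the top ``ceil(x * n / 100)`` links (at least one) are taken; at 100%
    the proportion equals the overall annotation base rate exactly.
    Returns columns ``percent, n_top, proportion``.
    """
    keys = [e for e in annotation if e in coeff]
    if not keys:
        raise ValueError("no annotated edges with coefficients")
    if grid is None:
        grid = list(range(1, 101))
    grid = list(grid)
    if not grid:
        raise ValueError("grid must not be empty")
    ranked = _ranked_edges(coeff, keys)
    flags = np.array([bool(annotation[e]) for e in ranked])
    cum = np.cumsum(flags)
    n = len(ranked)
    rows = []
    for x in grid:
        k = min(n, max(1, math.ceil(x * n / 100.0)))
        rows.append((float(x), k, cum[k - 1] / k))
    return pd.DataFrame(rows, columns=["percent", "n_top", "proportion"])


def ranked_bin_median(coeff: Mapping[Edge, float],
                      attribute: Mapping[Edge, float],
                      n_bins: int = 10) -> pd.DataFrame:
    """Median attribute per equal-count bin of coefficient-ranked links.

    Bin 0 holds the highest-coefficient links (rank 0%).  Returns columns
    ``bin, rank_lo_pct, rank_hi_pct, n_edges, median``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    keys = [e for e in attribute if e in coeff]
    if not keys:
        raise ValueError("no attributed edges with coefficients")
    ranked = _ranked_edges(coeff, keys)
    values = np.array([float(attribute[e]) for e in ranked])
    n = len(ranked)
    rows = []
    offset = 0
    for b, chunk in enumerate(np.array_split(values, min(n_bins, n))):
        rows.append((b, 100.0 * offset / n,
                     100.0 * (offset + len(chunk)) / n,
                     len(chunk), float(np.median(chunk))))
        offset += len(chunk)
    return pd.DataFrame(rows, columns=[
        "bin", "rank_lo_pct", "rank_hi_pct", "n_edges", "median"])


@dataclass
class FisherEnrichment:
    """Fisher's exact test of annotation enrichment in the top fraction.

    ``table`` is [[top & annotated, top & not], [rest & annotated,
    rest & not]].  ``odds_ratio`` uses the Haldane 0.5 correction when a
    cell is zero.  ``degenerate`` flags tables where the annotation does
    not vary (all or none annotated), for which every p is 1.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float
    p_greater: float
    p_less: float
    degenerate: bool = False


def enrichment_in_top_fraction(coeff: Mapping[Edge, float],
                               annotation: Mapping[Edge, bool],
                               top_fraction: float) -> FisherEnrichment:
    """Test whether an annotation is enriched among top-ranked links."""
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must be in (0, 1)")
    keys = [e for e in annotation if e in coeff]
    if not keys:
        raise ValueError("no annotated edges with coefficients")
    ranked = _ranked_edges(coeff, keys)
    flags = np.array([bool(annotation[e]) for e in ranked])
    n = len(ranked)
    k = min(n, max(1, math.ceil(top_fraction * n)))
    a = int(flags[:k].sum())
    b = k - a
    c = int(flags[k:].sum())
    d = (n - k) - c
    table = ((a, b), (c, d))
    if flags.all() or not flags.any():
        return FisherEnrichment(table, math.nan, 1.0, 1.0, 1.0,
                                degenerate=True)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    arr = np.array(table)
    _, p_two = stats.fisher_exact(arr, alternative="two-sided")
    _, p_greater = stats.fisher_exact(arr, alternative="greater")
    _, p_less = stats.fisher_exact(arr, alternative="less")
    return FisherEnrichment(table, float(odds), float(p_two),
                            float(p_greater), float(p_less))
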