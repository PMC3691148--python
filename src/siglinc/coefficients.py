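"""Signed link-clustering coefficients and common-neighbor profiles.

For an edge e = (i, j), the link-clustering coefficient LC measures the
proportion of shared neighbors (common linking partners) of i and j among
their *excess* neighbors — neighbors excluding each other.  Each common
neighbor k is classified by the signs of the paired links (i,k) and (j,k):

* ``(+,+)`` pairs count toward PLC (positive same-sign),
* ``(-,-)`` pairs toward NLC (negative same-sign),
* mixed pairs toward HLC (hybrid).

SLC = PLC + NLC aggregates the same-sign contributions and LC = SLC + HLC
the total.  Under the default ``min_total`` denominator convention every
count is divided by d = min(n(i), n(j)), the smaller excess-neighbor
count, so the decomposition identities hold exactly per edge; edges with
d = 0 (pendant edges) get all coefficients 0.

An alternative ``min_signed`` convention normalizes each subtype by the
matching sign-specific excess counts (PLC by min(n+(i), n+(j)), NLC by
min(n-(i), n-(j)), HLC by min(n+(i), n-(j)) + min(n-(i), n+(j))); it is
provided for sensitivity analysis and does not preserve the decomposition
identities.

The common-neighbor (CNB) profile looks at each negative edge through the
hybrid link pairs that generate its HLC: for every hybrid common neighbor
k the pair {(i,k), (j,k)} contributes the PLC of its positive member and
the HLC of its negative member.  Per-edge medians of those values,
correlated against the edge's own HLC across all negative edges, quantify
how bridge-like negative links attach to positive clusters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd
from scipy import stats

from .network import SignedNetwork, canonical_edge

__all__ = [
    "common_neighbor_partition",
    "link_clustering_coefficients",
    "cnb_profile",
    "CnbProfile",
    "COEFFICIENT_COLUMNS",
]

COEFFICIENT_COLUMNS = [
    "source", "target", "sign", "lc", "slc", "hlc", "plc", "nlc",
    "c_pp", "c_nn", "c_hy", "n_i", "n_j",
    "n_pos_i", "n_neg_i", "n_pos_j", "n_neg_j",
]


def common_neighbor_partition(net: SignedNetwork, u: str,
                              v: str) -> tuple[int, int, int]:
    """Partition the common excess neighbors of edge (u, v) by sign pair.

    Returns ``(c_pp, c_nn, c_hy)``: counts of common neighbors k reached
    by two positive links, two negative links, or one of each.
    """
    if not net.has_edge(u, v):
        raise KeyError(f"no edge {u!r} -- {v!r}")
    adj = net.adjacency()
    return _partition(adj, u, v)


def _partition(adj: dict[str, dict[str, int]], u: str,
               v: str) -> tuple[int, int, int]:
    nu, nv = adj[u], adj[v]
    if len(nv) < len(nu):
        nu, nv = nv, nu
        u, v = v, u
    c_pp = c_nn = c_hy = 0
    for k, s_uk in nu.items():
        if k == v:
            continue
        s_vk = nv.get(k)
        if s_vk is None or k == u:
            continue
        if s_uk > 0 and s_vk > 0:
            c_pp += 1
        elif s_uk < 0 and s_vk < 0:
            c_nn += 1
        else:
            c_hy += 1
    return c_pp, c_nn, c_hy


def link_clustering_coefficients(
        net: SignedNetwork,
        denominator: str = "min_total") -> pd.DataFrame:
    """Per-edge signed link-clustering coefficient table.

    One row per edge (both signs) with columns
    ``source target sign lc slc hlc plc nlc c_pp c_nn c_hy n_i n_j
    n_pos_i n_neg_i n_pos_j n_neg_j``; rows are in canonical edge order.
    """
    if denominator not in ("min_total", "min_signed"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    adj = net.adjacency()
    rows = []
    for u, v, sign in net.edges():
        c_pp, c_nn, c_hy = _partition(adj, u, v)
        nu = {k: s for k, s in adj[u].items() if k != v}
        nv = {k: s for k, s in adj[v].items() if k != u}
        n_i, n_j = len(nu), len(nv)
        np_i = sum(1 for s in nu.values() if s > 0)
        np_j = sum(1 for s in nv.values() if s > 0)
        nn_i, nn_j = n_i - np_i, n_j - np_j
        d = min(n_i, n_j)
        if denominator == "min_total":
            lc = _ratio(c_pp + c_nn + c_hy, d)
            plc = _ratio(c_pp, d)
            nlc = _ratio(c_nn, d)
            hlc = _ratio(c_hy, d)
            slc = _ratio(c_pp + c_nn, d)
        else:
            plc = _ratio(c_pp, min(np_i, np_j))
            nlc = _ratio(c_nn, min(nn_i, nn_j))
            hlc = _ratio(c_hy, min(np_i, nn_j) + min(nn_i, np_j))
            slc = plc + nlc
            lc = _ratio(c_pp + c_nn + c_hy, d)
        rows.append((u, v, sign, lc, slc, hlc, plc, nlc,
                     c_pp, c_nn, c_hy, n_i, n_j, np_i, nn_i, np_j, nn_j))
    return pd.DataFrame(rows, columns=COEFFICIENT_COLUMNS)


def _ratio(num: int, den: int) -> float:
    # 0/0 is defined as 0: a pendant edge has no room for shared neighbors
    return num / den if den > 0 else 0.0


@dataclass
class CnbProfile:
    """Common-neighbor profile of the negative edges of a network.

    ``table`` has one row per negative edge with at least one hybrid
    common neighbor: the edge's own HLC, the number of hybrid neighbors,
    and the medians of the positive members' PLC and negative members'
    HLC over the hybrid link pairs.  The two Pearson correlations relate
    those medians to the edge's HLC across all profiled edges; they are
    NaN when fewer than 3 rows exist or a variable is constant.
    """

    table: pd.DataFrame
    plc_correlation: float
    plc_pvalue: float
    hlc_correlation: float
    hlc_pvalue: float


def cnb_profile(net: SignedNetwork,
                coeffs: pd.DataFrame | None = None,
                denominator: str = "min_total") -> CnbProfile:
    """Build the CNB profile of every negative edge with hybrid neighbors."""
    if coeffs is None:
        coeffs = link_clustering_coefficients(net, denominator=denominator)
    plc_of = {}
    hlc_of = {}
    for row in coeffs.itertuples(index=False):
        key = (row.source, row.target)
        plc_of[key] = row.plc
        hlc_of[key] = row.hlc
    adj = net.adjacency()
    rows = []
    for u, v, sign in net.edges():
        if sign > 0:
            continue
        pos_plcs: list[float] = []
        neg_hlcs: list[float] = []
        for k, s_uk in adj[u].items():
            if k == v:
                continue
            s_vk = adj[v].get(k)
            if s_vk is None:
                continue
            if s_uk * s_vk < 0:  # hybrid common neighbor
                pos_end, neg_end = (u, v) if s_uk > 0 else (v, u)
                pos_plcs.append(plc_of[canonical_edge(pos_end, k)])
                neg_hlcs.append(hlc_of[canonical_edge(neg_end, k)])
        if pos_plcs:
            rows.append((u, v, hlc_of[(u, v)], len(pos_plcs),
                         median(pos_plcs), median(neg_hlcs)))
    table = pd.DataFrame(rows, columns=[
        "source", "target", "hlc", "n_hybrid", "median_plc", "median_hlc"])
    r_plc = p_plc = r_hlc = p_hlc = math.nan
    if len(table) >= 3:
        x = table["hlc"].to_numpy()
        for col, slot in (("median_plc", "plc"), ("median_hlc", "hlc")):
            y = table[col].to_numpy()
            if np.std(x) > 0 and np.std(y) > 0:
                r, p = stats.pearsonr(y, x)
                if slot == "plc":
                    r_plc, p_plc = r, p
                else:
                    r_hlc, p_hlc = r, p
    return CnbProfile(table, r_plc, p_plc, r_hlc, p_hlc)
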