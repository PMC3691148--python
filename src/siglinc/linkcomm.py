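"""Link-community discovery on same-sign links via partition density.

Positive links are scored by the same-sign similarity S_e = PLC_e + NLC_e
(the link-clustering contribution of same-sign neighbor pairs).  Sweeping
a cutoff down through the distinct score values, links with S_e >= cutoff
are retained and merged single-linkage style: two retained links belong
to the same community iff they share a node (connected components of the
retained-link graph).  Each level is scored by the partition density of
Ahn et al.,

    D = (2 / M) * sum_c m_c * (m_c - (n_c - 1)) / ((n_c - 2) (n_c - 1)),

where community c has m_c links over n_c nodes and M = sum_c m_c; a
community that is a tree contributes 0, a clique contributes its maximal
value, so D runs from 0 (forest) to 1 (disjoint cliques).  Communities
with n_c = 2 contribute 0 by convention.  The module-extraction cutoff is
the score maximizing D (ties broken toward the largest, most stringent
cutoff by default), and modules are the link communities whose induced
gene set reaches ``min_genes``.

The module map summarizes a set of modules as a meta-network: per module
the intra-module positive/negative link densities, per module pair the
number of network links spanning them and the fraction that is negative.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coefficients import link_clustering_coefficients
from .network import SignedNetwork

__all__ = [
    "link_similarity_scores",
    "partition_density",
    "sweep_partition_density",
    "extract_modules",
    "LinkPartition",
    "Module",
    "module_map",
    "ModuleMap",
]

Edge = tuple[str, str]


def link_similarity_scores(coeffs: pd.DataFrame,
                           sign: int = 1) -> dict[Edge, float]:
    """Same-sign similarity score S_e = PLC_e + NLC_e per edge of ``sign``."""
    out: dict[Edge, float] = {}
    for row in coeffs.itertuples(index=False):
        if row.sign == sign:
            out[(row.source, row.target)] = row.plc + row.nlc
    return out


def _community_term(m: int, n: int) -> float:
    """Contribution m_c (m_c - (n_c-1)) / ((n_c-2)(n_c-1)) of one community."""
    if m < n - 1:
        raise ValueError(
            f"community with {m} links cannot connect {n} nodes")
    if n <= 2:
        return 0.0
    return m * (m - (n - 1)) / ((n - 2) * (n - 1))


def partition_density(communities: Iterable[Sequence[Edge]]) -> float:
    """Partition density D of disjoint link communities.

    Each community is a collection of edges; node counts are derived from
    the endpoints.  D = (2/M) * sum of per-community terms with M the
    total number of links across communities; empty input gives 0.
    """
    total_links = 0
    acc = 0.0
    for edges in communities:
        edges = list(edges)
        nodes = {n for e in edges for n in e}
        total_links += len(edges)
        acc += _community_term(len(edges), len(nodes))
    if total_links == 0:
        return 0.0
    return 2.0 * acc / total_links


class _DisjointSet:
    """Union-find over nodes tracking per-component link/node counts."""

    def __init__(self) -> None:
        self.parent: dict[str, str] = {}
        self.m: dict[str, int] = {}
        self.n: dict[str, int] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def add_node(self, x: str) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.m[x] = 0
            self.n[x] = 1

    def add_edge(self, u: str, v: str) -> tuple[str, float, float]:
        """Attach edge (u, v); returns (new root, removed term, added term)."""
        self.add_node(u)
        self.add_node(v)
        ru, rv = self.find(u), self.find(v)
        removed = _community_term(self.m[ru], self.n[ru])
        if ru == rv:
            self.m[ru] += 1
        else:
            removed += _community_term(self.m[rv], self.n[rv])
            if self.n[ru] < self.n[rv]:
                ru, rv = rv, ru
            self.parent[rv] = ru
            self.m[ru] += self.m[rv] + 1
            self.n[ru] += self.n[rv]
        return ru, removed, _community_term(self.m[ru], self.n[ru])


def sweep_partition_density(net: SignedNetwork,
                            scores: Mapping[Edge, float] | None = None,
                            sign: int = 1) -> pd.DataFrame:
    """Partition density at every distinct score cutoff, descending.

    Returns a DataFrame with columns ``cutoff, n_edges, n_communities,
    density``; each row retains edges with S_e >= cutoff.  The last row
    (the minimum score) retains every edge of the requested sign, i.e.
    the connected components of the same-sign subnetwork.
    """
    if scores is None:
        scores = link_similarity_scores(
            link_clustering_coefficients(net), sign=sign)
    sign_edges = [(u, v) for u, v, s in net.edges() if s == sign]
    if not sign_edges:
        raise ValueError(f"network has no edges of sign {sign:+d}")
    missing = [e for e in sign_edges if e not in scores]
    if missing:
        raise ValueError(f"missing scores for {len(missing)} edges, "
                         f"e.g. {missing[0]}")
    ordered = sorted(sign_edges, key=lambda e: (-scores[e], e))
    dsu = _DisjointSet()
    acc = 0.0
    retained = 0
    rows = []
    i = 0
    while i < len(ordered):
        cutoff = scores[ordered[i]]
        while i < len(ordered) and scores[ordered[i]] == cutoff:
            u, v = ordered[i]
            _, removed, added = dsu.add_edge(u, v)
            acc += added - removed
            retained += 1
            i += 1
        roots = {dsu.find(x) for x in dsu.parent}
        n_comm = sum(1 for r in roots if dsu.m[r] > 0)
        rows.append((cutoff, retained, n_comm,
                     2.0 * acc / retained if retained else 0.0))
    return pd.DataFrame(rows,
                        columns=["cutoff", "n_edges", "n_communities",
                                 "density"])


@dataclass
class Module:
    """A link community: its edges and the induced gene (node) set."""

    module_id: int
    genes: frozenset[str]
    edges: tuple[Edge, ...]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_links(self) -> int:
        return len(self.edges)


@dataclass
class LinkPartition:
    """Link-community partition of the same-sign subnetwork at a cutoff."""

    sign: int
    cutoff: float
    communities: list[Module]
    density: float
    n_sign_edges: int  # total links of this sign in the network
    sweep: pd.DataFrame

    @property
    def n_retained(self) -> int:
        return sum(c.n_links for c in self.communities)


def _communities_at_cutoff(ordered: list[Edge],
                           scores: Mapping[Edge, float],
                           cutoff: float) -> list[list[Edge]]:
    dsu = _DisjointSet()
    kept = [e for e in ordered if scores[e] >= cutoff]
    for u, v in kept:
        dsu.add_edge(u, v)
    groups: dict[str, list[Edge]] = {}
    for e in kept:
        groups.setdefault(dsu.find(e[0]), []).append(e)
    return list(groups.values())


def extract_modules(net: SignedNetwork,
                    scores: Mapping[Edge, float] | None = None,
                    sign: int = 1, min_genes: int = 3,
                    tie_rule: str = "stringent",
                    denominator: str = "min_total",
                    ) -> tuple[LinkPartition, list[Module]]:
    """Link communities at the partition-density-maximizing cutoff.

    Returns the full partition (every community, regardless of size) and
    the modules — communities whose gene set has at least ``min_genes``
    members.  Ties in maximal density go to the largest cutoff under the
    default ``"stringent"`` rule (``"inclusive"`` picks the smallest).
    """
    if tie_rule not in ("stringent", "inclusive"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    if scores is None:
        scores = link_similarity_scores(
            link_clustering_coefficients(net, denominator=denominator),
            sign=sign)
    sweep = sweep_partition_density(net, scores, sign=sign)
    best = sweep["density"].max()
    at_best = sweep[sweep["density"] == best]["cutoff"]
    cutoff = float(at_best.max() if tie_rule == "stringent"
                   else at_best.min())
    sign_edges = [(u, v) for u, v, s in net.edges() if s == sign]
    ordered = sorted(sign_edges, key=lambda e: (-scores[e], e))
    communities = []
    for mid, edges in enumerate(
            sorted(_communities_at_cutoff(ordered, scores, cutoff),
                   key=lambda es: (-len(es), sorted(es)))):
        genes = frozenset(n for e in edges for n in e)
        communities.append(Module(mid, genes, tuple(sorted(edges))))
    partition = LinkPartition(sign=sign, cutoff=cutoff,
                              communities=communities,
                              density=float(best),
                              n_sign_edges=len(sign_edges), sweep=sweep)
    modules = [c for c in communities if c.n_genes >= min_genes]
    return partition, modules


@dataclass
class ModuleMap:
    """Meta-network over modules.

    ``nodes``: one row per module (gene count, intra-module positive and
    negative link densities over C(n_genes, 2) possible pairs).
    ``edges``: one row per module pair joined by at least one spanning
    link, with the spanning-link count and the fraction negative.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame


def module_map(net: SignedNetwork,
               modules: Sequence[Module | frozenset[str] | set[str]],
               ) -> ModuleMap:
    """Summarize modules and their interconnections as a meta-network."""
    gene_sets: list[frozenset[str]] = []
    ids: list[int] = []
    for idx, m in enumerate(modules):
        if isinstance(m, Module):
            gene_sets.append(m.genes)
            ids.append(m.module_id)
        else:
            gene_sets.append(frozenset(m))
            ids.append(idx)
    edges = list(net.edges())
    node_rows = []
    for mid, genes in zip(ids, gene_sets):
        n = len(genes)
        possible = n * (n - 1) // 2
        pos = sum(1 for u, v, s in edges
                  if u in genes and v in genes and s > 0)
        neg = sum(1 for u, v, s in edges
                  if u in genes and v in genes and s < 0)
        node_rows.append({
            "module_id": mid, "n_genes": n,
            "pos_density": pos / possible if possible else 0.0,
            "neg_density": neg / possible if possible else 0.0,
        })
    edge_rows = []
    for (ia, ga), (ib, gb) in combinations(zip(ids, gene_sets), 2):
        count = neg = 0
        for u, v, s in edges:
            in_a = u in ga and v in ga
            in_b = u in gb and v in gb
            spans = ((u in ga and v in gb) or (u in gb and v in ga))
            if spans and not in_a and not in_b:
                count += 1
                if s < 0:
                    neg += 1
        if count:
            edge_rows.append({
                "module_a": ia, "module_b": ib,
                "n_links": count, "prop_negative": neg / count,
            })
    return ModuleMap(
        nodes=pd.DataFrame(node_rows, columns=[
            "module_id", "n_genes", "pos_density", "neg_density"]),
        edges=pd.DataFrame(edge_rows, columns=[
            "module_a", "module_b", "n_links", "prop_negative"]))
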