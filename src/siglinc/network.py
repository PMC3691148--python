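"""Data model and I/O for signed undirected networks.

A :class:`SignedNetwork` is a simple undirected graph whose edges carry a
sign in ``{+1, -1}``: positive links model coexpression or alleviating
(positive) genetic interactions, negative links anti-coexpression or
aggravating interactions such as synthetic lethality.  Node identifiers are
opaque, case-sensitive strings; edges are keyed internally by the
lexicographically sorted node pair so iteration order is deterministic.

The module also provides readers for plain signed edge lists (TSV) and
BioGRID-style tab-delimited genetic-interaction records, including the
sign mapping from interaction-type labels and removal of ambiguous pairs
that were reported with both signs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

POSITIVE = 1
NEGATIVE = -1

#: Canonical genetic-interaction sign map: alleviating / suppressing
#: interaction types are positive, aggravating ones negative.  Lookup is
#: case-insensitive.
DEFAULT_GI_SIGN_MAP: dict[str, int] = {
    "synthetic rescue": POSITIVE,
    "positive genetic": POSITIVE,
    "synthetic lethality": NEGATIVE,
    "negative genetic": NEGATIVE,
}

_SIGN_TOKENS = {"+1": POSITIVE, "+": POSITIVE, "1": POSITIVE,
                "-1": NEGATIVE, "-": NEGATIVE}


class SignConflictError(ValueError):
    """Raised when the same node pair is given both a + and a - sign."""

    def __init__(self, pair: tuple[str, str]):
        self.pair = pair
        super().__init__(f"conflicting signs for edge {pair[0]} -- {pair[1]}")


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered pair (u, v) in canonical (sorted) order."""
    if u == v:
        raise ValueError(f"self-loop on node {u!r}")
    return (u, v) if u <= v else (v, u)


@dataclass
class ExcessNeighbors:
    """Neighbor counts of a node excluding one designated partner.

    ``n`` is the number of excess neighbors, ``n_pos``/``n_neg`` the counts
    reached through positive / negative links; ``n == n_pos + n_neg``.
    """

    n: int
    n_pos: int
    n_neg: int


class SignedNetwork:
    """Simple undirected graph with a sign in {+1, -1} on every edge.

    Invariants: no self-loops, at most one edge (hence one sign) per node
    pair, and the node set contains every edge endpoint.  Backed by a
    :class:`networkx.Graph` with a ``sign`` edge attribute.
    """

    def __init__(self, edges: Iterable[tuple[str, str, int]] = (),
                 nodes: Iterable[str] = ()):
        self._g = nx.Graph()
        for node in nodes:
            self._g.add_node(str(node))
        for u, v, sign in edges:
            self.add_edge(u, v, sign)

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        self._g.add_node(str(node))

    def add_edge(self, u: str, v: str, sign: int) -> None:
        """Add an edge; re-adding with the same sign is a no-op.

        Raises :class:`SignConflictError` if the pair already carries the
        opposite sign, and ``ValueError`` for self-loops or invalid signs.
        """
        u, v = str(u), str(v)
        key = canonical_edge(u, v)
        sign = int(sign)
        if sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"sign must be +1 or -1, got {sign!r}")
        existing = self._g.edges.get(key)
        if existing is not None:
            if existing["sign"] != sign:
                raise SignConflictError(key)
            return
        self._g.add_edge(*key, sign=sign)

    def remove_edge(self, u: str, v: str) -> None:
        self._g.remove_edge(u, v)

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Iterate edges as (u, v, sign) in canonical sorted order."""
        for u, v in sorted(canonical_edge(a, b) for a, b in self._g.edges):
            yield u, v, self._g.edges[u, v]["sign"]

    def has_node(self, node: str) -> bool:
        return node in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def sign(self, u: str, v: str) -> int:
        try:
            return self._g.edges[u, v]["sign"]
        except KeyError:
            raise KeyError(f"no edge {u!r} -- {v!r}") from None

    def neighbors(self, node: str) -> set[str]:
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")
        return set(self._g[node])

    def degree(self, node: str) -> int:
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")
        return self._g.degree[node]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def n_positive(self) -> int:
        return sum(1 for _, _, s in self.edges() if s == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, s in self.edges() if s == NEGATIVE)

    def adjacency(self) -> dict[str, dict[str, int]]:
        """Node -> {neighbor: sign} mapping (copy)."""
        return {u: {v: d["sign"] for v, d in nbrs.items()}
                for u, nbrs in self._g.adjacency()}

    def excess_neighbors(self, node: str, exclude: str) -> ExcessNeighbors:
        """Signed neighbor counts of ``node`` excluding ``exclude``.

        ``exclude`` need not be adjacent to ``node``; if it is not, the
        counts equal the plain signed degree.
        """
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")
        n_pos = n_neg = 0
        for nbr, data in self._g[node].items():
            if nbr == exclude:
                continue
            if data["sign"] == POSITIVE:
                n_pos += 1
            else:
                n_neg += 1
        return ExcessNeighbors(n_pos + n_neg, n_pos, n_neg)

    def subnetwork_of_sign(self, sign: int) -> "SignedNetwork":
        """Subnetwork keeping only edges of one sign (nodes preserved)."""
        sub = SignedNetwork(nodes=self.nodes)
        for u, v, s in self.edges():
            if s == sign:
                sub.add_edge(u, v, s)
        return sub

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.edges(), nodes=self.nodes)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return (self.nodes == other.nodes
                and list(self.edges()) == list(other.edges()))

    def __len__(self) -> int:
        return self.n_nodes

    def __repr__(self) -> str:
        return (f"SignedNetwork(n_nodes={self.n_nodes}, "
                f"n_edges={self.n_edges}, "
                f"n_positive={self.n_positive}, n_negative={self.n_negative})")


def signed_excess_neighbors(net: SignedNetwork, node: str,
                            exclude: str) -> ExcessNeighbors:
    """Functional alias for :meth:`SignedNetwork.excess_neighbors`."""
    return net.excess_neighbors(node, exclude)


def parse_sign(token: str) -> int:
    token = token.strip()
    if token not in _SIGN_TOKENS:
        raise ValueError(f"cannot parse sign {token!r}")
    return _SIGN_TOKENS[token]


def _open_maybe(source: str | Path | TextIO, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_signed_edge_list(source: str | Path | TextIO,
                          conflict_policy: str = "error") -> SignedNetwork:
    """Read a signed edge list (TSV: ``node_a  node_b  sign``).

    Blank lines and ``#`` comments are skipped; an optional single header
    row is detected by its unparseable sign column.  Duplicate rows with an
    identical sign are deduplicated.  Self-loop rows are skipped with a
    logged warning.  Pairs appearing with both signs raise
    :class:`SignConflictError` under ``conflict_policy="error"`` or are
    removed entirely under ``"drop"``.
    """
    if conflict_policy not in ("error", "drop"):
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    stream, should_close = _open_maybe(source)
    signs: dict[tuple[str, str], int] = {}
    conflicted: set[tuple[str, str]] = set()
    try:
        seen_data = False
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected 3 columns, "
                                 f"got {len(fields)}")
            a, b, sign_token = fields[0].strip(), fields[1].strip(), fields[2]
            try:
                sign = parse_sign(sign_token)
            except ValueError:
                if not seen_data:
                    # header row
                    seen_data = True
                    continue
                raise ValueError(
                    f"line {lineno}: cannot parse sign {sign_token!r}")
            seen_data = True
            if a == b:
                logger.warning("line %d: skipping self-loop on %r", lineno, a)
                continue
            key = canonical_edge(a, b)
            if key in signs and signs[key] != sign:
                if conflict_policy == "error":
                    raise SignConflictError(key)
                conflicted.add(key)
            else:
                signs[key] = sign
    finally:
        if should_close:
            stream.close()
    net = SignedNetwork()
    for (a, b), sign in signs.items():
        if (a, b) not in conflicted:
            net.add_edge(a, b, sign)
    return net


def write_signed_edge_list(net: SignedNetwork,
                           target: str | Path | TextIO) -> None:
    """Write a network as TSV with signs rendered as ``+1`` / ``-1``.

    Round-trips exactly through :func:`read_signed_edge_list` for networks
    without isolated nodes (isolated nodes have no row to carry them).
    """
    stream, should_close = _open_maybe(target, "w")
    try:
        stream.write("source\ttarget\tsign\n")
        for u, v, sign in net.edges():
            stream.write(f"{u}\t{v}\t{'+1' if sign > 0 else '-1'}\n")
    finally:
        if should_close:
            stream.close()


@dataclass
class InteractionReport:
    """Bookkeeping from building a network out of interaction records."""

    n_records: int = 0
    n_unmapped: int = 0
    n_self_pairs: int = 0
    n_ambiguous_pairs: int = 0
    ambiguous_pairs: list[tuple[str, str]] = field(default_factory=list)


def from_interaction_records(
    records: Iterable[tuple[str, str, str]],
    sign_map: Mapping[str, int] | None = None,
    ambiguous_policy: str = "drop",
) -> tuple[SignedNetwork, InteractionReport]:
    """Build a signed network from (gene_a, gene_b, type_label) records.

    Labels absent from ``sign_map`` (case-insensitive) are ignored,
    self-pairs dropped, and pairs supported by both signs ("ambiguous")
    removed entirely under the default ``drop`` policy (``"error"`` raises
    instead).  The report counts everything that was discarded.
    """
    if sign_map is None:
        sign_map = DEFAULT_GI_SIGN_MAP
    if not sign_map:
        raise ValueError("sign_map must not be empty")
    if ambiguous_policy not in ("drop", "error"):
        raise ValueError(f"unknown ambiguous policy {ambiguous_policy!r}")
    lower_map = {str(k).lower(): int(v) for k, v in sign_map.items()}
    if any(v not in (POSITIVE, NEGATIVE) for v in lower_map.values()):
        raise ValueError("sign_map values must be +1 or -1")

    report = InteractionReport()
    signs: dict[tuple[str, str], int] = {}
    ambiguous: set[tuple[str, str]] = set()
    for a, b, label in records:
        report.n_records += 1
        sign = lower_map.get(str(label).lower())
        if sign is None:
            report.n_unmapped += 1
            continue
        a, b = str(a), str(b)
        if a == b:
            report.n_self_pairs += 1
            continue
        key = canonical_edge(a, b)
        if key in ambiguous:
            continue
        if key in signs and signs[key] != sign:
            if ambiguous_policy == "error":
                raise SignConflictError(key)
            ambiguous.add(key)
            del signs[key]
        else:
            signs[key] = sign
    report.n_ambiguous_pairs = len(ambiguous)
    report.ambiguous_pairs = sorted(ambiguous)
    net = SignedNetwork()
    for (a, b), sign in signs.items():
        net.add_edge(a, b, sign)
    return net, report


def read_biogrid(
    source: str | Path | TextIO,
    sign_map: Mapping[str, int] | None = None,
    col_a: int = 6,
    col_b: int = 7,
    col_label: int = 12,
    col_taxid_a: int = 16,
    col_taxid_b: int = 17,
    taxid: str | None = None,
    ambiguous_policy: str = "drop",
) -> tuple[SignedNetwork, InteractionReport]:
    """Parse a BioGRID-style tab-delimited file into a signed network.

    Column indices are 1-based and default to the TAB 2.0 layout
    (systematic names in columns 6/7, experimental system in column 12,
    organism identifiers in 16/17).  ``#``-prefixed lines are skipped.
    ``taxid`` optionally restricts records to rows where both interactors
    belong to that organism.
    """
    stream, should_close = _open_maybe(source)
    try:
        records = []
        max_col = max(col_a, col_b, col_label,
                      *( (col_taxid_a, col_taxid_b) if taxid else () ))
        for raw in stream:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < max_col:
                continue
            if taxid is not None:
                if (fields[col_taxid_a - 1].strip() != taxid
                        or fields[col_taxid_b - 1].strip() != taxid):
                    continue
            records.append((fields[col_a - 1].strip(),
                            fields[col_b - 1].strip(),
                            fields[col_label - 1].strip()))
    finally:
        if should_close:
            stream.close()
    return from_interaction_records(records, sign_map,
                                    ambiguous_policy=ambiguous_policy)
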