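"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from siglinc import BlockSpec, SignedNetwork, balanced_block_network

#: 5-node worked example used throughout: a positive triangle {1,2,3}
#: plus node 4 (positive to 1, negative to 2) and node 5 (negative to
#: both 1 and 2).
E1_EDGES = [("1", "2", 1), ("1", "3", 1), ("2", "3", 1),
            ("1", "4", 1), ("2", "4", -1), ("1", "5", -1), ("2", "5", -1)]


@pytest.fixture
def e1() -> SignedNetwork:
    return SignedNetwork(E1_EDGES)


@pytest.fixture
def balanced_pair() -> tuple[SignedNetwork, dict[str, int]]:
    """Complete balanced two-block network with blocks of size 3."""
    return balanced_block_network(BlockSpec(sizes=(3, 3), seed=0))


def random_net(seed: int, n_max: int = 30, p: float = 0.25,
               positive_fraction: float = 0.6) -> SignedNetwork:
    """Deterministic small random signed graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    net = SignedNetwork(nodes=[f"n{i:02d}" for i in range(n)])
    nodes = sorted(net.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                sign = 1 if rng.random() < positive_fraction else -1
                net.add_edge(nodes[i], nodes[j], sign)
    return net


# ---------------------------------------------------------------------
# Independent oracles.  These deliberately avoid the library's adjacency
# helpers: everything is recomputed from the raw edge list by scanning
# node triples, so they share no code path with the implementation.
# ---------------------------------------------------------------------

def oracle_coefficients(net: SignedNetwork) -> dict:
    """Brute-force signed link-clustering coefficients per edge.

    For every edge (i, j), enumerate all other nodes k and classify the
    triples via raw edge-list membership.
    """
    edge_sign = {(u, v): s for u, v, s in net.edges()}
    edge_sign.update({(v, u): s for (u, v), s in list(edge_sign.items())})
    nodes = sorted(net.nodes)
    out = {}
    for (i, j), sign in list(edge_sign.items()):
        if i > j:
            continue
        c = {"pp": 0, "nn": 0, "hy": 0}
        for k in nodes:
            if k in (i, j):
                continue
            s_ik = edge_sign.get((i, k))
            s_jk = edge_sign.get((j, k))
            if s_ik is None or s_jk is None:
                continue
            if s_ik > 0 and s_jk > 0:
                c["pp"] += 1
            elif s_ik < 0 and s_jk < 0:
                c["nn"] += 1
            else:
                c["hy"] += 1
        n_i = sum(1 for k in nodes
                  if k not in (i, j) and (i, k) in edge_sign)
        n_j = sum(1 for k in nodes
                  if k not in (i, j) and (j, k) in edge_sign)
        d = min(n_i, n_j)

        def frac(x: int) -> float:
            return x / d if d else 0.0

        out[(i, j)] = {
            "sign": sign, "c_pp": c["pp"], "c_nn": c["nn"],
            "c_hy": c["hy"], "n_i": n_i, "n_j": n_j,
            "lc": frac(c["pp"] + c["nn"] + c["hy"]),
            "slc": frac(c["pp"] + c["nn"]), "hlc": frac(c["hy"]),
            "plc": frac(c["pp"]), "nlc": frac(c["nn"]),
        }
    return out


def oracle_triads(net: SignedNetwork) -> dict[str, int]:
    """Brute-force triple scan over all node triples."""
    edge_sign = {(u, v): s for u, v, s in net.edges()}
    edge_sign.update({(v, u): s for (u, v), s in list(edge_sign.items())})
    nodes = sorted(net.nodes)
    counts = {"T1": 0, "T2": 0, "T3": 0, "T4": 0}
    type_by_neg = {0: "T1", 1: "T3", 2: "T2", 3: "T4"}
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            for c in range(b + 1, len(nodes)):
                u, v, w = nodes[a], nodes[b], nodes[c]
                signs = [edge_sign.get((u, v)), edge_sign.get((u, w)),
                         edge_sign.get((v, w))]
                if None in signs:
                    continue
                counts[type_by_neg[sum(1 for s in signs if s < 0)]] += 1
    return counts
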