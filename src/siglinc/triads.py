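"""Signed triad census and the sign-shuffling null model.

Every triangle (node triple with all three edges present) is classified
by the multiset of its edge signs:

* T1 ``+++`` and T2 ``+--`` are the *balanced* types,
* T3 ``++-`` and T4 ``---`` the *unbalanced* ones.

A structurally balanced network — one divisible into groups with positive
links inside groups and negative links between them — contains only T1
and T2 triangles.  Over-representation of a type is measured against the
sign-shuffle null: the topology is held fixed and the multiset of signs
permuted uniformly at random, preserving the positive/negative edge
counts (and hence the total triangle count) exactly.  Fold enrichment is
observed / null mean; empirical p-values use an add-one pseudocount so
they are never exactly 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import SignedNetwork

__all__ = [
    "TRIAD_TYPES",
    "TriadCensus",
    "count_signed_triads",
    "shuffle_signs",
    "expected_triad_counts",
    "triad_enrichment",
]

#: Triad type -> sign multiset (number of negative edges: 0, 2, 1, 3).
TRIAD_TYPES = {"T1": "+++", "T2": "+--", "T3": "++-", "T4": "---"}
_NEG_TO_TYPE = {0: "T1", 2: "T2", 1: "T3", 3: "T4"}


@dataclass
class TriadCensus:
    """Counts of signed triangle types, optionally with null statistics.

    ``counts`` maps T1..T4 to observed counts.  After an enrichment run,
    ``null_mean``/``null_sd``/``fold``/``p_over``/``p_under`` are filled
    per type; fold is ``inf`` when the null mean is 0 but the type was
    observed, and NaN when both are 0.
    """

    counts: dict[str, int]
    total: int
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)
    fold: dict[str, float] = field(default_factory=dict)
    p_over: dict[str, float] = field(default_factory=dict)
    p_under: dict[str, float] = field(default_factory=dict)
    n_shuffles: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, pattern in TRIAD_TYPES.items():
            rows.append({
                "type": t,
                "pattern": pattern,
                "observed": self.counts[t],
                "null_mean": self.null_mean.get(t, math.nan),
                "null_sd": self.null_sd.get(t, math.nan),
                "fold": self.fold.get(t, math.nan),
                "p_over": self.p_over.get(t, math.nan),
                "p_under": self.p_under.get(t, math.nan),
            })
        return pd.DataFrame(rows)


def _triangle_sign_index(net: SignedNetwork):
    """Triangle list as index triples into the canonical edge array."""
    edges = list(net.edges())
    edge_index = {(u, v): i for i, (u, v, _) in enumerate(edges)}
    adj = {n: set() for n in net.nodes}
    for u, v, _ in edges:
        adj[u].add(v)
        adj[v].add(u)
    triples = []
    for u, v, _ in edges:  # canonical order ensures u < v
        common = adj[u] & adj[v]
        for w in common:
            if w > v:
                triples.append((edge_index[(u, v)],
                                edge_index[(u, w) if u < w else (w, u)],
                                edge_index[(v, w) if v < w else (w, v)]))
    signs = np.array([s for _, _, s in edges], dtype=np.int8)
    return signs, np.array(triples, dtype=np.int64).reshape(-1, 3)


def _classify(signs: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Counts [T1, T3, T2, T4] indexed by number of negative edges 0..3."""
    if len(triples) == 0:
        return np.zeros(4, dtype=np.int64)
    n_neg = (signs[triples] < 0).sum(axis=1)
    return np.bincount(n_neg, minlength=4)


def count_signed_triads(net: SignedNetwork) -> TriadCensus:
    """Exhaustive census of signed triangles, each counted exactly once."""
    signs, triples = _triangle_sign_index(net)
    by_neg = _classify(signs, triples)
    counts = {t: int(by_neg[k]) for k, t in _NEG_TO_TYPE.items()}
    return TriadCensus(counts=counts, total=int(by_neg.sum()))


def shuffle_signs(net: SignedNetwork,
                  rng: np.random.Generator) -> SignedNetwork:
    """Permute the multiset of edge signs uniformly, keeping topology.

    The returned network has identical node pairs and degree sequence and
    exactly the same number of positive and negative edges.
    """
    edges = list(net.edges())
    signs = np.array([s for _, _, s in edges])
    shuffled = rng.permutation(signs)
    out = SignedNetwork(nodes=net.nodes)
    for (u, v, _), s in zip(edges, shuffled):
        out.add_edge(u, v, int(s))
    return out


def expected_triad_counts(net: SignedNetwork) -> dict[str, float]:
    """Closed-form null expectations under uniform sign permutation.

    Drawing the 3 signs of a triangle is a without-replacement draw from
    the global sign multiset, so E[count of the type with k negative
    edges] = total_triangles * hypergeom.pmf(k; M, M_neg, 3).
    """
    census = count_signed_triads(net)
    m = net.n_edges
    m_neg = net.n_negative
    return {
        t: census.total * float(stats.hypergeom.pmf(k, m, m_neg, 3))
        for k, t in _NEG_TO_TYPE.items()
    }


def triad_enrichment(net: SignedNetwork, n_shuffles: int = 1000,
                     seed: int | None = None) -> TriadCensus:
    """Census plus fold-enrichment and empirical p-values vs the null.

    The seed drives a splittable stream (one child per shuffle), so the
    per-shuffle draws are independent of evaluation order.  Empirical
    p-values use the add-one convention
    ``p_over = (1 + #{null >= obs}) / (n_shuffles + 1)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    signs, triples = _triangle_sign_index(net)
    observed = _classify(signs, triples)
    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    null = np.empty((n_shuffles, 4), dtype=np.int64)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        null[s] = _classify(rng.permutation(signs), triples)

    census = TriadCensus(
        counts={t: int(observed[k]) for k, t in _NEG_TO_TYPE.items()},
        total=int(observed.sum()),
        n_shuffles=n_shuffles, seed=seed)
    for k, t in _NEG_TO_TYPE.items():
        obs = observed[k]
        mean = float(null[:, k].mean())
        census.null_mean[t] = mean
        census.null_sd[t] = float(null[:, k].std(ddof=1)) \
            if n_shuffles > 1 else math.nan
        if mean > 0:
            census.fold[t] = obs / mean
        else:
            census.fold[t] = math.inf if obs > 0 else math.nan
        census.p_over[t] = (1 + int((null[:, k] >= obs).sum())) \
            / (n_shuffles + 1)
        census.p_under[t] = (1 + int((null[:, k] <= obs).sum())) \
            / (n_shuffles + 1)
    return census
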