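"""Synthetic signed networks and expression matrices with ground truth.

Three generators give the analysis modules a download-free test surface:

* :func:`balanced_block_network` — structurally balanced block networks
  (positive links inside blocks, negative links between, optional sign
  noise), the canonical testbed for balance-driven invariants and module
  recovery;
* :func:`random_signed_network` — Erdős–Rényi topology with signs drawn
  independently of structure, the natural null for triad enrichment;
* :func:`planted_module_expression` — expression matrices with planted
  correlated gene modules arranged in anti-correlated (anti-phase) pairs
  across two sample condition blocks, from which PCC thresholding should
  recover positive links within modules and negative links between the
  paired ones.

Every generator is bit-reproducible under a fixed seed (seeds are split
deterministically per call; no global RNG state) and returns ground
truth sufficient to score recovery.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .network import SignedNetwork

__all__ = [
    "BlockSpec",
    "balanced_block_network",
    "random_signed_network",
    "planted_module_expression",
]


@dataclass
class BlockSpec:
    """Parameters of a structurally balanced block network.

    ``sizes`` gives the number of nodes per block; intra-block node pairs
    receive a positive edge with probability ``p_in`` and inter-block
    pairs a negative edge with probability ``p_out``.  Each realized
    edge's sign is then flipped independently with probability
    ``sign_noise`` — at 0 the network is exactly balanced.
    """

    sizes: tuple[int, ...]
    p_in: float = 1.0
    p_out: float = 1.0
    sign_noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if len(self.sizes) < 1 or any(s < 1 for s in self.sizes):
            raise ValueError("block sizes must be positive")
        for name in ("p_in", "p_out", "sign_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def balanced_block_network(
        spec: BlockSpec) -> tuple[SignedNetwork, dict[str, int]]:
    """Sample a (noisy) balanced block network and its block labels."""
    rng = np.random.default_rng(spec.seed)
    labels: dict[str, int] = {}
    for b, size in enumerate(spec.sizes):
        for g in range(size):
            labels[f"b{b}n{g:03d}"] = b
    nodes = sorted(labels)
    net = SignedNetwork(nodes=nodes)
    for u, v in combinations(nodes, 2):
        same = labels[u] == labels[v]
        p = spec.p_in if same else spec.p_out
        if rng.random() < p:
            sign = 1 if same else -1
            if spec.sign_noise > 0 and rng.random() < spec.sign_noise:
                sign = -sign
            net.add_edge(u, v, sign)
    return net, labels


def random_signed_network(n: int, p: float, positive_fraction: float = 0.5,
                          seed: int | None = None) -> SignedNetwork:
    """Erdős–Rényi G(n, p) with independent random edge signs."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError(
            f"positive_fraction must be in [0, 1], got {positive_fraction}")
    rng = np.random.default_rng(seed)
    width = len(str(max(n - 1, 1)))
    nodes = [f"v{i:0{width}d}" for i in range(n)]
    net = SignedNetwork(nodes=nodes)
    for u, v in combinations(nodes, 2):
        if rng.random() < p:
            net.add_edge(u, v,
                         1 if rng.random() < positive_fraction else -1)
    return net


def _standardize(x: np.ndarray) -> np.ndarray:
    """Exact zero mean, unit sample standard deviation (population ddof)."""
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate latent profile (zero variance)")
    return x / sd


def planted_module_expression(
        n_modules: int = 4,
        genes_per_module: int = 20,
        n_samples: int = 40,
        condition_split: float = 0.5,
        within_r: float = 0.95,
        between_r: float = -0.95,
        noise_sd: float = 1.0,
        seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix with planted anti-phase module pairs.

    Modules are arranged in pairs (0,1), (2,3), ...; the two members of a
    pair load on a shared condition profile with opposite signs, so their
    genes anti-correlate, while genes inside a module correlate.  The
    first pair's profile is the two-block condition contrast (the first
    ``condition_split`` fraction of samples up, the rest down); later
    pairs use latent profiles orthogonalized against all earlier ones, so
    distinct pairs are uncorrelated in expectation (exactly so at
    ``noise_sd=0``).

    Each gene in module m of pair p is built as

        x = b * u_m + phase_m * c * z_p + noise_sd * eps,

    with u_m a module-private latent profile, z_p the pair profile (both
    standardized) and eps i.i.d. normal noise.  b and c are calibrated so
    the expected within-module PCC is ``within_r`` and the expected PCC
    between paired modules is ``between_r`` (which must be negative, with
    |between_r| <= within_r).  At ``noise_sd=0`` within-module PCC is
    exactly 1 and paired-module PCC exactly -|between_r|/within_r.

    Returns ``(expression, truth)`` where ``truth`` has one row per gene
    with columns ``gene, module, pair, phase``.
    """
    if n_modules < 1 or genes_per_module < 1:
        raise ValueError("need at least one module and one gene")
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if not (0.0 < condition_split < 1.0):
        raise ValueError("condition_split must be in (0, 1)")
    if not (0.0 < within_r <= 1.0):
        raise ValueError(f"within_r must be in (0, 1], got {within_r}")
    if between_r > 0.0:
        raise ValueError("between_r must be <= 0 (anti-phase design)")
    if abs(between_r) > within_r:
        raise ValueError(
            f"|between_r| = {abs(between_r)} cannot exceed "
            f"within_r = {within_r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and within_r >= 1.0:
        raise ValueError("within_r = 1 requires noise_sd = 0")

    rng = np.random.default_rng(seed)
    r_b = abs(between_r)
    if noise_sd == 0:
        # noiseless: split the unit signal between shared and private parts
        c2 = r_b if within_r == 1.0 else r_b / within_r
        b2 = 1.0 - c2
    else:
        total = noise_sd**2 / (1.0 - within_r)
        c2 = r_b * total
        b2 = (within_r - r_b) * total
    b, c = np.sqrt(b2), np.sqrt(c2)

    n_up = int(round(condition_split * n_samples))
    n_up = min(max(n_up, 1), n_samples - 1)
    cond = np.concatenate([np.ones(n_up), -np.ones(n_samples - n_up)])

    n_pairs = (n_modules + 1) // 2
    if n_samples < n_pairs + n_modules + 2:
        raise ValueError(
            f"need n_samples >= {n_pairs + n_modules + 2} for "
            f"{n_modules} modules (orthogonal latent profiles)")

    # growing orthogonal basis: pair profiles first, then module privates,
    # so all latent profiles are exactly uncorrelated across the sample axis
    basis: list[np.ndarray] = []

    def _orthogonal_profile(x: np.ndarray) -> np.ndarray:
        x = x - x.mean()
        for q in basis:
            x = x - q * (q @ x) / n_samples
        x = _standardize(x)
        basis.append(x)
        return x

    pair_profiles = [_orthogonal_profile(cond.copy())]
    for _ in range(1, n_pairs):
        pair_profiles.append(
            _orthogonal_profile(rng.standard_normal(n_samples)))

    genes, rows, truth = [], [], []
    samples = ([f"condA_s{i:03d}" for i in range(n_up)]
               + [f"condB_s{i:03d}" for i in range(n_samples - n_up)])
    for m in range(n_modules):
        pair, phase = divmod(m, 2)
        phase = 1 if phase == 0 else -1
        u = _orthogonal_profile(rng.standard_normal(n_samples))
        base = b * u + phase * c * pair_profiles[pair]
        for g in range(genes_per_module):
            gene = f"m{m}_g{g:03d}"
            noise = (noise_sd * rng.standard_normal(n_samples)
                     if noise_sd > 0 else 0.0)
            genes.append(gene)
            rows.append(base + noise)
            truth.append((gene, m, pair, phase))
    expr = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    truth_df = pd.DataFrame(truth,
                            columns=["gene", "module", "pair", "phase"])
    return expr, truth_df
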