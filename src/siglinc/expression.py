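"""Coexpression-network construction from expression matrices.

Gene pairs are scored by the Pearson correlation coefficient (PCC) of
their expression profiles across samples and turned into a signed network
by thresholding: strongly correlated pairs (PCC >= ``pos_threshold``,
default 0.9) become positive coexpression links, strongly anti-correlated
pairs (PCC <= ``neg_threshold``, default -0.9) negative links.  Only genes
retaining at least one link enter the node set.

Missing values are handled with pairwise-complete observations; pairs with
fewer than ``min_samples`` shared observations, or zero variance on the
shared samples, are undefined and excluded.
"""
from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .network import SignedNetwork

__all__ = ["read_expression", "pairwise_pcc", "build_cen"]


def read_expression(source: str | Path | TextIO) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    First column holds gene identifiers, header row sample identifiers.
    GEO Series Matrix files are accepted: ``!``-prefixed metadata lines are
    skipped and surrounding quotes stripped from identifiers.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("!")]
    if not lines:
        raise ValueError("no data rows in expression input")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    return df.astype(float)


def _validate_matrix(expr: pd.DataFrame) -> None:
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate")
    if not expr.index.is_unique:
        raise ValueError("gene identifiers must be unique")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")


def pairwise_pcc(expr: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """All-pairs Pearson correlations as a long table.

    Returns a DataFrame with columns ``gene_a, gene_b, pcc, n_obs`` (one
    row per unordered gene pair, gene_a < gene_b).  Self-correlations are
    excluded, as are pairs with fewer than ``min_samples`` complete
    observations or zero variance over the shared samples (undefined PCC).
    """
    _validate_matrix(expr)
    corr, n_obs = _pcc_matrix(expr, min_samples)
    genes = expr.index.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    pcc = corr[iu]
    nn = n_obs[iu]
    keep = ~np.isnan(pcc)
    out = pd.DataFrame({
        "gene_a": genes[iu[0][keep]],
        "gene_b": genes[iu[1][keep]],
        "pcc": pcc[keep],
        "n_obs": nn[keep].astype(int),
    })
    swap = out["gene_a"] > out["gene_b"]
    out.loc[swap, ["gene_a", "gene_b"]] = out.loc[
        swap, ["gene_b", "gene_a"]].to_numpy()
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)


def _pcc_matrix(expr: pd.DataFrame,
                min_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense PCC matrix and pairwise-complete observation counts.

    Undefined entries (too few shared samples, zero variance) are NaN.
    """
    X = expr.to_numpy(dtype=float)
    finite = np.isfinite(X)
    n_obs = (finite.astype(np.int64) @ finite.T.astype(np.int64))
    if finite.all():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(X)
    else:
        # pairwise-complete path, delegated to pandas
        corr = expr.T.corr(min_periods=max(min_samples, 3)).to_numpy()
    corr = np.asarray(corr, dtype=float)
    corr[n_obs < min_samples] = np.nan
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, n_obs


def build_cen(expr: pd.DataFrame, pos_threshold: float = 0.9,
              neg_threshold: float = -0.9,
              min_samples: int = 10,
              block_size: int = 1024) -> SignedNetwork:
    """Build a signed coexpression network by PCC thresholding.

    An edge (g, h, +1) is created iff PCC(g, h) >= ``pos_threshold`` and
    (g, h, -1) iff PCC(g, h) <= ``neg_threshold``; ties at the thresholds
    are included.  Genes without any retained link are excluded from the
    node set.  Correlations are computed in row blocks of ``block_size``
    genes to bound memory; results match the naive all-pairs computation.
    """
    if not (-1.0 <= neg_threshold < 0.0 < pos_threshold <= 1.0):
        raise ValueError(
            f"thresholds must satisfy -1 <= neg < 0 < pos <= 1, got "
            f"neg={neg_threshold}, pos={pos_threshold}")
    _validate_matrix(expr)
    genes = expr.index.to_numpy()
    X = expr.to_numpy(dtype=float)
    finite = np.isfinite(X)
    net = SignedNetwork()

    if finite.all():
        # standardized rows: corr = Z @ Z.T / m
        m = X.shape[1]
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        ok = (sd[:, 0] > 0) & (np.full(len(genes), m >= min_samples))
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - mu) / (sd * np.sqrt(m))
        for start in range(0, len(genes), block_size):
            stop = min(start + block_size, len(genes))
            block = Z[start:stop] @ Z.T
            np.clip(block, -1.0, 1.0, out=block)
            for bi in range(stop - start):
                i = start + bi
                if not ok[i]:
                    continue
                row = block[bi, i + 1:]
                js = np.nonzero((row >= pos_threshold)
                                | (row <= neg_threshold))[0] + i + 1
                for j in js:
                    if ok[j]:
                        sign = 1 if row[j - i - 1] >= pos_threshold else -1
                        net.add_edge(genes[i], genes[j], sign)
    else:
        corr, _ = _pcc_matrix(expr, min_samples)
        iu = np.triu_indices(len(genes), k=1)
        vals = corr[iu]
        sel = np.nonzero((vals >= pos_threshold) | (vals <= neg_threshold))[0]
        for k in sel:
            i, j = iu[0][k], iu[1][k]
            net.add_edge(genes[i], genes[j],
                         1 if vals[k] >= pos_threshold else -1)
    return net
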