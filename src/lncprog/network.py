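"""Coding–lncRNA co-expression network construction.

All-pairs Pearson (or Spearman) correlation, Fisher's asymptotic z-test for
the significance of each coefficient, Bonferroni control over the tested
family, thresholded edge selection, and edge-class accounting
(coding-coding / coding-lncRNA / lncRNA-lncRNA).

The all-pairs computation runs blockwise over rows of the gene × gene
correlation matrix so memory stays bounded for thousands of genes; results
are identical for any block size.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError
from .io import GeneCatalog

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("coding-coding", "coding-lncRNA", "lncRNA-lncRNA")


def _standardize(values: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm, so Z @ Z.T is the correlation matrix.

    Returns (Z, zero_variance_mask).  Spearman = Pearson on average ranks.
    """
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    elif method != "pearson":
        raise DomainError(f"unknown correlation method {method!r}")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return centered / safe[:, None], zero


def pairwise_correlation(mat: pd.DataFrame, method: str = "pearson") -> tuple[pd.DataFrame, int]:
    """Full symmetric gene × gene correlation matrix and the sample count.

    Zero-variance genes get NaN correlations (their pairs are excluded from
    testing downstream, with a logged count).
    """
    n = mat.shape[1]
    if n <= 3:
        raise DomainError("correlation testing needs more than 3 samples")
    Z, zero = _standardize(mat.to_numpy(float), method)
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    if zero.any():
        logger.warning("%d zero-variance gene(s): correlations undefined", int(zero.sum()))
        R[zero, :] = np.nan
        R[:, zero] = np.nan
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=mat.index, columns=mat.index), n


def fisher_correlation_pvalue(r, n):
    """Two-sided p for H0: ρ=0 via Fisher's z transform.

    z = atanh(r), se = 1/√(n−3), p = 2·Φ(−|z|·√(n−3)).  |r| = 1 returns an
    exact 0.  Accepts scalars or arrays.
    """
    r_arr = np.asarray(r, float)
    n_arr = np.asarray(n, float)
    if np.any(n_arr <= 3):
        raise DomainError("Fisher's z test needs n > 3")
    if np.any(np.abs(r_arr) > 1):
        raise DomainError("correlation outside [-1, 1]")
    exact = np.abs(r_arr) >= 1.0
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.where(exact, 0.0, r_arr))
    p = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n_arr - 3.0))
    p = np.where(exact, 0.0, p)
    return float(p) if np.isscalar(r) and np.isscalar(n) else p


def _edge_class(bt_a: str, bt_b: str) -> str:
    if bt_a == bt_b:
        return f"{bt_a}-{bt_b}" if bt_a == "coding" else "lncRNA-lncRNA"
    return "coding-lncRNA"


def build_network(
    mat: pd.DataFrame,
    catalog: GeneCatalog,
    method: str = "pearson",
    alpha: float = 0.01,
    correction: str = "bonferroni",
    genes: list[str] | None = None,
    block_size: int = 1024,
) -> nx.Graph:
    """Build the significant-correlation network among ``genes``.

    Tests every unordered pair of non-degenerate genes; the Bonferroni
    denominator m is the number of pairs actually tested.  Edges are kept
    when the adjusted (or raw, with ``correction="none"``) p is strictly
    below ``alpha``.  Nodes appear only when incident to a kept edge and
    carry their catalog biotype; the graph's ``graph`` dict records the
    summary bookkeeping.
    """
    if genes is not None:
        missing = [g for g in genes if g not in mat.index]
        if missing:
            raise DomainError(f"genes absent from matrix: {missing[:5]}")
        mat = mat.loc[list(genes)]
    uncatalogued = [g for g in mat.index if g not in catalog.biotype]
    if uncatalogued:
        raise DomainError(f"matrix genes absent from catalog: {uncatalogued[:5]}")
    if mat.shape[0] < 2:
        raise DomainError("network construction needs at least 2 genes")
    if correction not in ("bonferroni", "none"):
        raise DomainError(f"unknown correction {correction!r}")
    n = mat.shape[1]
    if n <= 3:
        raise DomainError("correlation testing needs more than 3 samples")

    Z, zero = _standardize(mat.to_numpy(float), method)
    if zero.any():
        logger.warning(
            "%d zero-variance gene(s) excluded from pair testing", int(zero.sum())
        )
    valid = np.where(~zero)[0]
    ids = mat.index.to_numpy()
    g_valid = len(valid)
    m_tested = g_valid * (g_valid - 1) // 2
    mult = float(m_tested) if correction == "bonferroni" else 1.0

    graph = nx.Graph()
    Zv = Z[valid]
    sqrt_nm3 = np.sqrt(n - 3.0)
    for start in range(0, g_valid, block_size):
        stop = min(start + block_size, g_valid)
        block = np.clip(Zv[start:stop] @ Zv.T, -1.0, 1.0)
        # keep strictly-upper-triangle pairs (global indices)
        gi = np.repeat(np.arange(start, stop), g_valid)
        cols = np.tile(np.arange(g_valid), stop - start)
        rvals = block.ravel()
        keep = cols > gi
        gi, cols, rvals = gi[keep], cols[keep], rvals[keep]
        exact = np.abs(rvals) >= 1.0
        with np.errstate(divide="ignore"):
            zstat = np.abs(np.arctanh(np.where(exact, 0.0, rvals))) * sqrt_nm3
        p_raw = np.where(exact, 0.0, 2.0 * stats.norm.sf(zstat))
        p_adj = np.minimum(p_raw * mult, 1.0)
        sig = p_adj < alpha
        for a_i, b_i, r, pr, pa in zip(gi[sig], cols[sig], rvals[sig], p_raw[sig], p_adj[sig]):
            a, b = ids[valid[a_i]], ids[valid[b_i]]
            graph.add_edge(
                a,
                b,
                r=float(r),
                n=int(n),
                p_raw=float(pr),
                p_adj=float(pa),
                edge_class=_edge_class(catalog.biotype_of(a), catalog.biotype_of(b)),
            )
    for node in graph.nodes:
        graph.nodes[node]["biotype"] = catalog.biotype_of(node)
    graph.graph.update(
        n_samples=n,
        m_tested=m_tested,
        method=method,
        alpha=alpha,
        correction=correction,
        n_zero_variance=int(zero.sum()),
    )
    return graph


def network_summary(network: nx.Graph) -> dict:
    """Node counts by biotype and edge counts by class; totals consistent."""
    nodes = {"coding": 0, "lncRNA": 0}
    for _, bt in network.nodes(data="biotype"):
        nodes[bt] += 1
    edges = {cls: 0 for cls in EDGE_CLASSES}
    for _, _, cls in network.edges(data="edge_class"):
        edges[cls] += 1
    return {
        "nodes": nodes,
        "n_nodes": network.number_of_nodes(),
        "edges": edges,
        "n_edges": network.number_of_edges(),
    }
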