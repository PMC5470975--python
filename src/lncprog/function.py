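"""Guilt-by-association function prediction for lncRNAs.

Two routes over the co-expression network, mirroring the classic
coding/non-coding annotation strategy:

* module-based — Markov clustering (MCL) partitions the network; each
  lncRNA inherits the term enrichments of the protein-coding genes in its
  module;
* hub-based — each lncRNA is the center of a star of its directly connected
  protein-coding neighbors, which are enriched the same way.

Enrichment is the upper-tail hypergeometric test against the coding genes of
the network (configurable background); following the screening convention,
raw p < 0.01 terms are kept by default, with BH available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, DomainError
from .io import GeneCatalog
from .screen import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


@dataclass
class ModulePartition:
    """Disjoint MCL modules covering every network node exactly once."""

    modules: dict[str, set[str]]
    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assignment:
            self.assignment = {
                node: mid for mid, members in self.modules.items() for node in members
            }
        covered = [n for members in self.modules.values() for n in members]
        if len(covered) != len(set(covered)):
            raise DomainError("MCL modules overlap")
        if any(not members for members in self.modules.values()):
            raise DomainError("empty MCL module")

    def module_of(self, node: str) -> str:
        return self.assignment[node]

    def to_frame(self, network: nx.Graph | None = None) -> pd.DataFrame:
        rows = [
            {
                "gene_id": node,
                "module_id": mid,
                "biotype": network.nodes[node].get("biotype") if network else None,
            }
            for node, mid in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def mcl_cluster(
    network: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    weighted: bool = False,
) -> ModulePartition:
    """Canonical MCL on the (by default unweighted) adjacency matrix.

    Self-loops are added, columns normalised, then expansion (matrix power)
    and inflation (entrywise power + renormalisation) alternate, pruning
    entries below ``prune_threshold``, until the matrix is stable within
    ``tol``.  Clusters are read off the attractor rows; a node attracted by
    several clusters is assigned deterministically to the largest one, then
    to the lexicographically smallest module id.  Nodes left unattracted
    (isolated by pruning) become singleton modules.
    """
    if network.number_of_nodes() == 0:
        raise DomainError("MCL on an empty network")
    nodes = sorted(network.nodes)
    size = len(nodes)
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight" if weighted else None)
    if weighted:
        A = np.abs(
            nx.to_numpy_array(network, nodelist=nodes, weight="r")
        )
    np.fill_diagonal(A, A.diagonal() + 1.0)
    M = A / A.sum(axis=0)
    converged = False
    for iteration in range(1, max_iter + 1):
        expanded = np.linalg.matrix_power(M, expansion)
        inflated = expanded**inflation
        inflated[inflated < prune_threshold] = 0.0
        colsum = inflated.sum(axis=0)
        dead = colsum == 0
        if dead.any():  # pruning can empty a column; restore its self-loop
            inflated[dead, dead] = 1.0
            colsum = inflated.sum(axis=0)
        inflated /= colsum
        diff = float(np.max(np.abs(inflated - M)))
        M = inflated
        if diff < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"MCL did not converge in {max_iter} iterations",
            iterations=max_iter,
            last_diff=diff,
        )

    attractors = [i for i in range(size) if M[i, i] > 0]
    # attractors appearing in each other's rows belong to one cluster
    parent = list(range(size))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    attractor_set = set(attractors)
    for i in attractors:
        for j in np.nonzero(M[i])[0]:
            if j in attractor_set:
                union(i, int(j))
    raw: dict[int, set[int]] = {}
    for i in attractors:
        raw.setdefault(find(i), set()).update(np.nonzero(M[i])[0].tolist())

    # deterministic module ids: ordered by smallest member node label
    ordered = sorted(raw.values(), key=lambda mem: min(nodes[i] for i in mem))
    ids = [f"M{k + 1:03d}" for k in range(len(ordered))]
    assignment: dict[str, str] = {}
    claimed: dict[int, list[tuple[int, str]]] = {}
    for mid, members in zip(ids, ordered):
        for i in members:
            claimed.setdefault(i, []).append((len(members), mid))
    for i, claims in claimed.items():
        # overlap tie-break: largest module, then smallest module id
        claims.sort(key=lambda c: (-c[0], c[1]))
        assignment[nodes[i]] = claims[0][1]
    next_id = len(ordered)
    for i in range(size):
        if nodes[i] not in assignment:
            next_id += 1
            assignment[nodes[i]] = f"M{next_id:03d}"
    modules: dict[str, set[str]] = {}
    for node, mid in assignment.items():
        modules.setdefault(mid, set()).add(node)
    return ModulePartition(modules=modules, assignment=assignment)


# ---------------------------------------------------------------------------
# hub subnetworks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HubSubnetwork:
    """A central lncRNA with its directly connected protein-coding neighbors."""

    center: str
    neighbors: frozenset[str]


def hub_subnetworks(network: nx.Graph) -> list[HubSubnetwork]:
    """One hub per lncRNA node with at least one coding neighbor."""
    hubs = []
    skipped = 0
    for node in sorted(network.nodes):
        if network.nodes[node].get("biotype") != "lncRNA":
            continue
        coding = frozenset(
            nb for nb in network.neighbors(node) if network.nodes[nb].get("biotype") == "coding"
        )
        if coding:
            hubs.append(HubSubnetwork(center=node, neighbors=coding))
        else:
            skipped += 1
    if skipped:
        logger.info("%d lncRNA(s) without coding neighbors omitted from hubs", skipped)
    return hubs


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    query,
    catalog: GeneCatalog,
    background,
    threshold: float = 0.01,
    correction: str = "none",
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment of a coding-gene query.

    For each term with K members in the N-gene background and k hits in the
    n_q-gene query: p = P(X ≥ k), X ~ Hypergeom(N, K, n_q).  Only coding
    genes participate; the query is filtered accordingly.  Rows come back
    sorted ascending by p with a ``kept`` flag (p < threshold, raw by
    default; ``correction="bh"`` flags on BH-adjusted p instead).
    """
    if not catalog.terms:
        raise DomainError("catalog carries no term sets; enrichment refuses to run")
    background = set(background) & catalog.coding_genes
    query = set(query) & background
    if not query:
        logger.warning("empty coding query after filtering; no enrichment computed")
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "n_query", "K", "N", "p", "kept"]
        )
    N, n_q = len(background), len(query)
    rows = []
    for term in sorted(catalog.terms):
        members = catalog.terms[term] & background
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_q)) if K else 1.0
        rows.append((term, catalog.term_names.get(term, term), k, n_q, K, N, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n_query", "K", "N", "p"]
    )
    if correction == "bh":
        table["kept"] = bh_adjust(table["p"].to_numpy()) < threshold
    elif correction == "none":
        table["kept"] = table["p"] < threshold
    else:
        raise DomainError(f"unknown enrichment correction {correction!r}")
    return table.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


def annotate_lncrnas(
    partition: ModulePartition,
    hubs: list[HubSubnetwork],
    catalog: GeneCatalog,
    network: nx.Graph,
    threshold: float = 0.01,
    background=None,
) -> dict[str, dict]:
    """Ranked kept terms per lncRNA via the module and hub routes.

    The two lists are reported separately with their overlap summarised, so
    agreement between routes (the usual sanity check for guilt-by-association
    calls) is immediate.
    """
    if background is None:
        background = {
            n for n, bt in network.nodes(data="biotype") if bt == "coding"
        }
    module_terms: dict[str, list[str]] = {}
    annotations: dict[str, dict] = {}
    hub_by_center = {h.center: h for h in hubs}
    lncrnas = sorted(
        n for n, bt in network.nodes(data="biotype") if bt == "lncRNA"
    )
    for lnc in lncrnas:
        mid = partition.module_of(lnc)
        if mid not in module_terms:
            coding = {g for g in partition.modules[mid] if g in catalog.coding_genes}
            if coding and catalog.terms:
                table = hypergeometric_enrichment(coding, catalog, background, threshold)
                module_terms[mid] = table.loc[table["kept"], "term_id"].tolist()
            else:
                module_terms[mid] = []
        hub_list: list[str] = []
        if lnc in hub_by_center and catalog.terms:
            table = hypergeometric_enrichment(
                hub_by_center[lnc].neighbors, catalog, background, threshold
            )
            hub_list = table.loc[table["kept"], "term_id"].tolist()
        mod_list = module_terms[mid]
        annotations[lnc] = {
            "module_id": mid,
            "module_terms": mod_list,
            "hub_terms": hub_list,
            "shared_terms": [t for t in mod_list if t in set(hub_list)],
        }
    return annotations


def correlate_candidates(
    mat: pd.DataFrame, lnc_gene: str, coding_genes, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation of one lncRNA against named coding genes, with Fisher p."""
    from .network import _standardize, fisher_correlation_pvalue

    coding_genes = list(coding_genes)
    missing = [g for g in [lnc_gene, *coding_genes] if g not in mat.index]
    if missing:
        raise DomainError(f"genes absent from matrix: {missing}")
    sub = mat.loc[[lnc_gene, *coding_genes]]
    Z, zero = _standardize(sub.to_numpy(float), method)
    if zero[0]:
        raise DomainError(f"{lnc_gene} has zero variance")
    r = np.clip(Z[1:] @ Z[0], -1.0, 1.0)
    n = mat.shape[1]
    p = fisher_correlation_pvalue(r, np.full(len(r), n))
    return pd.DataFrame({"r": r, "n": n, "p": p}, index=coding_genes)
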