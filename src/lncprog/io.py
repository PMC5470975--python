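"""Readers and writers for the pipeline's external formats.

Expression matrices, sample sheets, biotype catalogs, GMT gene sets and
network exports are all plain UTF-8, tab-delimited text.  Loaders validate
identifiers and value domains and never silently reorder, rename or impute.

Expression values are assumed to arrive already log2-scaled (the upstream
normalisation is out of scope); no transformation is applied at load.
Survival times are in months throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DomainError, IdentityError, MissingValueError, ParseError

logger = logging.getLogger(__name__)

BIOTYPES = ("coding", "lncRNA")

#: canonical sample-sheet columns beyond the required sample_id/group
OPTIONAL_SHEET_COLUMNS = (
    "subtype",
    "time",
    "event",
    "endpoint",
    "gender",
    "age",
    "ipi",
    "ann_arbor",
    "ecog",
    "ldh_ratio",
    "extranodal",
)

EDGE_COLUMNS = ("gene_a", "gene_b", "r", "n", "p_raw", "p_adj", "edge_class")


@dataclass
class GeneCatalog:
    """Gene → biotype map plus optional GMT-derived term sets.

    Terms are intersected with the catalogued genes at load time; genes that
    appear in a term but not in the catalog are dropped (counted in
    ``dropped_term_genes``).
    """

    biotype: dict[str, str]
    terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)
    dropped_term_genes: int = 0

    def __post_init__(self) -> None:
        bad = {b for b in self.biotype.values()} - set(BIOTYPES)
        if bad:
            raise DomainError(f"unknown biotype token(s): {sorted(bad)}")

    @property
    def coding_genes(self) -> set[str]:
        return {g for g, b in self.biotype.items() if b == "coding"}

    @property
    def lncrna_genes(self) -> set[str]:
        return {g for g, b in self.biotype.items() if b == "lncRNA"}

    def biotype_of(self, gene: str) -> str:
        return self.biotype[gene]


def _check_unique(ids, kind: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise IdentityError(f"duplicate {kind} identifier(s): {sorted(set(dups))}")


def read_expression_matrix(
    path, delimiter: str = "\t", *, impute: bool = False
) -> pd.DataFrame:
    """Load a genes × samples log2 expression matrix.

    First row holds sample ids, first column gene ids.  Duplicate identifiers
    raise :class:`IdentityError`; non-numeric cells raise :class:`ParseError`
    with their coordinates.  Missing values are rejected unless
    ``impute=True``, in which case they are replaced by the row (gene) mean.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "gene")
    _check_unique(list(raw.columns), "sample")
    values = raw.apply(pd.to_numeric, errors="coerce")
    stripped = raw.apply(lambda col: col.astype(str).str.strip())
    bad = values.isna() & raw.notna() & (stripped != "")
    if bad.to_numpy().any():
        g = values.index[bad.any(axis=1)][0]
        s = values.columns[bad.loc[g]][0]
        raise ParseError(f"non-numeric cell at gene={g!r}, sample={s!r}: {raw.loc[g, s]!r}")
    if values.isna().to_numpy().any():
        if not impute:
            n_missing = int(values.isna().to_numpy().sum())
            raise MissingValueError(
                f"{n_missing} missing expression value(s); pass impute=True for row-mean imputation"
            )
        values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
        if values.isna().to_numpy().any():
            raise MissingValueError("gene(s) with all values missing cannot be imputed")
    values = values.astype(float)
    values.index.name = None
    values.columns.name = None
    return values


def write_expression_matrix(mat: pd.DataFrame, path, delimiter: str = "\t") -> None:
    mat.to_csv(path, sep=delimiter, index_label="gene_id")


def read_sample_sheet(path, delimiter: str = "\t") -> pd.DataFrame:
    """Load per-sample annotations (group, subtype, survival, covariates).

    Required columns: ``sample_id``, ``group``.  Missing optional columns are
    added with "unknown" (subtype/endpoint) or NA markers — never fabricated
    values.  Domain checks: time ≥ 0, event ∈ {0, 1}, IPI ∈ [0, 5].
    """
    sheet = pd.read_csv(path, sep=delimiter)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ParseError(f"sample sheet lacks required column {col!r}")
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    _check_unique(list(sheet["sample_id"]), "sample")
    for col in OPTIONAL_SHEET_COLUMNS:
        if col not in sheet.columns:
            sheet[col] = "unknown" if col in ("subtype", "endpoint") else pd.NA
    sheet["subtype"] = sheet["subtype"].fillna("unknown")
    for col in ("time", "event", "age", "ipi"):
        sheet[col] = pd.to_numeric(sheet[col], errors="coerce")
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    time = sheet["time"].dropna()
    if (time < 0).any():
        raise DomainError("negative survival time in sample sheet")
    event = sheet["event"].dropna()
    if not event.isin([0, 1]).all():
        bad = sorted(set(event[~event.isin([0, 1])]))
        raise DomainError(f"event indicator outside {{0,1}}: {bad}")
    ipi = sheet["ipi"].dropna()
    if ((ipi < 0) | (ipi > 5)).any():
        raise DomainError("IPI score outside [0, 5]")
    return sheet.set_index("sample_id", drop=False)


def write_sample_sheet(sheet: pd.DataFrame, path, delimiter: str = "\t") -> None:
    sheet.to_csv(path, sep=delimiter, index=False)


def read_gene_catalog(biotype_path, gmt_path=None, delimiter: str = "\t") -> GeneCatalog:
    """Load the gene → biotype map and, optionally, GMT term sets.

    The biotype vocabulary is strict ({coding, lncRNA}); any other token is a
    :class:`DomainError`.  GMT member genes absent from the catalog are
    dropped with a logged count.
    """
    tab = pd.read_csv(biotype_path, sep=delimiter, dtype=str)
    if not {"gene_id", "biotype"}.issubset(tab.columns):
        raise ParseError("biotype file needs columns gene_id, biotype")
    _check_unique(list(tab["gene_id"]), "gene")
    catalog = GeneCatalog(biotype=dict(zip(tab["gene_id"], tab["biotype"])))
    if gmt_path is not None:
        terms, names = read_gmt(gmt_path)
        known = set(catalog.biotype)
        dropped = 0
        for term, members in terms.items():
            kept = members & known
            dropped += len(members) - len(kept)
            catalog.terms[term] = kept
        catalog.term_names = names
        catalog.dropped_term_genes = dropped
        if dropped:
            logger.warning("dropped %d uncatalogued gene(s) from GMT terms", dropped)
    return catalog


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"GMT line {lineno}: need at least term and description")
            term, desc, *genes = parts
            if term in terms:
                raise IdentityError(f"duplicate term identifier: {term}")
            terms[term] = {g for g in genes if g}
            names[term] = desc
    return terms, names


def write_gmt(terms: dict[str, set[str]], names: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in terms:
            members = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\t{names.get(term, term)}\t{members}\n")


def write_biotype_table(biotype: dict[str, str], path, delimiter: str = "\t") -> None:
    pd.DataFrame({"gene_id": list(biotype), "biotype": list(biotype.values())}).to_csv(
        path, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------


def write_network(network: nx.Graph, path, format: str = "edge_list") -> None:
    """Export a co-expression network.

    ``edge_list`` writes a TSV with ``gene_a < gene_b`` lexicographically and
    full-precision statistics; ``graphml`` keeps biotype as a node attribute
    and r as an edge attribute.
    """
    if format == "graphml":
        nx.write_graphml(network, path)
        return
    if format != "edge_list":
        raise DomainError(f"unknown network format {format!r}")
    rows = []
    for u, v, attrs in network.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append(
            (a, b, repr(float(attrs["r"])), str(int(attrs["n"])),
             repr(float(attrs["p_raw"])), repr(float(attrs["p_adj"])), attrs["edge_class"])
        )
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_network(path, biotype: dict[str, str] | None = None) -> nx.Graph:
    """Re-load an edge-list TSV written by :func:`write_network`."""
    tab = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    graph = nx.Graph()
    for row in tab.itertuples(index=False):
        graph.add_edge(
            row.gene_a,
            row.gene_b,
            r=float(row.r),
            n=int(row.n),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            edge_class=row.edge_class,
        )
    if biotype:
        for node in graph.nodes:
            graph.nodes[node]["biotype"] = biotype[node]
    return graph
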