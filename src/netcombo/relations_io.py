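"""Tabular and graph input/output plus the shared domain vocabulary.

The package's primitive records are drug–gene relations extracted from
the literature: a drug acting on one or more genes in a named cancer
type, optionally qualified by cell line, treatment outcome, and the
source publication. Gene symbols are normalized lexically (trimmed,
internal whitespace collapsed, upper-cased); drug names keep their case
but are trimmed and collapsed the same way. Interactomes are simple
undirected unweighted :class:`networkx.Graph` objects of gene symbols.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, RowValidationError

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_gene(symbol: str) -> str:
    """Trim, collapse internal whitespace runs, and upper-case a gene symbol."""
    return _WS.sub(" ", str(symbol).strip()).upper()


def normalize_drug(name: str) -> str:
    """Trim and collapse whitespace in a drug name, preserving its case."""
    return _WS.sub(" ", str(name).strip())


def normalize_genes(genes: Iterable[str]) -> frozenset[str]:
    """Normalize and deduplicate a collection of gene symbols."""
    out = {normalize_gene(g) for g in genes}
    out.discard("")
    return frozenset(out)


@dataclass(frozen=True)
class RelationRecord:
    """One curated cancer–drug–gene relation.

    ``genes`` holds every gene the source co-mentions with the drug;
    multi-gene relations are what create network edges downstream.
    """

    cancer_type: str
    drug: str
    genes: frozenset[str]
    cell_line: str | None = None
    outcome: str | None = None
    source_id: str | None = None

    def __post_init__(self):
        if not self.cancer_type or not self.drug:
            raise ValueError("cancer_type and drug must be non-empty labels")
        if not self.genes:
            raise ValueError("genes must be non-empty")
        object.__setattr__(self, "genes", normalize_genes(self.genes))
        if not self.genes:
            raise ValueError("genes empty after normalization")


# A drug → target-gene-set mapping. Plain dict keeps the surface simple.
DrugTargetMap = dict[str, frozenset[str]]


@dataclass
class Dialect:
    """Column mapping and cell conventions for relation tables."""

    cancer_type: str = "cancer_type"
    drug: str = "drug"
    genes: str = "genes"
    cell_line: str | None = "cell_line"
    outcome: str | None = "outcome"
    source_id: str | None = "source_id"
    gene_delimiter: str = ";"
    sep: str = "\t"


def _optional(row: Mapping, column: str | None) -> str | None:
    if column is None or column not in row:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    value = str(value).strip()
    return value or None


def read_relations(path: str | Path, dialect: Dialect | None = None) -> list[RelationRecord]:
    """Read a relation table into a list of :class:`RelationRecord`.

    Required columns (per the dialect) are cancer type, drug, and genes;
    multi-gene cells are split on the dialect's delimiter. Row order is
    preserved. A missing required column raises :class:`FormatError`; an
    empty gene cell raises :class:`RowValidationError` with the 1-based
    data row number.
    """
    dialect = dialect or Dialect()
    frame = pd.read_csv(path, sep=dialect.sep, dtype=str)
    for required in (dialect.cancer_type, dialect.drug, dialect.genes):
        if required not in frame.columns:
            raise FormatError(f"{path}: missing required column {required!r}")
    records: list[RelationRecord] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        raw_genes = row[dialect.genes]
        if raw_genes is None or (isinstance(raw_genes, float) and pd.isna(raw_genes)):
            raise RowValidationError("empty genes cell", row=i)
        genes = normalize_genes(str(raw_genes).split(dialect.gene_delimiter))
        if not genes:
            raise RowValidationError("empty genes cell after normalization", row=i)
        cancer = _optional(row, dialect.cancer_type)
        drug = _optional(row, dialect.drug)
        if cancer is None:
            raise RowValidationError("empty cancer_type cell", row=i)
        if drug is None:
            raise RowValidationError("empty drug cell", row=i)
        records.append(
            RelationRecord(
                cancer_type=cancer,
                drug=normalize_drug(drug),
                genes=genes,
                cell_line=_optional(row, dialect.cell_line),
                outcome=_optional(row, dialect.outcome),
                source_id=_optional(row, dialect.source_id),
            )
        )
    return records


def write_relations(records: Iterable[RelationRecord], path: str | Path,
                    dialect: Dialect | None = None) -> None:
    """Write records as a TSV readable back by :func:`read_relations`."""
    dialect = dialect or Dialect()
    rows = []
    for r in records:
        rows.append(
            {
                dialect.cancer_type: r.cancer_type,
                dialect.drug: r.drug,
                dialect.genes: dialect.gene_delimiter.join(sorted(r.genes)),
                dialect.cell_line or "cell_line": r.cell_line,
                dialect.outcome or "outcome": r.outcome,
                dialect.source_id or "source_id": r.source_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a drug→target map from a two-column (drug, gene) TSV.

    A ``gene`` cell may itself hold a ';'-separated list. Repeated drug
    rows union their targets; drug labels that differ only by case are
    merged (with a warning) under the first spelling seen.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (drug, gene)")
    drug_col, gene_col = frame.columns[:2]
    mapping: dict[str, set[str]] = {}
    canonical: dict[str, str] = {}  # casefolded -> first spelling
    if frame.empty:
        logger.warning("drug-target file %s is empty", path)
        return {}
    for i, row in enumerate(frame.to_dict("records"), start=1):
        drug_raw, gene_raw = row[drug_col], row[gene_col]
        if _optional(row, drug_col) is None or _optional(row, gene_col) is None:
            raise RowValidationError("empty drug or gene cell", row=i)
        drug = normalize_drug(drug_raw)
        key = drug.casefold()
        if key in canonical and canonical[key] != drug:
            logger.warning(
                "drug labels %r and %r differ only by case; merged under %r",
                drug, canonical[key], canonical[key],
            )
        drug = canonical.setdefault(key, drug)
        genes = normalize_genes(str(gene_raw).split(";"))
        mapping.setdefault(drug, set()).update(genes)
    return {d: frozenset(g) for d, g in mapping.items()}


def merge_drug_targets(*maps: DrugTargetMap) -> DrugTargetMap:
    """Union several drug→target maps (e.g. curated plus database-derived)."""
    out: dict[str, set[str]] = {}
    for m in maps:
        for drug, genes in m.items():
            out.setdefault(drug, set()).update(genes)
    return {d: frozenset(g) for d, g in out.items()}


def write_drug_targets(targets: DrugTargetMap, path: str | Path) -> None:
    rows = [
        {"drug": drug, "gene": gene}
        for drug in sorted(targets)
        for gene in sorted(targets[drug])
    ]
    pd.DataFrame(rows, columns=["drug", "gene"]).to_csv(path, sep="\t", index=False)


_GRAPH_FORMATS = ("edgelist", "gml", "graphml")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _GRAPH_FORMATS:
            raise FormatError(f"unknown graph format {format!r}; use one of {_GRAPH_FORMATS}")
        return format
    suffix = path.suffix.lower()
    if suffix == ".gml":
        return "gml"
    if suffix == ".graphml":
        return "graphml"
    return "edgelist"


def read_interactome(path: str | Path, format: str | None = None,
                     name: str | None = None) -> nx.Graph:
    """Read an interactome as a simple undirected graph.

    Formats: 2-column edge-list TSV (default for .tsv/.txt), GML, or
    GraphML; the format is inferred from the extension unless given.
    Self-loops and duplicate edges are dropped with counts logged.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gml":
        raw = nx.read_gml(path)
    elif fmt == "graphml":
        raw = nx.read_graphml(path)
    else:
        raw = nx.MultiGraph()
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
                raw.add_edge(normalize_gene(parts[0]), normalize_gene(parts[1]))
    graph = nx.Graph()
    graph.add_nodes_from(raw.nodes())
    loops = dupes = 0
    for u, v in raw.edges():
        if u == v:
            loops += 1
        elif graph.has_edge(u, v):
            dupes += 1
        else:
            graph.add_edge(u, v)
    if loops or dupes:
        logger.info("%s: dropped %d self-loops and %d duplicate edges", path, loops, dupes)
    graph.graph["name"] = name or path.stem
    return graph


def write_interactome(net: nx.Graph, path: str | Path, format: str | None = None) -> None:
    """Write a graph in edge-list TSV, GML, or GraphML."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gml":
        nx.write_gml(net, path)
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        with open(path, "w", encoding="utf-8") as handle:
            for u, v in sorted(map(sorted, net.edges())):
                handle.write(f"{u}\t{v}\n")
            for node in sorted(nx.isolates(net)):
                # edge lists cannot express isolated nodes; emit a self-loop-free
                # marker line is not possible, so they are simply omitted
                logger.warning("node %r is isolated and omitted from edge list", node)
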