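"""Cancer-specific co-occurrence network construction.

Genes co-mentioned in the same source form a clique: every pair of
genes reported together in one publication (for the cancer type at
hand) receives an edge. Self-loops never arise from distinct genes and
isolated nodes — genes reported alone — are pruned, so a single-gene
record contributes nothing to the final network.

The literature network can then be composed with a large background
protein–protein interactome, either by intersecting edges with it or by
augmenting with background edges among the co-occurring genes.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable

import networkx as nx

from .relations_io import RelationRecord

logger = logging.getLogger(__name__)

#: records with at least this many genes trigger a clique-explosion warning
LARGE_RECORD_THRESHOLD = 50


def _default_group_key(record: RelationRecord) -> object:
    # group co-mentions per source publication; records lacking a
    # source id stand alone (object identity keeps them distinct)
    return record.source_id if record.source_id is not None else id(record)


def build_cancer_network(
    records: Iterable[RelationRecord],
    cancer_type: str,
    group_key: Callable[[RelationRecord], object] | None = None,
    large_record_threshold: int = LARGE_RECORD_THRESHOLD,
) -> nx.Graph:
    """Build the co-occurrence network for one cancer type.

    Records are grouped by source (``group_key``, default: the record's
    ``source_id``, each anonymous record its own group); the union of
    each group's genes becomes a clique. Isolated nodes are deleted, so
    the result contains only genes with at least one co-mention partner.
    An unknown cancer type yields an empty network with a warning.
    """
    key = group_key or _default_group_key
    groups: dict[object, set[str]] = {}
    n_matched = 0
    for record in records:
        if record.cancer_type != cancer_type:
            continue
        n_matched += 1
        groups.setdefault(key(record), set()).update(record.genes)
    if n_matched == 0:
        logger.warning("no relation records for cancer type %r; empty network", cancer_type)
    graph = nx.Graph(name=cancer_type)
    for genes in groups.values():
        if len(genes) >= large_record_threshold:
            logger.warning(
                "source group with %d genes (>= %d) adds a %d-edge clique; "
                "check for upstream parse errors",
                len(genes), large_record_threshold, len(genes) * (len(genes) - 1) // 2,
            )
        members = sorted(genes)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                graph.add_edge(u, v)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def restrict_to_background(net: nx.Graph, background: nx.Graph,
                           mode: str = "augment") -> nx.Graph:
    """Compose a co-occurrence network with a background interactome.

    mode="intersect" keeps only co-occurrence edges also present in the
    background; mode="augment" (default) additionally wires in every
    background edge between genes already in the co-occurrence network,
    supplying the connectivity shortest-path measures need. Isolated
    nodes are re-pruned either way.
    """
    if mode not in ("intersect", "augment"):
        raise ValueError(f"unknown mode {mode!r}; use 'intersect' or 'augment'")
    out = nx.Graph(name=net.graph.get("name"))
    if mode == "intersect":
        out.add_edges_from(e for e in net.edges() if background.has_edge(*e))
    else:
        out.add_edges_from(net.edges())
        nodes = set(net.nodes())
        out.add_edges_from(
            (u, v) for u, v in background.edges()
            if u in nodes and v in nodes and u != v
        )
    out.remove_edges_from(nx.selfloop_edges(out))
    out.remove_nodes_from(list(nx.isolates(out)))
    if out.number_of_nodes() == 0:
        logger.info("composition with background in mode %r produced an empty network", mode)
    return out
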