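"""Betweenness-centrality gene prioritization and cross-cancer hot genes.

Betweenness centrality — the fraction of all shortest paths passing
through a node — flags genes that broker communication in a
cancer-specific network. The top fraction of nodes by rank (default
60%) are that cancer's "important genes"; genes whose important status
recurs across more than a threshold number of cancer types (default
more than 10) are "hot cancer genes".
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Mapping

import networkx as nx


def betweenness_ranking(net: nx.Graph) -> list[tuple[str, float]]:
    """Exact normalized betweenness for every node, sorted descending.

    Ties are broken by gene label so the ranking is deterministic.
    An empty graph yields an empty list.
    """
    if net.number_of_nodes() == 0:
        return []
    scores = nx.betweenness_centrality(net, normalized=True)
    return sorted(scores.items(), key=lambda item: (-item[1], item[0]))


def important_genes(net: nx.Graph, top_fraction: float = 0.6) -> frozenset[str]:
    """The ceil(top_fraction * |V|) highest-betweenness genes."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    ranking = betweenness_ranking(net)
    k = math.ceil(top_fraction * len(ranking))
    return frozenset(gene for gene, _ in ranking[:k])


def hot_genes(important_sets: Mapping[str, frozenset[str] | set[str]],
              min_cancers: int = 10,
              strict: bool = True) -> tuple[frozenset[str], dict[str, int]]:
    """Genes recurring across many cancers' important-gene sets.

    Returns (hot set, per-gene frequency over all input sets). With
    ``strict`` (default) a gene must appear in *more than* min_cancers
    sets; ``strict=False`` relaxes to at least min_cancers.
    """
    if not important_sets:
        raise ValueError("at least one important-gene set is required")
    frequency: Counter[str] = Counter()
    for genes in important_sets.values():
        frequency.update(set(genes))
    if strict:
        hot = frozenset(g for g, n in frequency.items() if n > min_cancers)
    else:
        hot = frozenset(g for g, n in frequency.items() if n >= min_cancers)
    return hot, dict(frequency)
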