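"""Synthetic fixtures with planted structure.

Real cancer-specific networks come from curated literature and
interactome databases that cannot be redistributed; these generators
produce stand-ins whose ground truth is known by construction, so every
pipeline stage can be exercised end to end. A planted-partition
(stochastic block model) graph emulates a cancer network with community
structure; drug target sets are placed inside or across blocks to give
drug pairs known expected labels under the combination rule; and
random relation tables emulate curated literature extractions.

Drugs assigned to the same block additionally share a core subset of
targets (pathway neighbors in real pharmacology often coincide), which
is what drives their separation score negative: shared targets
contribute zero-length cross-distances while within-module distances in
a dense block stay near one hop.

A single seed propagates through :class:`numpy.random.SeedSequence`
spawning, so each generator draws from an independent, reproducible
stream.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .relations_io import DrugTargetMap, RelationRecord

logger = logging.getLogger(__name__)

OVERLAP_MODES = ("same-block", "cross-block", "mixed")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def planted_partition_graph(
    blocks: int, block_size: int, p_in: float, p_out: float, seed: int,
) -> tuple[nx.Graph, dict[str, int]]:
    """Stochastic block model graph with gene-style node names.

    Every intra-block pair is edged independently with probability
    p_in, every inter-block pair with p_out (0 <= p_out < p_in <= 1).
    Returns the graph and the planted node→block labels; nodes left
    isolated by the draw are pruned (and logged) to respect the
    interactome invariant.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if blocks < 1 or block_size < 1:
        raise ValueError("blocks and block_size must be positive")
    raw = nx.planted_partition_graph(blocks, block_size, p_in, p_out, seed=int(seed))
    rename = {i: f"G{i:04d}" for i in raw.nodes()}
    graph = nx.Graph()
    graph.add_nodes_from(rename.values())
    graph.add_edges_from((rename[u], rename[v]) for u, v in raw.edges())
    graph.graph["name"] = f"planted_b{blocks}x{block_size}"
    labels = {rename[i]: raw.nodes[i]["block"] for i in raw.nodes()}
    isolated = list(nx.isolates(graph))
    if isolated:
        logger.info("pruned %d isolated node(s) from planted graph", len(isolated))
        graph.remove_nodes_from(isolated)
        for node in isolated:
            labels.pop(node)
    return graph, labels


def synth_drug_targets(
    graph: nx.Graph,
    labels: dict[str, int],
    n_drugs: int = 4,
    targets_per_drug: int = 12,
    overlap_mode: str = "mixed",
    seed: int = 0,
    shared_fraction: float = 1 / 3,
) -> tuple[DrugTargetMap, pd.DataFrame]:
    """Drug target sets with controlled block placement.

    overlap_mode="same-block" puts every drug in block 0 (all pairs
    expected combinations), "cross-block" puts each drug in its own
    block (no pair expected), and "mixed" (default) assigns drugs to
    blocks in consecutive pairs, yielding both kinds. Same-block drugs
    share ``shared_fraction`` of their targets. Returns the target map
    and an expected-label table with one row per unordered pair
    (columns drug_a, drug_b, expected).
    """
    if overlap_mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}; use one of {OVERLAP_MODES}")
    if n_drugs < 1:
        raise ValueError("n_drugs must be positive")
    rng = np.random.default_rng(seed)
    n_blocks = max(labels.values()) + 1
    if overlap_mode == "same-block":
        assignment = {i: 0 for i in range(n_drugs)}
    elif overlap_mode == "cross-block":
        if n_drugs > n_blocks:
            raise ValueError(
                f"cross-block mode needs one block per drug ({n_drugs} > {n_blocks})"
            )
        assignment = {i: i for i in range(n_drugs)}
    else:
        assignment = {i: (i // 2) % n_blocks for i in range(n_drugs)}
    by_block: dict[int, list[int]] = {}
    for drug_idx, block in assignment.items():
        by_block.setdefault(block, []).append(drug_idx)

    core_size = max(1, round(shared_fraction * targets_per_drug))
    targets: dict[str, frozenset[str]] = {}
    for block, drug_indices in sorted(by_block.items()):
        pool = sorted(node for node, b in labels.items() if b == block)
        private_size = targets_per_drug - core_size
        need = core_size + private_size * len(drug_indices)
        if targets_per_drug > len(pool) or need > len(pool):
            raise ValueError(
                f"block {block} has {len(pool)} nodes; cannot place "
                f"{len(drug_indices)} drug(s) x {targets_per_drug} targets "
                f"with a shared core of {core_size}"
            )
        shuffled = list(rng.permutation(pool))
        core, rest = shuffled[:core_size], shuffled[core_size:]
        for j, drug_idx in enumerate(sorted(drug_indices)):
            private = rest[j * private_size:(j + 1) * private_size]
            targets[f"D{drug_idx + 1:02d}"] = frozenset(core) | frozenset(private)

    rows = []
    names = sorted(targets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ia, ib = int(a[1:]) - 1, int(b[1:]) - 1
            rows.append({"drug_a": a, "drug_b": b,
                         "expected": assignment[ia] == assignment[ib]})
    expected = pd.DataFrame(rows, columns=["drug_a", "drug_b", "expected"])
    return targets, expected


def synth_relations(
    cancers: int = 2,
    records_per_cancer: int = 50,
    genes_pool: int = 120,
    genes_per_record: int | tuple[int, int] = (2, 6),
    n_drugs: int = 8,
    seed: int = 0,
) -> list[RelationRecord]:
    """Random curated-literature-style relation records.

    ``genes_per_record`` is either a fixed count or an inclusive
    (low, high) range sampled uniformly per record. Defaults emulate a
    small curation effort: a few genes co-mentioned per abstract, a
    modest drug vocabulary, distinct source ids per record.
    """
    if cancers < 1 or records_per_cancer < 1 or genes_pool < 1:
        raise ValueError("cancers, records_per_cancer, and genes_pool must be positive")
    rng = np.random.default_rng(seed)
    pool = [f"G{i:04d}" for i in range(genes_pool)]
    drugs = [f"D{i + 1:02d}" for i in range(n_drugs)]
    records = []
    source = 0
    for c in range(cancers):
        cancer = f"CANCER{c + 1:02d}"
        for _ in range(records_per_cancer):
            source += 1
            if isinstance(genes_per_record, int):
                k = genes_per_record
            else:
                low, high = genes_per_record
                k = int(rng.integers(low, high + 1))
            k = min(k, genes_pool)
            genes = rng.choice(pool, size=k, replace=False)
            records.append(
                RelationRecord(
                    cancer_type=cancer,
                    drug=str(rng.choice(drugs)),
                    genes=frozenset(genes),
                    source_id=f"SRC{source:06d}",
                )
            )
    return records
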