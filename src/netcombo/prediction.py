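"""Community-hit criterion and the drug-combination decision rule.

A drug X "hits" a community C_j of the cancer-specific network when
enough of its targets fall inside it:

    |C_j ∩ T_X| >= min(alpha, beta * |C_j|)    with |C_j| >= gamma

alpha is an absolute target count, beta scales with community size (the
product is compared as a real number, no rounding), and gamma screens
out tiny communities that would produce false-positive hits. A drug
pair is called a combination when its target modules overlap
topologically (s_AB < 0) AND the two drugs hit at least one community
in common. s_AB = 0 is "no interaction" (strict inequality).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx

from .community import CommunityPartition
from .errors import TargetsAbsentError
from .proximity import SeparationResult, separation
from .relations_io import DrugTargetMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitParameters:
    """Thresholds of the community-hit rule (defaults alpha=10, beta=0.15, gamma=10).

    ``strict_size`` switches the community-size gate from |C_j| >= gamma
    to a strict |C_j| > gamma.
    """

    alpha: int = 10
    beta: float = 0.15
    gamma: int = 10
    strict_size: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be a positive integer")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie strictly between 0 and 1")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")


@dataclass(frozen=True)
class PredictionRecord:
    """Decision for one drug pair on one cancer network."""

    drug_a: str
    drug_b: str
    s_ab: float
    overlap: int
    predicted: bool
    cancer_type: str = ""

    def __post_init__(self):
        if self.overlap < 0:
            raise ValueError("overlap must be non-negative")
        if self.predicted != (self.s_ab < 0 and self.overlap >= 1):
            raise ValueError("predicted inconsistent with (s_ab < 0 and overlap >= 1)")


def hit_communities(partition: CommunityPartition, targets: set[str] | frozenset[str],
                    params: HitParameters | None = None) -> set[int]:
    """Community ids hit by a drug's target set under the hit rule."""
    params = params or HitParameters()
    if not targets:
        raise ValueError("targets must be non-empty")
    hits: set[int] = set()
    for cid, members in partition.communities.items():
        size = len(members)
        size_ok = size > params.gamma if params.strict_size else size >= params.gamma
        if not size_ok:
            continue
        inside = len(members & targets)
        if inside >= min(params.alpha, params.beta * size):
            hits.add(cid)
    return hits


def predict_pair(sep: SeparationResult, hits_a: set[int], hits_b: set[int],
                 drug_a: str = "drug_a", drug_b: str = "drug_b",
                 cancer_type: str = "") -> PredictionRecord:
    """Classify one drug pair from its separation and community hits."""
    overlap = len(hits_a & hits_b)
    return PredictionRecord(
        drug_a=drug_a,
        drug_b=drug_b,
        s_ab=sep.s_ab,
        overlap=overlap,
        predicted=bool(sep.s_ab < 0 and overlap >= 1),
        cancer_type=cancer_type,
    )


def predict_all(net: nx.Graph, partition: CommunityPartition, targets: DrugTargetMap,
                params: HitParameters | None = None,
                pairs: list[tuple[str, str]] | None = None,
                cancer_type: str | None = None) -> list[PredictionRecord]:
    """Score and classify every (or each supplied) unordered drug pair.

    Drugs with no in-network targets are skipped with a warning tally;
    output is sorted by (cancer_type, drug_a, drug_b) with each pair's
    drugs in lexicographic order.
    """
    params = params or HitParameters()
    cancer = cancer_type if cancer_type is not None else net.graph.get("name", "")
    usable: dict[str, set[str]] = {}
    skipped: list[str] = []
    for drug, tset in targets.items():
        present = {t for t in tset if t in net}
        if present:
            usable[drug] = present
        else:
            skipped.append(drug)
    if skipped:
        logger.warning("skipped %d drug(s) with no in-network targets: %s",
                       len(skipped), ", ".join(sorted(skipped)))
    if pairs is None:
        if len(usable) < 2:
            raise TargetsAbsentError("fewer than two drugs have in-network targets")
        pair_list = list(itertools.combinations(sorted(usable), 2))
    else:
        pair_list = []
        for a, b in pairs:
            if a in usable and b in usable:
                pair_list.append(tuple(sorted((a, b))))
            else:
                logger.warning("pair (%s, %s) skipped: missing in-network targets", a, b)
    hit_cache = {drug: hit_communities(partition, usable[drug], params) for drug in usable}
    records = []
    for a, b in pair_list:
        sep = separation(net, usable[a], usable[b], drug_a=a, drug_b=b)
        records.append(predict_pair(sep, hit_cache[a], hit_cache[b],
                                    drug_a=a, drug_b=b, cancer_type=cancer))
    records.sort(key=lambda r: (r.cancer_type, r.drug_a, r.drug_b))
    return records
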