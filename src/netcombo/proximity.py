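"""Network separation between two drugs' target modules.

The separation score compares the average network distance between two
target sets with the internal spread of each set:

    s_AB = d_AB - (d_AA + d_BB) / 2

Distances follow the closest-distance convention of network medicine:
each target contributes its shortest-path length to the nearest *other*
member of the relevant set (within-module), or to the nearest member of
the opposite set (cross-module), and contributions are averaged. A
singleton set has within-distance 0 by convention, and shared targets
contribute 0 to d_AB, which is what drives s_AB negative for
topologically overlapping modules. Negative s_AB means the two drugs
act in the same network neighborhood.

An all-pairs averaging mode is available for sensitivity analysis.
Unreachable contributions are excluded under the default "restrict"
reachability policy (with a tally kept on the result); "strict" raises
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .errors import TargetsAbsentError, UnreachableTargetsError

logger = logging.getLogger(__name__)

_MODES = ("closest", "all_pairs")
_POLICIES = ("restrict", "strict")


@dataclass(frozen=True)
class SeparationResult:
    """Separation of two target modules on one network.

    Distances are unweighted hop counts; ``n_a_used``/``n_b_used``
    count targets actually present in the network, and ``n_excluded``
    tallies unreachable contributions dropped under the "restrict"
    reachability policy.
    """

    d_aa: float
    d_bb: float
    d_ab: float
    s_ab: float
    n_a_used: int
    n_b_used: int
    n_excluded: int = 0


def _present(net: nx.Graph, targets: frozenset[str] | set[str], drug: str) -> set[str]:
    present = {t for t in targets if t in net}
    dropped = len(targets) - len(present)
    if dropped:
        logger.warning("%d target(s) of %s absent from the network; dropped", dropped, drug)
    if not present:
        raise TargetsAbsentError(drug)
    return present


def _nearest_mean(net: nx.Graph, sources: set[str], pools: dict[str, set[str]],
                  policy: str) -> tuple[float, int]:
    """Mean over sources of the distance to the nearest node of its pool.

    ``pools`` maps each source to its candidate set (excluding itself
    where relevant). Returns (mean, number of excluded sources).
    """
    contributions: list[float] = []
    excluded = 0
    for source in sorted(sources):
        pool = pools[source]
        if not pool:
            continue  # singleton convention: nothing to contribute
        if source in pool:
            contributions.append(0.0)
            continue
        lengths = nx.single_source_shortest_path_length(net, source)
        best = min((lengths[t] for t in pool if t in lengths), default=None)
        if best is None:
            if policy == "strict":
                raise UnreachableTargetsError(
                    f"target {source!r} cannot reach any counterpart"
                )
            excluded += 1
        else:
            contributions.append(float(best))
    if not contributions:
        return 0.0, excluded
    return sum(contributions) / len(contributions), excluded


def within_distance(net: nx.Graph, targets: set[str] | frozenset[str],
                    drug: str = "drug", mode: str = "closest",
                    policy: str = "restrict") -> float:
    """Mean within-module distance d_XX of one drug's target set.

    Closest-distance convention: each target contributes its distance
    to the nearest other target; a singleton set scores 0.
    """
    _check(mode, policy)
    present = _present(net, targets, drug)
    if len(present) == 1:
        return 0.0
    if mode == "all_pairs":
        return _all_pairs_mean(net, present, present, policy, within=True)
    pools = {t: present - {t} for t in present}
    value, excluded = _nearest_mean(net, present, pools, policy)
    if excluded:
        logger.info("within_distance(%s): %d unreachable target(s) excluded", drug, excluded)
    return value


def cross_distance(net: nx.Graph, targets_a: set[str] | frozenset[str],
                   targets_b: set[str] | frozenset[str],
                   drug_a: str = "drug_a", drug_b: str = "drug_b",
                   mode: str = "closest", policy: str = "restrict") -> float:
    """Mean cross-module distance d_AB between two drugs' target sets.

    Every node of A contributes its distance to the nearest node of B
    and vice versa (|A|+|B| contributions); shared targets contribute 0.
    """
    _check(mode, policy)
    a = _present(net, targets_a, drug_a)
    b = _present(net, targets_b, drug_b)
    if mode == "all_pairs":
        return _all_pairs_mean(net, a, b, policy, within=False)
    contributions: list[float] = []
    excluded = 0
    for source_set, pool in ((a, b), (b, a)):
        for source in sorted(source_set):
            if source in pool:
                contributions.append(0.0)
                continue
            lengths = nx.single_source_shortest_path_length(net, source)
            best = min((lengths[t] for t in pool if t in lengths), default=None)
            if best is None:
                if policy == "strict":
                    raise UnreachableTargetsError(
                        f"target {source!r} cannot reach the opposite module"
                    )
                excluded += 1
            else:
                contributions.append(float(best))
    if excluded:
        logger.info("cross_distance(%s, %s): %d unreachable contribution(s) excluded",
                    drug_a, drug_b, excluded)
    if not contributions:
        return 0.0
    return sum(contributions) / len(contributions)


def _all_pairs_mean(net: nx.Graph, a: set[str], b: set[str], policy: str,
                    within: bool) -> float:
    distances: list[float] = []
    excluded = 0
    for u in sorted(a):
        lengths = nx.single_source_shortest_path_length(net, u)
        for v in sorted(b):
            if within and v <= u:
                continue
            if v in lengths:
                distances.append(float(lengths[v]))
            else:
                if policy == "strict":
                    raise UnreachableTargetsError(f"{u!r} cannot reach {v!r}")
                excluded += 1
    if not distances:
        return 0.0
    return sum(distances) / len(distances)


def separation(net: nx.Graph, targets_a: set[str] | frozenset[str],
               targets_b: set[str] | frozenset[str],
               drug_a: str = "drug_a", drug_b: str = "drug_b",
               mode: str = "closest", policy: str = "restrict") -> SeparationResult:
    """Compute the full separation result for a drug pair.

    s_AB = d_AB - (d_AA + d_BB)/2; symmetric in the two drugs.
    """
    _check(mode, policy)
    a = _present(net, targets_a, drug_a)
    b = _present(net, targets_b, drug_b)
    d_aa = within_distance(net, a, drug_a, mode=mode, policy=policy)
    d_bb = within_distance(net, b, drug_b, mode=mode, policy=policy)
    d_ab = cross_distance(net, a, b, drug_a, drug_b, mode=mode, policy=policy)
    n_excluded = _count_excluded(net, a, b) if policy == "restrict" else 0
    return SeparationResult(
        d_aa=d_aa,
        d_bb=d_bb,
        d_ab=d_ab,
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        n_a_used=len(a),
        n_b_used=len(b),
        n_excluded=n_excluded,
    )


def _count_excluded(net: nx.Graph, a: set[str], b: set[str]) -> int:
    """Tally of unreachable nearest-neighbor contributions across all terms."""
    excluded = 0
    for source_set, pool_of in (
        (a, lambda t: a - {t}),
        (b, lambda t: b - {t}),
        (a, lambda t: b),
        (b, lambda t: a),
    ):
        for t in source_set:
            pool = pool_of(t)
            if not pool or t in pool:
                continue
            lengths = nx.single_source_shortest_path_length(net, t)
            if not any(p in lengths for p in pool):
                excluded += 1
    return excluded


def _check(mode: str, policy: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; use one of {_MODES}")
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; use one of {_POLICIES}")
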