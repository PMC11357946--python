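"""Confusion-matrix evaluation with binomial confidence intervals.

Predictions are compared against experimental ground truth (combination
observed / not observed) to give TP/FP/FN/TN counts, accuracy,
sensitivity, and specificity. Because validation panels are small,
point estimates are fragile; each rate is therefore wrapped in a panel
of binomial proportion confidence intervals computed by five standard
constructions — Clopper–Pearson (a.k.a. exact), Wilson score,
Agresti–Coull, Jeffreys, and the Wald normal approximation — so the
reader sees the full spread of optimistic-to-conservative bounds.
Rates whose denominator is zero are reported as missing, never as 0.

Interval computation is delegated to
:func:`statsmodels.stats.proportion.proportion_confint`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .community import CommunityPartition
from .errors import LookupError_
from .prediction import HitParameters, hit_communities, predict_pair
from .proximity import separation
from .relations_io import DrugTargetMap

#: label → statsmodels method name; "exact" is the conventional alias
#: for Clopper–Pearson
METHODS: dict[str, str] = {
    "exact": "beta",
    "clopper_pearson": "beta",
    "wilson": "wilson",
    "agresti_coull": "agresti_coull",
    "jeffreys": "jeffreys",
    "wald": "normal",
}

#: the default five-method panel
DEFAULT_PANEL: tuple[str, ...] = (
    "exact", "wilson", "agresti_coull", "clopper_pearson", "jeffreys",
)


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FP/FN/TN with derived rates (None where undefined)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None


@dataclass(frozen=True)
class IntervalEstimate:
    """One binomial confidence interval for successes/trials."""

    method: str
    level: float
    successes: int
    trials: int
    lower: float
    upper: float

    @property
    def point(self) -> float:
        return self.successes / self.trials


def confusion(outcomes: Iterable[tuple[bool, bool]]) -> ConfusionSummary:
    """Tally (predicted, truth) pairs into a :class:`ConfusionSummary`."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("cannot evaluate an empty prediction list")
    tp = fp = fn = tn = 0
    for predicted, truth in outcomes:
        if predicted and truth:
            tp += 1
        elif predicted and not truth:
            fp += 1
        elif not predicted and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def binomial_interval(successes: int, trials: int, method: str = "clopper_pearson",
                      level: float = 0.95) -> IntervalEstimate:
    """Confidence interval for a binomial proportion by a named method.

    Boundary cases (successes 0 or trials) collapse one-sidedly to 0/1
    per each method's convention; bounds are clipped to [0, 1].
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if method not in METHODS:
        raise LookupError_(f"unknown interval method {method!r}; known: {sorted(METHODS)}")
    lower, upper = proportion_confint(successes, trials, alpha=1 - level,
                                      method=METHODS[method])
    # one-sided collapse at the boundaries (Brown–Cai–DasGupta convention)
    lower = 0.0 if successes == 0 else max(0.0, float(lower))
    upper = 1.0 if successes == trials else min(1.0, float(upper))
    return IntervalEstimate(
        method=method,
        level=level,
        successes=successes,
        trials=trials,
        lower=lower,
        upper=upper,
    )


def interval_panel(summary: ConfusionSummary, level: float = 0.95,
                   methods: Sequence[str] = DEFAULT_PANEL) -> pd.DataFrame:
    """Interval estimates for accuracy/sensitivity/specificity × methods.

    Returns a tidy frame (metric, method, successes, trials, point,
    lower, upper); metrics with a zero denominator are omitted. Use
    :func:`panel_bounds` for the per-metric min/max envelope.
    """
    rows = []
    metrics = {
        "accuracy": (summary.tp + summary.tn, summary.total),
        "sensitivity": (summary.tp, summary.tp + summary.fn),
        "specificity": (summary.tn, summary.tn + summary.fp),
    }
    for metric, (successes, trials) in metrics.items():
        if trials == 0:
            continue
        for method in methods:
            est = binomial_interval(successes, trials, method=method, level=level)
            rows.append(
                {
                    "metric": metric,
                    "method": method,
                    "successes": successes,
                    "trials": trials,
                    "point": est.point,
                    "lower": est.lower,
                    "upper": est.upper,
                }
            )
    return pd.DataFrame(rows, columns=["metric", "method", "successes", "trials",
                                       "point", "lower", "upper"])


def panel_bounds(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-metric envelope of the interval panel (min/max lower and upper)."""
    grouped = panel.groupby("metric")
    return pd.DataFrame(
        {
            "min_lower": grouped["lower"].min(),
            "max_lower": grouped["lower"].max(),
            "min_upper": grouped["upper"].min(),
            "max_upper": grouped["upper"].max(),
        }
    ).reset_index()


def parameter_sweep(net: nx.Graph, partition: CommunityPartition,
                    targets: DrugTargetMap,
                    truth: Mapping[frozenset[str], bool],
                    alphas: Sequence[int] = (10,),
                    betas: Sequence[float] = (0.15,),
                    gammas: Sequence[int] = (10,)) -> pd.DataFrame:
    """Re-run the hit rule and decision over a grid of (alpha, beta, gamma).

    ``truth`` maps frozenset({drug_a, drug_b}) to the experimental
    outcome. Separations are computed once (they do not depend on the
    hit parameters); each grid point re-derives community hits and the
    decision, then tallies the confusion against the fixed truth.
    """
    pair_keys = sorted(truth, key=lambda k: tuple(sorted(k)))
    pairs = [tuple(sorted(k)) for k in pair_keys]
    seps = {
        (a, b): separation(net, targets[a], targets[b], drug_a=a, drug_b=b)
        for a, b in pairs
    }
    rows = []
    for alpha, beta, gamma in itertools.product(alphas, betas, gammas):
        params = HitParameters(alpha=alpha, beta=beta, gamma=gamma)
        hits = {
            drug: hit_communities(partition, {t for t in targets[drug] if t in net}, params)
            for drug in {d for pair in pairs for d in pair}
        }
        outcomes = []
        for a, b in pairs:
            record = predict_pair(seps[(a, b)], hits[a], hits[b], drug_a=a, drug_b=b)
            outcomes.append((record.predicted, truth[frozenset((a, b))]))
        summary = confusion(outcomes)
        rows.append(
            {
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "tp": summary.tp,
                "fp": summary.fp,
                "fn": summary.fn,
                "tn": summary.tn,
                "accuracy": summary.accuracy,
                "sensitivity": summary.sensitivity,
                "specificity": summary.specificity,
            }
        )
    return pd.DataFrame(rows)
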