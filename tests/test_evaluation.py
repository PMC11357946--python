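import numpy as np
import pytest
from scipy import stats

from netcombo.community import louvain
from netcombo.datasets import load_validation_benchmark
from netcombo.errors import LookupError_
from netcombo.evaluation import (
    DEFAULT_PANEL,
    ConfusionSummary,
    binomial_interval,
    confusion,
    interval_panel,
    panel_bounds,
    parameter_sweep,
)
from netcombo.synthetic import planted_partition_graph, synth_drug_targets


class TestConfusion:
    def test_benchmark_counts_and_rates(self):
        """Tallying the 19 published (prediction, ground-truth) pairs
        gives tp=3 fp=3 fn=1 tn=12 and the published rates."""
        bench = load_validation_benchmark()
        summary = confusion(list(zip(bench.prediction, bench.ground_truth)))
        assert (summary.tp, summary.fp, summary.fn, summary.tn) == (3, 3, 1, 12)
        assert summary.accuracy == pytest.approx(0.789, abs=5e-4)
        assert summary.sensitivity == pytest.approx(0.750, abs=5e-4)
        assert summary.specificity == pytest.approx(0.800, abs=5e-4)

    def test_all_correct(self):
        assert confusion([(True, True), (False, False)]).accuracy == 1.0

    def test_undefined_rates_are_missing_not_zero(self):
        summary = confusion([(False, False)])
        assert summary.sensitivity is None
        assert summary.specificity == 1.0

    def test_counts_sum_to_pairs(self):
        outcomes = [(bool(i % 2), bool(i % 3)) for i in range(17)]
        assert confusion(outcomes).total == 17

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([])


def _oracle(successes, trials, method, level):
    """Independent closed forms via scipy quantiles."""
    alpha = 1 - level
    x, n = successes, trials
    p = x / n
    z = stats.norm.ppf(1 - alpha / 2)
    if method in ("exact", "clopper_pearson"):
        lower = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
        upper = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    elif method == "wilson":
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lower, upper = center - half, center + half
    elif method == "agresti_coull":
        n_adj = n + z**2
        p_adj = (x + z**2 / 2) / n_adj
        half = z * np.sqrt(p_adj * (1 - p_adj) / n_adj)
        lower, upper = p_adj - half, p_adj + half
    elif method == "jeffreys":
        lower = stats.beta.ppf(alpha / 2, x + 0.5, n - x + 0.5)
        upper = stats.beta.ppf(1 - alpha / 2, x + 0.5, n - x + 0.5)
    elif method == "wald":
        half = z * np.sqrt(p * (1 - p) / n)
        lower, upper = p - half, p + half
    lower = 0.0 if x == 0 else max(0.0, lower)
    upper = 1.0 if x == n else min(1.0, upper)
    return lower, upper


class TestBinomialInterval:
    @pytest.mark.parametrize("method", sorted(set(DEFAULT_PANEL) | {"wald"}))
    @pytest.mark.parametrize("x,n", [(0, 7), (1, 7), (3, 4), (15, 19), (12, 15),
                                     (19, 19), (50, 200)])
    def test_matches_independent_closed_forms(self, method, x, n):
        est = binomial_interval(x, n, method=method)
        lower, upper = _oracle(x, n, method, 0.95)
        assert est.lower == pytest.approx(lower, abs=1e-9)
        assert est.upper == pytest.approx(upper, abs=1e-9)

    @pytest.mark.parametrize("method", sorted(set(DEFAULT_PANEL) | {"wald"}))
    def test_boundary_collapse(self, method):
        assert binomial_interval(19, 19, method=method).upper == 1.0
        assert binomial_interval(0, 19, method=method).lower == 0.0

    @pytest.mark.parametrize("method", sorted(set(DEFAULT_PANEL) | {"wald"}))
    @pytest.mark.parametrize("x,n", [(3, 4), (15, 19), (1, 30)])
    def test_interval_contains_point_estimate(self, method, x, n):
        est = binomial_interval(x, n, method=method)
        assert est.lower <= est.point <= est.upper

    def test_wilson_symmetric_at_half(self):
        est = binomial_interval(10, 20, method="wilson")
        assert est.upper - 0.5 == pytest.approx(0.5 - est.lower, abs=1e-12)

    @pytest.mark.parametrize("method", ["wilson", "clopper_pearson", "jeffreys"])
    def test_level_nesting(self, method):
        narrow = binomial_interval(15, 19, method=method, level=0.95)
        wide = binomial_interval(15, 19, method=method, level=0.99)
        assert wide.lower <= narrow.lower and wide.upper >= narrow.upper

    def test_exact_aliases_clopper_pearson(self):
        a = binomial_interval(15, 19, method="exact")
        b = binomial_interval(15, 19, method="clopper_pearson")
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_clopper_pearson_not_narrower_than_wilson_on_benchmark_input(self):
        cp = binomial_interval(15, 19, method="clopper_pearson")
        wilson = binomial_interval(15, 19, method="wilson")
        assert cp.upper - cp.lower >= wilson.upper - wilson.lower

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_interval(5, 0)
        with pytest.raises(ValueError):
            binomial_interval(8, 7)
        with pytest.raises(LookupError_):
            binomial_interval(1, 2, method="bogus")


@pytest.fixture(scope="module")
def benchmark_summary():
    bench = load_validation_benchmark()
    return confusion(list(zip(bench.prediction, bench.ground_truth)))


class TestIntervalPanel:
    def test_fifteen_estimates(self, benchmark_summary):
        panel = interval_panel(benchmark_summary)
        assert len(panel) == 15
        assert set(panel["metric"]) == {"accuracy", "sensitivity", "specificity"}

    def test_published_accuracy_envelope(self, benchmark_summary):
        """Across the five methods the accuracy envelope matches the
        published bounds: min lower 0.544, min upper 0.915 (Wilson)."""
        bounds = panel_bounds(interval_panel(benchmark_summary))
        accuracy = bounds.set_index("metric").loc["accuracy"]
        assert accuracy["min_lower"] >= 0.544
        assert accuracy["min_lower"] == pytest.approx(0.544, abs=5e-4)
        assert accuracy["min_upper"] == pytest.approx(0.915, abs=5e-4)

    def test_degenerate_single_trial_spans_nearly_everything(self):
        panel = interval_panel(ConfusionSummary(tp=1, fp=0, fn=0, tn=0))
        acc = panel[panel["metric"] == "accuracy"]
        assert (acc["upper"] == 1.0).all()
        assert (acc["lower"] < 0.35).all()

    def test_zero_denominator_metric_omitted(self):
        panel = interval_panel(ConfusionSummary(tp=0, fp=0, fn=0, tn=5))
        assert "sensitivity" not in set(panel["metric"])


@pytest.fixture(scope="module")
def sweep_fixture():
    graph, labels = planted_partition_graph(4, 40, 0.9, 0.01, seed=19)
    partition = louvain(graph, seed=4)
    targets, expected = synth_drug_targets(graph, labels, n_drugs=4,
                                           overlap_mode="mixed", seed=6)
    truth = {
        frozenset((row.drug_a, row.drug_b)): bool(row.expected)
        for row in expected.itertuples()
    }
    return graph, partition, targets, truth


class TestParameterSweep:
    def test_single_point_matches_direct_evaluation(self, sweep_fixture):
        graph, partition, targets, truth = sweep_fixture
        sweep = parameter_sweep(graph, partition, targets, truth)
        assert len(sweep) == 1
        row = sweep.iloc[0]
        assert row["tp"] + row["fp"] + row["fn"] + row["tn"] == len(truth)
        # planted structure is recovered at the defaults
        assert row["accuracy"] == 1.0

    def test_raising_beta_never_creates_new_positives(self, sweep_fixture):
        graph, partition, targets, truth = sweep_fixture
        sweep = parameter_sweep(graph, partition, targets, truth,
                                betas=(0.15, 0.3, 0.6, 0.9))
        positives = (sweep["tp"] + sweep["fp"]).tolist()
        assert positives == sorted(positives, reverse=True)

    def test_gamma_above_max_community_size_kills_positives(self, sweep_fixture):
        graph, partition, targets, truth = sweep_fixture
        sweep = parameter_sweep(graph, partition, targets, truth, gammas=(10_000,))
        row = sweep.iloc[0]
        assert row["tp"] + row["fp"] == 0
        assert row["sensitivity"] in (0.0, None) or np.isnan(row["sensitivity"])

    def test_grid_shape(self, sweep_fixture):
        graph, partition, targets, truth = sweep_fixture
        sweep = parameter_sweep(graph, partition, targets, truth,
                                alphas=(5, 10), betas=(0.15, 0.2), gammas=(5, 10))
        assert len(sweep) == 8
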