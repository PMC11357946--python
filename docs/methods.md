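# Methods

`netcombo` predicts anti-cancer drug combinations from the topology of
cancer-specific gene networks. This note records the model, the
parameter choices, the numerical conventions, and the limits of what
the synthetic fixtures can demonstrate.

## Cancer-specific network construction

The input is a table of curated drug–gene relations: each row states
that a publication reports a drug acting on one or more genes in a
named cancer type. For one cancer type, all genes co-mentioned in the
same source (grouped by `source_id`; records without a source stand
alone; the grouping key is configurable) form a clique. Self-loops are
impossible between distinct symbols, and isolated nodes — genes only
ever mentioned alone — are pruned, so single-gene records contribute
nothing. The resulting graph is simple, undirected, and unweighted;
co-mention frequency is deliberately not used as an edge weight.

Literature co-occurrence alone produces cliquey, fragmented graphs, so
the network can be composed with a background protein–protein
interactome. Two compositions are offered: `intersect` keeps only
co-occurrence edges confirmed by the background, and `augment`
(default) adds every background edge between genes already in the
co-occurrence network. Augment is the default because the downstream
proximity measure runs on shortest paths, which need connectivity
beyond the clique union.

Gene symbols are normalized lexically (trim, collapse internal
whitespace, upper-case); drug names are trimmed but keep their case.
This is a deterministic stand-in for identifier mapping against
PubChem/DrugBank/UniProt, which is out of scope; users with properly
mapped identifiers lose nothing.

## Community detection

Communities are found by the Louvain algorithm, implemented here
directly (not delegated) with Newman modularity

    Q = sum_c [ L_c/m − (D_c/2m)² ]

where `L_c` is the intra-community edge weight, `D_c` the summed
degree, and `m` the total edge weight. The local-move phase inserts an
isolated node `i` into community `c` when the gain

    ΔQ = k_i,in/m − D_c·k_i/(2m²)

is positive; the aggregation phase collapses communities into weighted
super-nodes (intra edges become self-loops) and the two phases
alternate until modularity stops improving. The gain expression is
verified in the test suite against a brute-force modularity-difference
oracle, exhaustively over all single-node moves on small random
graphs, including weighted graphs with self-loops as they arise from
aggregation.

Reproducibility conventions: node visit order is a seeded shuffle of
the sorted labels; on tied gains the node keeps its current community,
otherwise the lowest community id wins; returned community ids are
canonical (numbered by smallest member label). The resolution parameter
is fixed at 1. Interactomes are unweighted, so all weight terms reduce
to edge counts on the first level.

## Separation measure

For drugs A and B with target sets T_A, T_B mapped onto the network,
the separation score is

    s_AB = d̄_AB − (d̄_AA + d̄_BB)/2

under the closest-distance convention of network medicine: each target
contributes its shortest-path distance to the nearest *other* member of
its own set (for d̄_AA, d̄_BB; singleton sets score 0) or to the
nearest member of the opposite set (for d̄_AB, averaged over all
|A|+|B| contributions; shared targets contribute 0). Negative s_AB
means the two drugs' target modules overlap topologically — they act
in the same network neighborhood. An all-pairs averaging mode is
available behind a flag for sensitivity analysis; it is not the
default because the nearest-neighbor form is the one the separation
literature defines and is what makes s_AB(A,A) ≤ 0 hold.

Degenerate inputs: targets absent from the network are dropped with a
warning (a drug must keep at least one); under the default `restrict`
reachability policy a target that cannot reach any counterpart is
excluded from the average and tallied on the result, while `strict`
raises instead. Distances are unweighted hop counts.

## Combination decision rule

Drug X hits community C_j when

    |C_j ∩ T_X| ≥ min(α, β·|C_j|)   and   |C_j| ≥ γ

with defaults α=10, β=0.15, γ=10: in a community of at least ten
nodes, a drug hits when it covers ten nodes or 15% of the community,
whichever is smaller. β·|C_j| is compared as a real number against the
integer intersection count — no rounding — and the size gate uses ≥
(a strict-inequality variant is available behind `strict_size`). β
scales with the community's size, not the drug's target count: that is
the only reading consistent with comparing min(α, β|C_j|) against
|C_j ∩ T_X|.

A pair (A, B) is called a combination exactly when s_AB < 0 AND the
drugs share at least one hit community. s_AB = 0 counts as no
interaction (strict inequality). Both conditions are needed: proximity
alone or community overlap alone demonstrably produces false calls on
the validation panel.

## Gene prioritization

Within one cancer network, exact normalized betweenness centrality
ranks genes; the top 60% of nodes *by rank* (count-based, ties broken
by label, size exactly `ceil(0.6·|V|)`) are that cancer's important
genes. Count-based ranking rather than a value quantile keeps the
selection deterministic under the heavy ties betweenness produces.
Genes whose important status recurs in more than `min_cancers`
(default 10) cancer networks are hot cancer genes; the strict ">"
follows the defining phrase "more than ten", with a `strict=False`
escape hatch since with few networks the strict form is very
demanding.

## Evaluation

Predictions are scored against experimental ground truth as TP/FP/FN/TN
with accuracy, sensitivity, and specificity; a rate whose denominator
is zero is reported as missing, never 0. Because validation panels are
small (n=19 in the packaged benchmark), each rate is wrapped in a panel
of binomial confidence intervals: Clopper–Pearson (aliased as "exact"),
Wilson score, Agresti–Coull, Jeffreys, and optionally Wald. Interval
computation delegates to `statsmodels.stats.proportion.proportion_confint`,
with one-sided collapse to 0/1 at the boundaries (the
Brown–Cai–DasGupta convention); the test suite cross-checks every
method against independently coded closed forms to 1e−9. A parameter
sweep utility re-runs the hit rule and decision over a grid of
(α, β, γ) against fixed truth labels; separations are computed once
since they do not depend on those parameters.

The packaged benchmark (`netcombo.load_validation_benchmark`) is the
published panel of 19 tested drug pairs. On it the decision rule
reproduces all 19 predictions from the printed (s_AB, overlap) columns,
the confusion tally gives accuracy 78.9%, sensitivity 75.0%,
specificity 80.0%, and the five-method accuracy envelope spans
[0.544, 0.939] with the smallest upper bound 0.915 (Wilson), to
printed precision.

## Synthetic fixtures

The generators exist because the curated relation corpus and assembled
interactome behind the real networks are not redistributable.

* `planted_partition_graph` draws a stochastic block model (intra-block
  edge probability `p_in`, inter-block `p_out`) with gene-style node
  labels, returning the planted labels. Default test geometry is 4
  blocks of 30–40 nodes with p_in=0.9, p_out=0.01–0.02 — block sizes
  are kept well above and below γ=10 community boundaries elsewhere in
  the suite so the size gate is exercised on both sides.
* `synth_drug_targets` places each drug's targets inside one block
  (same-block / cross-block / mixed assignment) and gives same-block
  drugs a shared core of one third of their targets. The sharing is
  what makes the expected label well defined: shared targets contribute
  zero-length cross-distances, so for same-block pairs d̄_AB < d̄_AA ≈
  d̄_BB ≈ 1 and s_AB < 0 by construction, while cross-block pairs have
  d̄_AB well above 1 and no common hit community. Pharmacologically,
  partially overlapping target sets are also what same-pathway drug
  pairs look like.
* `synth_relations` emits relation records with 2–6 genes per source by
  default, the scale of gene mentions in a single abstract.

One master seed propagates through `numpy.random.SeedSequence`
spawning, so every generator (and Louvain's shuffle) draws from an
independent reproducible stream, and derived seeds stay below 2³¹.

What passing on these fixtures does **not** show: real interactomes are
scale-free with heavy degree tails, communities are neither
equal-sized nor cleanly separated, target sets are small and biased
toward hubs, and literature relations are redundant and noisy. The
planted recovery results certify the machinery (the rule chain and its
implementations), not field performance; the 19-pair experimental
panel is the only real-data anchor in the package.

## Problem sizes and determinism

The test suite and the acceptance script use 120-node planted graphs,
50-seed replications, exhaustive move enumeration on graphs of ≤ 8
nodes, and 100 random graphs of ≤ 12 nodes for the separation oracle —
sizes at which the brute-force oracles are exact and the whole suite
runs in well under a minute. All randomness is seeded; reruns are
byte-identical.

## Known limitations

* Edge direction and sign (activation vs inhibition) are ignored; the
  decision rule cannot distinguish synergy from antagonism, only
  topological compatibility.
* The headline combination counts reported for real cancers (tens of
  thousands of pairs per subtype) depend on the unreleased relation
  corpus and are not reproducible here; only the decision rule and its
  validation statistics are.
* The published specificity interval bounds could not be reproduced
  from the panel's tn=12, fp=3 by any of the six implemented methods
  and are treated as an erratum; the accuracy bounds reproduce exactly.
* Community detection is hard-partitioned; a gene on the boundary of
  two modules is assigned to one, which can suppress hit overlap for
  drugs targeting module interfaces.
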