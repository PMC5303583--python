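# Methods

## Data model

A cohort is a list of case records: case id, gender (male/female, may be
missing), age, poisoning substance, and a *set* of precipitating-problem
codes drawn from a fixed two-level taxonomy — 6 classes (health, family,
economic, romantic, educational, other) over 18 leaf subcategories.
Problems are unordered and deduplicated within a case; a case may report
zero problems. Cases with missing gender enter the total stratum but are
excluded from the male/female strata.

The cohort summary reports, per leaf and per class, the number of problem
reports and its percentage share per stratum. One rounding rule is used
throughout: **round half-up to one decimal**, with the stratum's total
report count as denominator for report percentages and the case count for
case-level fractions. Published tables of this kind sometimes mix rounding
and truncation (a 276/579 share may be printed 47.6 rather than 47.7); the
package does not reproduce such mixtures — it applies its single rule and
the summary is exactly reproducible from the counts.

## Co-occurrence network

For every case and every unordered pair within its problem set, the pair's
weight increases by one; the weight of an edge is therefore the number of
cases reporting both problems, and a problem's occurrence is the number of
cases reporting it at all. Single-problem cases contribute occurrence only.
An exact conservation law follows and is enforced in tests:
Σ weights = Σ_cases C(k_case, 2).

Networks are built at two levels. At leaf level the 18 subcategories are
the nodes. At class level each case's problems are first mapped to their
classes and deduplicated, so a class pair counts once per case regardless
of how many leaf pairs induce it — class networks are *not* naive
aggregations of the leaf network. Both levels are provided because it is
genuinely open which one a given published centrality table used.

Nodes never reported in a stratum stay in the taxonomy-ordered node list
(keeping matrix shapes stable across strata) and are flagged as unreported.
Density is defined on the binarized network — distinct co-occurring pairs
over C(n, 2) — because the underlying formula counts connections, not
weights.

## Centrality

Degree and betweenness run on the binarized graph via networkx (Brandes
accumulation for betweenness); the contract, however, is the brute-force
definition, and the test suite pins it against exhaustive path-enumeration
oracles on every non-isomorphic graph with ≤ 7 nodes and on random 8-node
graphs. Normalization always uses the full node count n, including
unreported nodes, so scores are comparable across strata; pairs in
different components contribute zero. A weighted betweenness variant
(distance = 1/weight) exists behind a flag but is not the default, since no
weight→distance transform is canonical for co-occurrence counts.

Stratified reporting: a stratum with no cases yields all-missing columns; a
stratum in which fewer than 3 nodes were reported yields missing
betweenness (the measure is vacuous there).

## CONCOR blockmodel

Profiles are rows of the weighted co-occurrence matrix (weights carry the
structural-equivalence signal; a binary profile source is available). The
first correlation step excludes the two self-entries pairwise — standard
one-mode practice. Subsequent steps correlate full columns of the running
correlation matrix. Iteration stops when every off-diagonal entry is within
`convergence_tol` (default 1e-8) of ±1, at a fixed point short of that, or
at `max_iterations` (default 200). The sign pattern of the first row then
defines the bipartition, applied recursively to submatrices of the original
profile matrix.

Deterministic conventions for the cases the iteration alone does not
settle:

- a pairwise-excluded vector with zero variance contributes r = 0;
- constant profiles (isolates) are removed before iteration and collected
  in a trailing residual block, since Pearson correlation is undefined for
  them and arbitrary signs would make the split order-dependent;
- a correlation matrix whose off-diagonal entries are all equal (e.g. from
  a complete uniform-weight network) has no sign structure: the group is
  returned unsplit and flagged;
- a stall short of ±1 triggers a convergence warning and the split uses the
  final sign pattern.

Recursion stops at `max_depth` (default 3, at most 8 blocks), when a group
has fewer than `2 × min_block_size` members (default min size 2), or when a
group is homogeneous. The number of blocks is thus an analysis choice, not
an estimate: no stopping rule is claimed to recover a "true" block count.
Blocks are numbered in left-to-right tree order.

Block densities are always computed on binarized edges: intrablock density
= edges within / C(|B|, 2) (missing for singletons), interblock density =
edges between / |B1||B2|. The whole-network density is the significance
cut-off; entries strictly above it are flagged. Density entries conserve
the edge count exactly (tested on random partitions).

## Synthetic cohort generator

Each case draws gender (Bernoulli, default P(female) = 0.574), a problem
count k from a categorical distribution, then k distinct leaves by
sequential weighted sampling without replacement: the first from the
gender's prevalence weights, each subsequent leaf with its weight
multiplied by β ≥ 1 if it shares a planted block with any already-drawn
leaf. Sequential sampling (rather than a joint exponential-family model)
was chosen because it is exactly simulable and analytic for k ≤ 2:
`expected_cooccurrence` gives closed-form pair expectations used as a 4σ
oracle for generator and network builder jointly.

Defaults emulate the motivating hospital cohort's published shape: 357
cases; zero/single/multi problem-count mass 93 : 107 : 157 (the reported
case split); multi-case counts spread {2: 0.25, 3: 0.5, 4: 0.25}, matching
the observed mean of ≈ 3 problems per multi-problem case (only the total is
published, 472 reports over 157 cases) and giving ≈ 579 expected reports;
per-gender leaf weights proportional to the published per-category report
margins; β = 1 (no planted blocks), because the true joint distribution of
problems is unpublished — planted structure is a validation device, not a
claim about the data.

What the generator does *not* emulate: age and substance structure,
temporal effects, and any dependence between gender and the number of
problems. Passing recovery tests therefore show that the algorithms work
when their assumptions hold, not that real admission data has planted-block
structure.

All randomness flows from one integer seed through a single
`numpy.random.Generator` stream; identical spec and seed give identical
cohorts, and the pipeline's outputs are byte-identical under identical
configuration (manifests carry no timestamps).

## Problem sizes and validation conditions

Test and acceptance computations use: exhaustive centrality oracles on the
1253 non-isomorphic graphs with ≤ 7 nodes plus 100 random 8-node graphs;
weight conservation on 1000 random cohorts of up to 25 cases; CONCOR
fixed-point agreement with a literal iterate-correlations loop on random
10-node matrices; and planted-block recovery over 20 cohorts of 2000 cases
with four planted blocks (sizes 5/5/4/4 over the 18 leaves), k ∈ {2, 3},
and β = 8, scored by adjusted Rand index against the planted labels. For
recovery the blockmodel runs at `max_depth=3, min_block_size=3`: depth 3 is
the smallest allowing four blocks regardless of which side of the first
split holds how many planted blocks, and a minimum block size of 3 stops
recovered 4–5-node blocks from being split again. Mean recovery under these
conditions is ≈ 0.99.

## Known limitations

- Published centrality values and block memberships for the motivating
  cohort depend on its unpublished raw co-occurrence matrix and cannot be
  recomputed; only the count/percentage arithmetic of its summary table is
  reproduced exactly.
- CONCOR convergence is empirical, not guaranteed; the package flags rather
  than hides non-convergence.
- Betweenness ignores edge weights by default; rank orders can change under
  the weighted variant.
- The class-level network is one of two defensible constructions (collapse
  then count vs. aggregate leaf scores); the package implements the former
  and exposes both levels.
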