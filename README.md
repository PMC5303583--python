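# precipnet

Network analysis of the problems that precede deliberate self-poisoning.

Hospital charts of self-poisoning admissions often record several
precipitating problems per case — family conflicts together with depression,
drug addiction together with unemployment. `precipnet` treats those
multi-problem records as a **co-occurrence network**: each of 18 problem
subcategories (grouped into 6 classes: health, family, economic, romantic,
educational, other) is a node, and two problems are linked with weight equal
to the number of cases reporting both. The package is aimed at
epidemiologists and public-health analysts who want to rank precipitating
problems not by raw frequency but by their position in that network, overall
and separately for men and women.

Three quantities drive the analysis:

- **normalized degree centrality** `C_D(v) = deg(v) / (n − 1)` — the share
  of other problems a problem ever co-occurs with;
- **normalized betweenness centrality**
  `C_B(v) = Σ_{s<t, s,t≠v} σ_st(v)/σ_st / [(n−1)(n−2)/2]` — the share of
  shortest paths between other problem pairs that pass through `v`
  (unweighted shortest paths on the binarized network);
- a **CONCOR blockmodel**: node profiles (rows of the weighted co-occurrence
  matrix) are correlated, the correlations are correlated again, and so on
  until every entry reaches ±1; the sign pattern bipartitions the nodes, and
  recursive application yields blocks of approximately structurally
  equivalent problems. Each block pair is scored by its intrablock /
  interblock **density** on the binarized network and judged against the
  whole-network density `Δ = edges / C(n, 2)` as cut-off.

Because real admission records cannot be shipped, the package includes a
synthetic cohort generator whose defaults emulate the shape of a published
hospital cohort (357 cases, 57.4 % female, 579 problem reports, many
zero- and one-problem charts) and which can plant block-structured
co-occurrence with a boost factor β, providing ground truth for every
downstream stage.

## Worked example

```python
import precipnet as pn

spec = pn.default_spec(seed=1)           # study-shaped synthetic cohort
cohort = pn.generate_cohort(spec)
summary = pn.summarize_cohort(cohort)
print(summary.n_cases, summary.report_totals)

net = pn.build_network(cohort, "leaf")
print(round(pn.network_density(net), 3))

table = pn.centrality_report(cohort, "leaf").table
print(table[["total_degree", "total_betweenness"]]
      .nlargest(3, "total_degree").round(3))

model = pn.concor_partition(net)
print(model.n_blocks, round(model.cutoff, 3))
```

prints

```
357 {'total': 568, 'male': 242, 'female': 326}
0.614
                       total_degree  total_betweenness
node
family_conflicts              1.000              0.134
other_mental_problems         0.882              0.064
others                        0.882              0.062
7 0.614
```

Read: the simulated cohort produced 568 problem reports over 357 cases;
61.4 % of all possible problem pairs co-occurred at least once; family
conflicts co-occurred with every other problem (degree 1.0) and carried the
largest share of shortest paths; CONCOR grouped the 18 problems into 7
blocks, whose density matrix is judged against the 0.614 cut-off.

The same pipeline runs from the shell:

```sh
precipnet simulate --seed 1 --out cohort.csv
precipnet summarize cohort.csv --out summary.csv
precipnet centrality cohort.csv --out centrality.csv
precipnet blockmodel cohort.csv --out-prefix bm
precipnet run --synthetic --seed 1 --out-dir results/run1
```

`precipnet run` writes the cohort, the summary table, per-stratum
(total/male/female) networks at leaf and class level (edge list, GraphML,
GEXF), centrality tables, blockmodel outputs and a manifest; identical
configuration and seed reproduce every file byte for byte.

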