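# salinet

Co-occurrence network analysis of microbial communities along salinity
gradients.

Freshwater-to-seawater transitions impose a steep, monotone environmental
stress on aquatic microbiomes.  `salinet` takes a taxon-by-sample count
table (e.g. an ASV table) plus per-sample salinity metadata and quantifies
how the community's *association structure* responds to that stress: it
builds a correlation network for each salinity band, tracks the networks'
complexity and robustness along the gradient, and contrasts the roles of
the **abundant biosphere** (taxa averaging > 0.1% relative abundance) and
the **rare biosphere** (< 0.01%) in holding the networks together.  It is
aimed at microbial ecologists who want the full gradient-network workflow —
rarefaction to robustness simulation — as tested, scriptable Python rather
than a chain of web tools, and it ships a synthetic-community generator so
the whole pipeline can be exercised and validated without sequencing data.

## The statistics at the core

* **Networks.** Within each salinity group, taxa present in all of the
  group's samples are CLR-transformed
  (`clr(x)_i = ln x_i − (1/D) Σ_j ln x_j` per sample) and connected wherever
  the Pearson correlation of their CLR profiles satisfies `|r| ≥ t` for a
  uniform threshold `t` (default 0.96).
* **Topology.** Node/link counts, average degree `2L/N`, clustering,
  density, Krackhardt connectedness (fraction of node pairs joined by a
  path), greedy modularity `Q`, and the log-log degree-distribution `R²`.
* **Natural connectivity** (robustness under simulated extinction):
  `λ̄ = ln((1/N) Σ_i e^{λ_i})` over the adjacency eigenvalues, recomputed
  after removing a random fraction of nodes.
* **Relative degree**: node degree divided by the network's average degree,
  making node importance comparable across networks; per network the
  abundant-minus-rare mean gap and **Freeman's θ**
  (`θ = |#(a>b) − #(a<b)| / (n_a n_b)` over abundant×rare cross pairs)
  summarise the imbalance between the biospheres.
* **Levins' niche breadth** `B = 1/Σ_j p_j²` with a Wilcoxon rank-sum
  comparison between abundant and rare taxa.
* Supporting gradient statistics: Mantel tests (Bray-Curtis community
  distance vs environmental distance), geographic-vs-environment distance
  correlations, alpha-diversity trends, and a random-forest salinity
  biomarker selector with out-of-bag permutation importance and
  cross-validated biomarker-count selection.

Every "metric vs salinity" claim reduces to an ordinary linear regression
with a two-sided slope test, mirroring standard practice in the field.

## Worked example

Simulate a 600-taxon, 48-sample gradient survey and run the full pipeline:

```bash
cat > design.yaml <<EOF
n_taxa: 600
seed: 7
EOF
salinet simulate --config design.yaml --outdir sim

cat > config.yaml <<EOF
counts_path: sim/counts.tsv
metadata_path: sim/metadata.tsv
outdir: out
rarefaction_depth: 51323
n_groups: 6
correlation_threshold: 0.96
removal_fractions: [0.5]
n_removal_replicates: 50
mantel_permutations: 199
rf_iterations: 5
rf_trees: 100
rf_grid_max: 8
seed: 7
EOF
salinet run-all --config config.yaml    # ~1.5 minutes
```

`out/networks/topology.csv` then contains one row per salinity group
(abridged):

```
group_id  mean_salinity  n_nodes  n_links  avg_degree  density  connectedness  modularity
n1        2.03           186      235      2.53        0.0137   0.074          0.807
n2        5.56           237      326      2.75        0.0117   0.103          0.806
n3        9.05           184      162      1.76        0.0096   0.069          0.899
n4        12.72          100       61      1.22        0.0123   0.017          0.962
n5        16.22           47       25      1.06        0.0231   0.026          0.950
n6        19.79           30       15      1.00        0.0345   0.034          0.933
```

and `out/networks/networks.json` the fitted trends — network size and
complexity fall with salinity while modularity rises
(`n_nodes: slope −11.5, p = 0.011`; `avg_degree: slope −0.106, p = 0.008`;
`modularity: slope +0.0091, p = 0.029`).  The companion reports show the
same gradient story from the other angles:

* `gradient/gradient.json`: salinity is a significant correlate of
  community structure (Mantel `r = 0.318`, `p = 0.005` at 199 permutations)
  and richness declines along the gradient (slope −2.06 taxa per g/L,
  `p = 0.008`).
* `stability/stability.json`: after removing 50% of nodes, both robustness
  indices fall with salinity (natural connectivity slope −0.049,
  `p = 0.006`).
* `turnover/turnover.json`: network-community similarity declines with the
  salinity span between networks (slope −0.016 per g/L, `p = 0.019`), and
  rare taxa are nearly absent from the overlap between adjacent network
  communities (0.9% of the n1∩n2 overlap, versus 40% abundant).
* `roles/roles.json`: abundant taxa occupy significantly broader niches
  than rare taxa (mean Levins' B 29.9 vs 16.3, Wilcoxon `p < 1e-14`).

The demo survey uses the generator's default, gently-decaying association
structure; at this size the four role-trend regressions are present in the
report but not individually significant.  The planted-effect benchmark
designs (`salinet.association_decay_design()` and
`salinet.hub_erosion_design()`, used by the test suite) plant stronger,
calibrated effects and recover all trend directions in ≥ 90% of surveys —
see `docs/methods.md`.

As a library, the same pipeline is a handful of calls:

```python
import salinet as sn

table, meta, truth = sn.simulate_gradient(sn.GradientDesign(seed=7))
res    = sn.rarefy(table, depth=51_323, seed=7)
classes = sn.classify_abundance(res.table)
groups  = sn.assign_salinity_groups(meta, n_groups=6)
for grp in groups:
    sub = sn.prevalence_filter(res.table, grp.sample_ids, 1.0)
    net = sn.build_network(sn.clr_transform(sub, 0), threshold=0.96,
                           group_salinity=grp.mean_salinity)
    print(grp.group_id, sn.topology(net))
```

## Layout

```
src/salinet/
  simulate.py    synthetic gradient surveys (GradientDesign, benchmarks)
  prep.py        rarefaction, biosphere classes, grouping, CLR
  gradient.py    Mantel, distance correlations, diversity, linear trends
  biomarkers.py  RF salinity biomarkers (sklearn-style estimator)
  network.py     co-occurrence networks and topology
  stability.py   natural connectivity, removal simulation
  turnover.py    network-community overlap and similarity
  roles.py       relative degree, Freeman's θ, Levins' breadth
  io.py          TSV/GraphML/YAML readers and writers, config
  pipeline.py    staged end-to-end driver
  cli.py         `salinet` command-line interface
```
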