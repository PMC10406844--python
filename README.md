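# micronet

Compositional co-occurrence networks and their null models for microbiome
count tables.

Microbiome surveys routinely find that *which* microbes are present varies
enormously across hosts while community function stays stable. One
explanation is that the microbiome's *architecture* — the co-occurrence
network among taxa — is the conserved feature, not the taxon list.
`micronet` implements the full analysis needed to test that idea on
family-level count tables (samples × taxa): diversity and composition
statistics, sparse network inference from compositional data, and
null-model tests that ask whether an inferred network's degree
distribution looks Erdős–Rényi while its community structure exceeds what
its degree sequence alone implies. A synthetic-data generator with planted
ground truth makes every stage verifiable.

## What it computes

**Diversity & composition.** Proportional abundance; per-sample richness
S, Shannon H (natural log), effective diversity e^H, Pielou evenness
J = H/ln S; Kruskal–Wallis with Dunn post-hoc; Bray–Curtis dissimilarity;
classical PCoA; one-way PERMANOVA with pairwise contrasts
(pseudo-F = (SS_B/(k−1))/(SS_W/(N−k)), permutation p).

**Network inference.** Abundance filter (mean count ≥ 100) → centered
log-ratio transform (clr_i = ln x_i − mean_j ln x_j, pseudocount 1) →
Meinshausen–Bühlmann neighborhood selection (per-taxon lasso along a
150-point log-spaced λ path from λ_max down to 0.05·λ_max, OR-rule
symmetrization) → StARS stability selection at target instability 0.05.
Exposed as a scikit-learn estimator, `StarsNetworkInference`.

**Architecture null models.** Uniform G(n, m) ensembles with two-sample
Kolmogorov–Smirnov tests on degree distributions; Clauset–Newman–Moore
modularity Q with cluster counts; degree-preserved randomization
(accepted double-edge swaps, 10·|E| per replicate) confidence bounds for
Q; keystone summaries (betweenness centrality vs mean relative abundance,
Spearman ρ with permutation p).

**Synthetic truth.** Logistic-normal–multinomial count simulation whose
latent precision matrix has a planted association graph as its exact zero
pattern, with group-level compositional effects; defaults mirror a
74-sample, five-group, 150-taxon study design.

## Worked example

```python
import micronet as mn

# simulate a grouped study with a planted 180-edge modular truth graph
cfg = mn.SimulationConfig(n_taxa=150, seed=1)
table, truth = mn.simulate_grouped_study(cfg)

# composition differs across groups ...
dist = mn.bray_curtis(table)
res = mn.permanova(dist, table.groups("aggregation"), seed=2)
print(f"PERMANOVA F={res.pseudo_f:.2f} R2={res.r2:.3f} p={res.p:.4f}")

# ... but each group's network shares the planted architecture
sub = table.select_samples(
    table.metadata.index[table.groups("aggregation") == "Cancun"])
clr = mn.clr_transform(mn.filter_taxa(sub, min_mean=100))
profile, net = mn.stars_select(clr, nlambda=50, n_subsamples=20, seed=3)
net = net.subgraph([v for v, d in net.degree if d > 0]).copy()
print(f"network: {net.number_of_nodes()} nodes, "
      f"{net.number_of_edges()} edges, Q={mn.cnm_modularity(net).q:.2f}")

er = mn.er_consistency_test(net, n_replicates=1000, seed=4)
print(f"fraction of KS p > 0.05 vs G(n,m): {er.frac_p_above_alpha:.3f}")
```

prints

```
PERMANOVA F=4.02 R2=0.189 p=0.0001
network: 21 nodes, 16 edges, Q=0.69
fraction of KS p > 0.05 vs G(n,m): 0.999
```

i.e. aggregation explains ~19% of compositional variance (highly
significant by permutation), while the inferred per-group network is
sparse, strongly modular, and its degree distribution is indistinguishable
from an Erdős–Rényi random graph of the same size in ~99.9% of the
ensemble's KS tests.

The same pipeline is available from a shell:

```
micronet simulate  --seed 1 --config study.yaml --out run/sim
micronet diversity --counts run/sim/counts.tsv --metadata run/sim/metadata.tsv \
                   --seed 2 --out run/div
micronet network   --counts run/sim/counts.tsv --metadata run/sim/metadata.tsv \
                   --group Cancun --seed 3 --out run/net
micronet nulls     --graph run/net/network.graphml --seed 4 --out run/nulls
micronet keystones --graph run/net/network.graphml --counts run/sim/counts.tsv \
                   --seed 5 --out run/keys
micronet report    --run-dir run --out run/report.json
```

Every command writes a versioned, seed-stamped `results.json` and a
plaintext log; stochastic commands refuse to run without `--seed`.

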