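# Methods

`micronet` analyses family-level microbiome count tables in three stages:
diversity/composition statistics, sparse co-occurrence network inference,
and null-model tests of network architecture. A synthetic-data generator
with planted ground truth makes every stage verifiable end to end. This
note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Diversity and composition statistics

All comparisons operate on proportional abundances (each sample's counts
divided by its library size); no rarefaction is performed. Per sample we
report richness S (taxa with nonzero count), Shannon entropy
H = −Σ p_i ln p_i over nonzero proportions (natural logs), effective
diversity e^H (the "effective number of taxa"), and Pielou evenness
J = H / ln S. J is reported as missing when S ≤ 1. Evenness is Pielou's
J rather than the literal quotient H/S: only H/ln S lies in [0, 1] and
matches the conventional use of "evenness" for community data.

Group differences in scalar diversity indices use the Kruskal–Wallis H
test with the standard tie correction, followed by Dunn pairwise z tests
with tie-corrected pooled variance. The Dunn p-values are unadjusted by
default; Bonferroni, Holm and Benjamini–Hochberg adjustments are
selectable.

Beta diversity uses Bray–Curtis dissimilarity on proportions,
d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i), which makes the matrix invariant
to per-sample sequencing depth. Ordination is classical PCoA (metric
scaling: double-centering of squared dissimilarities followed by
eigendecomposition); negative eigenvalues are reported rather than
silently dropped, and requesting more axes than there are positive
eigenvalues truncates with a warning.

PERMANOVA is the one-way pseudo-F partition of squared dissimilarities:
SS_total = (1/N) Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
F = (SS_between/(k−1)) / (SS_within/(N−k)), R² = SS_between/SS_total.
The p-value permutes sample labels freely (no strata) and uses the
(1 + exceedances)/(1 + permutations) convention, so p ≥ 1/(B+1). The
default is 9,999 permutations. Pairwise mode reruns the two-group test
per pair and adjusts p (Bonferroni by default). Degenerate inputs — an
all-zero dissimilarity matrix, or a pairwise contrast with zero
within-group degrees of freedom — raise informative errors.

## Network inference

The inference stage assumes the standard compositional workflow: taxa
with mean count below 100 across all samples are removed (a taxon at
exactly the threshold is retained), a pseudocount of 1 is added (family
tables are zero-rich and the transform needs positivity), and counts are
mapped to centered log-ratios, clr_i = ln x_i − mean_j ln x_j.

Conditional-dependence structure is estimated by Meinshausen–Bühlmann
neighborhood selection: each standardized CLR column is regressed on all
others with an L1 penalty, and an edge i–j is placed when either variable
selects the other (OR rule). The penalty path has 150 log-spaced values
from λ_max — the largest absolute pairwise correlation of the
standardized columns, at which the lasso solution is exactly empty —
down to λ_max · 0.05. The lasso is solved by cyclic coordinate descent
with warm starts along the path (tolerance 1e-6 on the coefficient
update).

The path point is chosen by StARS stability selection: 50 row subsamples
of 80% without replacement, per-edge selection frequencies θ̂ per λ, edge
instability ξ = 2θ̂(1−θ̂) averaged over all node pairs (so ξ ∈ [0, 0.5]),
monotonized by a running maximum from the sparse end. The selected λ is
the smallest (densest fit) whose monotonized instability is at or below
the target β = 0.05; if no λ qualifies the densest fit is returned with
a warning flag. The final network is the full-data fit at the selected λ,
with edges unweighted (architecture statistics are topological) and
isolated taxa retained in the graph document but excluded from
architecture statistics.

The stage is packaged as a scikit-learn estimator
(`StarsNetworkInference.fit` on a CLR matrix; fitted attributes
`graph_`, `lambda_`, `stability_profile_`) so it composes with sklearn
tooling; `stars_select` is the equivalent functional wrapper.

## Null models of network architecture

*Erdős–Rényi consistency.* The question "is the degree distribution of
the inferred network what a random graph of the same size would give?" is
answered by ensemble comparison: 5,000 graphs drawn uniformly from all
simple graphs with the same node and edge counts (G(n, m)), each
KS-tested against the empirical degree multiset. Degree ECDFs are
integer-valued and tie-rich, which makes the two-sample KS test
conservative; the ensemble p-values inside these loops use the asymptotic
Smirnov formula (exact enumeration is used by the public test when the
smaller sample has ≤ 10 observations). The network is declared consistent
with Erdős–Rényi when at least 95% of replicate p-values exceed 0.05,
mirroring the near-unanimous fractions such ensembles produce under the
null.

*Degree-preserved modularity.* Community structure is quantified by
Clauset–Newman–Moore greedy modularity maximization
(Q = Σ_c [L_c/m − (D_c/2m)²]), computed by igraph's fast-greedy
agglomeration (the CNM algorithm) after dropping isolated nodes; an
edgeless graph is an error. Whether the observed Q exceeds what the
degree sequence alone implies is tested against 5,000 degree-preserved
randomizations: each replicate applies 10·|E| accepted double-edge swaps
(proposals creating self-loops or multi-edges are rejected; every swap
exactly preserves all degrees) and reruns community detection. The
verdict is "modular beyond degree" when the empirical Q exceeds the
97.5th percentile of the null (a one-sided 95th-percentile option is
available). Graphs admitting no swaps (e.g. stars) return the input
unchanged with a warning and a false verdict. Chain-mixing adequacy is
checked in the test suite by the lag-1 autocorrelation of Q across
replicates.

*Keystones.* Per node: degree, unnormalized shortest-path betweenness,
CNM cluster id, and mean relative abundance; plus the Spearman rank
correlation between betweenness and abundance with a permutation p-value
(999 label permutations, two-sided on |ρ|). A negative-or-null ρ is the
signature of keystone taxa: central but not abundant.

## Synthetic data generator

The generator follows a logistic-normal–multinomial composition model.
A planted association graph (Erdős–Rényi with an exact edge budget,
planted-partition "modular", or Barabási–Albert "scale_free") defines the
zero pattern of a latent precision matrix: off-diagonal entries are
±edge_magnitude exactly on edges (random signs), the uniform diagonal
starts at the maximum absolute off-diagonal row sum (diagonal dominance)
and is inflated by multiplicative 1.05 steps until the matrix is positive
definite with condition number ≤ cond_target (default 100), and the
inverse is rescaled to unit diagonal. The rescaling preserves the zero
pattern, so the truth graph remains exactly the support of the inverse
covariance. A consequence of the diagonal-dominance start worth knowing:
the achievable partial-correlation strength scales like 1/(maximum
degree of the truth graph), so dense hubs produce weak edges regardless
of edge_magnitude.

Per sample, a latent vector is drawn from N(μ_g, Σ), softmaxed to a
composition, and observed as a multinomial draw at a depth sampled
uniformly from depth_range. Defaults mirror the targeted study design:
74 samples in five aggregation groups of sizes {14, 19, 6, 16, 19},
150 taxa, depths 5,000–20,000 (a desk-scale stand-in for metagenome
library sizes of order 10^5; the larger range is available via config).
Group-level compositional shifts multiply the latent means (i.e. add
ln(effect) on the log scale) of a per-group random 20% taxon subset by
effect_size = 3.0; effect 1.0 for every taxon makes the groups
exchangeable, which is the null used for type-I-error calibration.

What the generator does *not* emulate: taxon-specific dispersion
heterogeneity, heavy-tailed abundance distributions, sequencing-run batch
effects, and water-column contamination. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not field realism of whale-shark data.

## Problem sizes used in tests and the acceptance script

Simulation scales are chosen for desk-scale runtimes and stated here as
package choices: network-recovery benchmarks use a 50-taxon, 60-edge
modular truth with n = 500 samples at full StARS settings (150 λ values,
50 subsamples); ensemble calibrations use 200 outer draws × 500
replicates (ER consistency), 50 trials × 200 replicates (degree-preserved
null), and 500 simulated null datasets at 199 permutations (PERMANOVA
type I). The study-shaped end-to-end run keeps the full 74-sample design
but scales the per-group inference to 50 λ values and 20 subsamples and
the null ensembles to 200–1,000 replicates; the 5,000-replicate defaults
remain the package defaults. At the scaled sequencing depths the default
abundance filter (mean ≥ 100) retains only the few dozen most abundant
taxa per group, so the per-group networks in that run are small and
sparse — the regime in which their architecture verdicts are stable
across groups.

## Known limitations

- StARS instability is averaged over all node pairs, so with very small
  sample counts (n ≈ 15) heavily overlapping subsamples can certify
  fairly dense fits as "stable"; inferred networks at such n contain a
  substantial noise component, and their modularity sits close to the
  degree-preserved null bound.
- The KS ensemble test is conservative on tie-rich integer degree data;
  this is inherited from the method it reproduces and documented rather
  than corrected.
- CNM greedy modularity is a heuristic; it attains the exhaustive-search
  optimum on the small oracle graphs in the test suite but is not
  guaranteed to in general.
- PERMANOVA permutes labels freely; stratified permutation (e.g. by
  sequencing run) is not implemented.
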