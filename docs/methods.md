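# Methods

This note documents the statistical models and algorithms behind `netreg`,
the defaults chosen where the design was genuinely open, and what the
synthetic generators do and do not emulate.

## Differential-expression screen

The screen assumes log2-scale, approximately normal expression values with
gene-specific variances. The fold change is the difference of group means
on the log2 scale, which equals the log2 ratio of geometric means on the
linear scale; linear input is transformed as log2(x + pseudocount) with a
default pseudocount of 1.0.

The moderated t-test follows the standard empirical-Bayes hierarchy: the
gene-wise pooled variance s²g on d = n₁ + n₂ − 2 degrees of freedom is
shrunk toward a prior, s̃²g = (d₀s₀² + d·s²g)/(d₀ + d), and the moderated t
is referred to a t distribution on d + d₀ degrees of freedom. The prior
(d₀, s₀²) is estimated by moment matching on log s²g: under the model,
log s²g follows a log-F distribution whose mean and variance involve the
digamma and trigamma functions, so d₀ solves trigamma(d₀/2) = observed
excess variance of log s²g (Newton inversion) and s₀² follows from the
mean. When the observed spread of log variances is no larger than
chi-square sampling noise, d₀ = ∞ and all genes share s₀². `test="ordinary"`
forces d₀ = 0, the classical pooled-variance t-test; this switch is used in
tests to verify the moderated path against a textbook implementation. This
is a documented approximation of the limma scheme, not a claim of
bit-compatibility with it.

Filtering uses |log2FC| ≥ 1, p < 0.05 and BH-adjusted p ≤ 0.05 with exactly
that comparison strictness. Genes with any missing or non-finite value are
dropped with a logged warning. BH adjustment is the classic step-up
p(i)·n/i with a cumulative minimum from the largest rank, clipped at 1.

## Network construction

Interaction tables are cleaned before use: self-pairs dropped (warned),
A–B/B–A duplicates collapsed keeping the maximum score, scores validated to
[0, 1] (STRING exports are divided by 1000). Edges are kept when the
combined score is strictly greater than the threshold (default 0.4) and
both endpoints are in the DEG whitelist; whitelist genes left isolated are
excluded from the graph with a logged count. Gene symbols match by exact
string; identifier mapping is the caller's responsibility.

## Topology metrics

Per node: degree k; clustering C = 2T/(k(k−1)) with C := 0 for k < 2 (the
standard convention keeping C in range for leaves); neighborhood
connectivity C_N = mean neighbor degree; betweenness C_B normalized by
(n−1)(n−2)/2; closeness C_C = (n_comp − 1)/Σ within-component distances
(0 for singleton components); eigenvector centrality C_E computed per
connected component from the leading eigenpair of the dense adjacency
matrix and rescaled so the maximum entry is 1 (disconnected graphs have no
canonical global eigenvector). Standard graph algorithms are delegated to
networkx; the test suite verifies them against independent hand-written
brute-force oracles (BFS path enumeration for betweenness, triple
enumeration for triangles) on hundreds of small random graphs.

Profiles are raw per-degree arithmetic means (no log binning), since that
is what the degree-dependent fits consume; degrees with no nodes are absent
from the profile and Σ P(k) = 1 by construction.

## Power-law fitting

The degree distribution is fitted by the Clauset–Shalizi–Newman procedure:

* **xmin** minimizes the Kolmogorov–Smirnov distance between the tail
  empirical CDF and the fitted power law, scanning candidate xmins over the
  unique observed values (capped at 256 quantile-spaced candidates; ties
  broken toward the smallest xmin).
* **Exponent** by maximum likelihood: continuous α̂ = 1 + n[Σ ln(x/xmin)]⁻¹
  (closed form); discrete by bounded numerical maximization of the
  Hurwitz-zeta likelihood (verified against a 10⁻³-step grid search).
  During the xmin scan the standard analytic discrete approximation
  α̂ ≈ 1 + n[Σ ln(x/(xmin − ½))]⁻¹ is used for speed where it is accurate
  (xmin ≥ 10); for smaller xmin the approximation is visibly biased and the
  exact MLE is used for those few candidates as well. The reported exponent
  is always the exact MLE at the chosen xmin.
* **Goodness of fit** by the semi-parametric bootstrap: each of n_boot
  (default 2500) resamples draws the tail from the fitted model (exact
  inverse-CDF sampling from a precomputed zeta pmf table for discrete data;
  inverse transform for continuous) and the body empirically, then refits
  xmin and exponent; boot_p is the fraction of resamples whose refitted KS
  distance exceeds the observed one. Deterministic given a seed. A fit is
  called plausible when boot_p > 0.1 and KS D ≤ 0.35.

The five per-degree profiles C(k), C_N(k), C_B(k), C_C(k), C_E(k) are
fitted by ordinary least squares on (ln k, ln mean), preserving the slope
sign; zero-valued bins are dropped with a warning and at least 3 usable
points are required. Exponents are stored as a magnitude plus a direction
(decaying/growing/flat) to avoid sign-convention ambiguity in reports. The
bootstrap test is applied to the degree distribution; the profile means are
not i.i.d. samples, so a KS bootstrap is not meaningful for them.

Classification: scale-free when the degree-distribution bootstrap p exceeds
0.1; mixing by the sign of the C_N(k) exponent (growing → assortative);
hierarchy strong when C(k) decays with |β| ≥ 1, weak when C(k) decays with
|β| < 1 together with an assortative trend 0 < ∅ ≤ 0.5, otherwise none.
Every call carries a human-readable trace of the criteria applied.

## Leading-eigenvector decomposition

For a node subset g the generalized modularity matrix is
B_g(i,j) = A_ij − k_i k_j/2m − δ_ij Σ_{l∈g}(A_il − k_i k_l/2m); a proposed
bisection is the sign pattern of its leading eigenvector (zero entries to
the positive side), with modularity gain ΔQ = sᵀB_g s/4m. A split is
accepted only when the leading eigenvalue and ΔQ are positive and both
sides are non-empty — complete graphs, for example, are indivisible. The
leading eigenpair comes from shifted power iteration (Gershgorin shift,
deterministic start vector, tolerance 1e−10) with a dense symmetric
eigendecomposition fallback when convergence is slow; the residual
‖B_g v − λ₁v‖∞ ≤ 1e−8 is asserted in tests. An optional Kernighan–Lin-style
refinement (`refine="kl"`) hill-climbs single-node flips to a local
optimum; the raw sign split is kept as the default since the refinement
changes Table-style outputs only marginally. The raw LEV split is a
heuristic: it is not guaranteed to match the best bisection, and only the
refined split is guaranteed to be a single-flip local optimum.

Recursion proceeds from the whole graph (label "C", level 0) until a
community is exactly a triangle — the G(3,3) motif, the terminal unit —
has fewer than 3 members, hits `max_level`, or is indivisible. Children are
indexed by decreasing size (ties by smallest member symbol), producing the
dotted path labels; disconnected member sets get one child per connected
component.

Two divisibility regimes are provided. The default, `mode="subgraph"`,
re-analyzes each community's induced subgraph as a standalone graph with
its own null model — the way per-level re-application of LEV community
detection behaves in practice. This matters: global modularity has a
well-known resolution limit (merging or freezing communities smaller than
roughly √m), so with a global criterion (`mode="global"`) recursion stalls
far above the triangle scale on any realistically sized network and no
motif leaves are found. Subgraph mode escapes the limit and terminates in
triangle motifs; global mode guarantees instead that every accepted split
strictly increases the global Q (asserted in tests for that mode).
Communities lacking any internal triangle are kept in the tree but flagged
`has_motif=False`; they are not counted as communities by the motif
criterion and contribute no key regulators.

## Key regulators

Under nested partitions, membership in a terminal triangle leaf is
equivalent to having an ancestor community at every level of the hierarchy,
so the key regulators are exactly the union of motif-leaf members and their
count is 3 × (number of motif leaves); the equivalence is verified by an
explicit root-to-leaf trace in the tests. The summary joins each regulator
with its network statistics (full precision internally; report output
rounded half-even to 4 decimals) and flags "low-degree bridges": degree ≤
11 with a motif partner of degree ≥ 17. Those two cutoffs are report
heuristics mirroring the extremes seen in published low-degree/hub motif
pairings, not part of the regulator definition, and are configurable.

## Over-representation analysis

One-sided hypergeometric ORA: p = P[X ≥ k] for X ~ Hypergeometric(N, K, n)
via the exact survival function, BH-adjusted across the sets of the queried
collection; fold enrichment (k/n)/(K/N). The default universe is the genes
of the analyzed network (configurable), and set members outside the
universe are dropped with a logged count. Note that DAVID-style tools use a
modified Fisher statistic (EASE) and their own background, so printed
p-values from such tools are not reproduction targets for this engine.

## Synthetic data

`gen_expression` draws control samples Normal(baseline_g, σ_g) on the log2
scale with baseline_g ~ Uniform(6, 12) and gene variances from a scaled
inverse-chi-square (d₀ = 10, s₀ = 0.4 — microarray-like heterogeneity that
the EB screen's own hierarchical model assumes); the first n_deg genes
(default 100 of 2000) are shifted by ±effect_lfc (default 2.0) in the case
group, half up and half down so both DEG directions are exercised.
Defaults use 10 samples per group. It does not emulate count noise,
library-size effects, normalization artifacts or correlated genes — so
passing tests demonstrate the screen's behavior under its stated model, not
robustness to RNA-seq count data.

`gen_graph` provides Barabási–Albert preferential attachment (degree
exponent ≈ 3, the positive control for scale-freeness), Erdős–Rényi nulls,
planted-partition block graphs (ground truth for LEV recovery), a
deterministic Ravasz-style hierarchical graph (k-clique replication,
C(k) ~ 1/k, the hierarchy-classifier control), and `triangle_hierarchy`:
nested binary bisections terminating in planted triangles, with optional
pendant nodes. The last is the pipeline's default synthetic interaction
graph because it is the one model whose ground truth exercises the full
decomposition-and-tracing chain: BA subgraphs are triangle-poor, Ravasz
cliques are LEV-indivisible, and dense planted blocks stall above the
motif scale. Real PPI networks are noisier than any of these models; the
synthetic runs validate algorithmic correctness, not biological recall.

`sample_powerlaw` draws exact continuous Pareto samples by inverse CDF and
exact discrete zeta samples by inverse-CDF lookup in a pmf table covering
all but ~1e−9 of the mass (continuous-approximation fallback beyond).

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the bootstrap at n = 10000
observations × 2500 resamples, oracle comparisons on 200 random graphs of
≤ 12 nodes, and end-to-end pipelines of 2000 genes / 100-node networks —
sizes chosen so the full suite completes in well under a minute of compute
per component while leaving every statistical check well-powered.
Tolerances: eigenpair residuals ≤ 1e−8 (iteration tolerance 1e−10),
MLE/closed-form agreement 1e−12, hypergeometric p within 1e−12 of the
explicit pmf sum. Degenerate inputs are errors with named messages (empty
groups, all-zero variances, zero log-spread tails, empty networks) rather
than silent results.

## Known limitations

* The moderated test covers the two-group design only — no multi-factor
  models, no count-based (voom/NB) modeling.
* Identifier mapping between expression tables and interaction tables is
  exact-string.
* Power-law fitting does not compare against alternative heavy-tailed
  models (log-normal, exponential) by likelihood ratio; a plausible fit is
  not evidence against those alternatives.
* The LEV bisection is a heuristic; exact agreement with the best-Q
  bisection is not guaranteed (and not asserted).
* Discrete power-law sampling truncates beyond a 5×10⁶-entry pmf table;
  for α close to 1 the extreme tail is approximated by the continuous
  transform.
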