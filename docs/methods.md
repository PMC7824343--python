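# Methods

This note documents the models and procedures implemented in `perconet`,
the numerical conventions chosen where several are defensible, and what the
synthetic-data generator does and does not emulate.

## Normalization: cumulative sum scaling (CSS)

Marker-gene count tables have library sizes that vary by orders of
magnitude for technical reasons. Dividing by total library size lets a few
dominant taxa control the scaling; CSS instead divides the counts of sample
*j* by

s<sub>j</sub> = Σ<sub>i : c<sub>ij</sub> ≤ q<sub>j</sub></sub> c<sub>ij</sub>,

the cumulative sum of counts up to the *p*-th quantile q<sub>j</sub>, then
multiplies by a scale constant *N* (default 1000).

Conventions, fixed for determinism and documented because they change
s<sub>j</sub>:

- **q<sub>j</sub> is the quantile of the *positive* counts only**, with
  linear interpolation between order statistics. On sparse tables the
  all-counts quantile is frequently 0, which would break s<sub>j</sub> > 0.
- **Ties equal to q<sub>j</sub> are included** (≤, not <), the
  cumulative-sum reading.
- **The percentile is fixed** (configurable, default *p* = 0.5 — a
  median-quantile scaling) rather than selected adaptively per dataset.
  Determinism and a closed-form testable rule were preferred; an adaptive
  rule could be added without changing the interface.

Consequences verified by tests: s<sub>j</sub> is positive and never exceeds
the library size, and multiplying a sample's counts by a positive integer
leaves its normalized column unchanged (both q and s scale by the same
factor).

## Filtering

OTUs whose *total* count is 1 (unique singletons) are removed — they are
overwhelmingly artefacts and carry no co-occurrence signal; the operation
is idempotent. A prevalence floor (default: nonzero in ≥ 3 samples) is
applied before correlation, because a rank correlation over a vector with a
single nonzero observation is meaningless. The floor is deliberately
conservative and logged.

## Co-occurrence matrix and network

Spearman's ρ is computed as the Pearson correlation of mid-ranks (ties
averaged), the only tie convention that stays well behaved for heavily tied
sparse counts. The classical 1 − 6Σd²/(n(n²−1)) shortcut is valid only
without ties and is used purely as an independent test oracle. The matrix
is made exactly symmetric with a unit diagonal; OTUs with zero variance get
ρ = 0 (not NaN) plus a warning, keeping all graph operations total.

Correlations are computed on CSS-normalized values by default
(`correlate_on="raw"` switches to raw counts). Raw counts share each
sample's library-size factor, which induces spurious positive correlation
among unrelated taxa; CSS removes most of that common factor, which is
observable in the synthetic benchmark (background mean |ρ| drops from
≈0.15 to ≈0.13 and, more importantly, background pairs stop sharing a
systematic positive shift).

The network keeps only positive correlations (edge weight = ρ), with an
optional floor `min_weight`. Negative associations are discarded at
construction but the full signed matrix can be persisted for audit.
"Strong, non-random association" is operationalized as a weight threshold
(the 0.7–0.95 range conventional for this kind of analysis). For users who
want a formal null, `permutation_pvalues` shuffles each OTU's sample order
independently (destroying co-variation, preserving marginals) and returns
Benjamini–Hochberg-adjusted two-sided p-values per pair; it is optional and
off by default, since the weight threshold is the primary criterion.

## Percolation threshold

The percolation threshold t\* of a weighted network is the largest edge
weight cutoff at which the retained edges still connect the entire analysed
node set (nodes of degree ≥ 1): the network at t\* is the minimal giant
cluster with the fewest, strongest links required for overall connectivity.
This is computed exactly as the *bottleneck* of a maximum spanning tree —
the smallest weight on the tree that connects all nodes as strongly as
possible — an equivalence guarded in the tests by a brute-force descending
scan over unique weights (exact equality on hundreds of random graphs).

Conventions:

- thresholds iterate over **unique** weights only, so equal-weight edges
  enter and leave together (no order dependence);
- a disconnected input falls back to its largest connected component with
  an explicit `fragmented` flag, rather than failing — mirroring the
  practice of dropping to a lower manual threshold when focal nodes detach;
- the trajectory S(t) (giant component size) and E(t) (edge count) are
  computed incrementally with union-find and are non-increasing in t by
  construction.

## Module detection

Weighted modularity

Q = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − γ k<sub>i</sub>k<sub>j</sub>/(2m)] δ(c<sub>i</sub>, c<sub>j</sub>)

is optimized with the seeded two-phase Louvain heuristic (resolution γ
defaults to 1.0). Two safeguards:

- the **reported Q is always re-evaluated directly from the formula** on
  the final assignment, never taken from the optimizer's internal
  bookkeeping; tests compare it against a third, naive O(n²) double-sum;
- a fixed seed yields an identical partition across runs; module ids are
  renumbered by decreasing size (ties by smallest member id) so reports are
  stable.

Isolated nodes become singleton modules; an edgeless network yields the
all-singletons partition with Q = 0 and a warning. Module summaries
histogram member lineages at a chosen rank and flag modules containing the
target lineage; a module whose members are *all* target-lineage
("singleton-target") is flagged so partner analyses can exclude it — such a
module says nothing about partners.

## Focus reports

For every OTU whose lineage contains the target string (case-insensitive
substring, because taxonomy exports vary in rank prefixes and casing), the
report lists neighbours in the thresholded network with weight ≥
w<sub>min</sub> (default 0.7), sorted by descending weight and annotated
with module co-membership. Raising w<sub>min</sub> can only shrink partner
lists (tested); a target matching nothing produces an empty report with a
warning, not an error.

## Diversity

Shannon H′ = −Σ p<sub>i</sub> ln p<sub>i</sub> (natural log) and Simpson
reported as 1 − D = 1 − Σ p<sub>i</sub>² (probability two random reads
differ). Both are computed on raw counts: per-sample rescaling leaves the
proportions p<sub>i</sub> unchanged. Bray–Curtis dissimilarity
Σ|x−y|/Σ(x+y) feeds a sample-similarity network (edge iff BC ≤ max_bc,
weight 1 − BC); `max_bc` has no privileged default and must be chosen by
the analyst.

## qPCR quantification

The standard curve Ct = slope·log₁₀(copies) + intercept is fitted by OLS
over a dilution ladder (the simulated ladder spans 10⁻¹–10⁸ copies, 10
points). Efficiency E = 10^(−1/slope) − 1; the canonical slope −3.3219
gives E = 100 % (perfect doubling). Quality gates — efficiency in 90–110 %,
r² > 0.99, replicate Ct ≤ 30 — produce *flags*, not failures, so partially
quantifiable series can still be reported; only a non-negative slope is a
hard error. Unknown copies are 10^((Ct − intercept)/slope) ×
dilution_factor / mass_or_volume; conversion factors are explicit input
columns, never a hard-coded chain. Replicates are aggregated as the
arithmetic mean of per-replicate copy numbers (not mean Ct). A sample is
flagged biologically relevant at ≥ 10³ copies per gram or mL.

Enrichment across timepoints is tested on log₁₀-transformed replicate
copies (variance stabilization for an exponential assay): one-way ANOVA
across all timepoints and a two-sided t-test between first and last; the
fold change is log₁₀ of the ratio of linear-scale means. Noiseless
generation and re-quantification round-trip exactly; at Ct sd 0.1 with
triplicates the recovered efficiency is within 2 percentage points and
copies within 15 % (tested).

## Synthetic-data generator

`generate_table` draws, for each planted block k and sample s, a latent
factor f<sub>k</sub>(s) ~ N(0, latent_sd); block member i has expected
log-abundance a<sub>i</sub> + b<sub>i</sub>f<sub>k</sub>(s) with loading
b<sub>i</sub> ~ U(loading_range) and baseline a<sub>i</sub> ~ N(0, 1).
Background OTUs have constant log mean. Expected abundances are scaled per
sample to a library size drawn uniformly from `library_size_range`, then
counts are drawn negative-binomially with dispersion k
(var = μ + μ²/k). Finally `n_singletons` OTUs receive exactly one read
each. This is the simplest mechanism that produces rank-correlated,
overdispersed, sparse counts with uneven libraries — precisely the features
the Spearman-on-CSS chain assumes.

Default condition: 40 samples × 300 OTUs, four blocks of 10 with latent sd
1.5 and loadings 0.8–1.2, the first block carrying a
*Methanomassiliicoccales*-style lineage; libraries 5 000–50 000 reads,
dispersion k = 5, 10 singletons. Library range and dispersion were chosen
once as realistic for mixed environmental amplicon runs: k = 5 is moderate
overdispersion under which within-block Spearman ρ averages ≈0.85 on
CSS-normalized values while background pairs average ≈0.13 in absolute
value — a strong but not trivial planted signal.

What the generator does **not** emulate: compositional closure (counts are
not multinomially conditioned on the library; the analysis chain never
assumes it), taxonomic misassignment, chimeras, batch effects, or phylogenetic
correlation between blocks. Passing the end-to-end recovery benchmark
therefore shows the chain correctly extracts planted rank-correlation
structure from sparse overdispersed counts — not that real habitat data
meet those assumptions.

Recovery is scored by the adjusted Rand index restricted to planted block
members; background OTUs have no planted community and legitimately scatter
across modules. Focus-partner recovery is the fraction of a target OTU's
block mates listed at w<sub>min</sub> = 0.7, averaged over target OTUs.

## Problem sizes

The test suite and the acceptance script use 200 random graphs (n ≤ 30) for
the percolation oracle, 100 graphs for the modularity and Spearman oracles,
20 seeds of the 60-node planted-partition benchmark, and 10 seeds of the
full 300 × 40 end-to-end benchmark — sizes at which every check runs in
seconds while the oracles (brute-force scans and O(n²) double sums) remain
tractable.

## Known limitations

- Spearman co-occurrence ignores compositionality; on strongly compositional
  data, association methods built for it (SparCC, SPIEC-EASI) are the
  appropriate alternative — deliberately out of scope here.
- Edge weights carry no significance test by default; the weight floor is a
  convention, not a null-calibrated cutoff.
- Louvain is a heuristic: partitions are seed-deterministic but not
  guaranteed optimal, and module granularity depends on the resolution γ.
- The percolation fallback for disconnected inputs (largest component) is a
  pragmatic choice; other conventions (per-component thresholds) are
  defensible.
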