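# Methods

`neoblastsig` identifies transcriptional signatures of proliferating cells in
a flatworm-style system by combining two experimental designs — lethal
irradiation, which ablates every proliferating cell, and Hoechst-based FACS,
which sorts differentiated (2C) from late-S/G2/M proliferating (4C) cells —
and resolving the proliferating signature into germline and somatic
stem-cell (neoblast) components. This note describes the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The cell-composition mixture model (synthetic data)

Every simulated sample is a mixture of three cell compartments:
differentiated cells, somatic neoblasts, and proliferating germline cells.
The whole-worm default is 93.5% / 4.5% / 2.0% — 6.5% of cells proliferating,
split 70/30 between soma and germline. The 6.5% total is the accepted
neoblast fraction for this organism; the 70/30 split is a simulator default
chosen so that both proliferating sub-compartments remain statistically
recoverable, not an empirical claim.

Each transcript cluster carries one of four expression programs:
*housekeeping* (all compartments), *neoblast* (somatic neoblasts only),
*germline* (proliferating germline only), *tissue* (differentiated only).
Default program proportions are 57% / 5% / 8% / 30%. The expected count of
cluster *g* in sample *j* is

```
mu_gj = (L_j / 10^6) * b_g * sum_c f_cj * 1[program(g) expressed in c] * exp(sigma_b * l_g * z_j)
```

where `L_j` is the library size (default 10^6), `b_g` a per-cluster base
mean (program base mean — 100 for housekeeping/tissue, 400 for
neoblast/germline — times a lognormal spread with sdlog 0.6), `f_cj` the
compartment fractions of the sample, and the last factor a multiplicative
batch effect with per-cluster loadings `l_g ~ N(0,1)`, per-sample factors
`z_j ~ N(0,1)` and strength `sigma_b` (default 0.2; 0 turns it off).
Program base means were chosen once as realistic bulk depths at which a
neoblast-program cluster still has double-digit expected whole-worm counts
despite its 4.5% cell fraction — i.e. detectable the way real
proliferating-cell genes are. Counts are negative binomial via a
gamma–Poisson mixture with `var = mu + phi mu^2`, default `phi = 0.1`.

Compartment compositions per condition follow the designs: irradiated
samples at any post-irradiation timepoint have both proliferating
compartments set to zero (an optional leakage parameter, default 0,
reintroduces a small fraction at 72 h); 2C gates are purely differentiated;
the intact 4C gate contains neoblasts and germline renormalised to sum to
one; juvenile and amputated-head 4C gates — gonad-free animals — are pure
neoblast. Every composition is validated to sum to one.

Transcript sequences are uniform-random DNA (lengths 200–1500 nt) with the
44-nt trans-splice leader `CCGTAAAGACGGTCTCTTACTGCGAAGACTCAATTTATTGCATG`
prepended verbatim to a Bernoulli(leader_fraction, default 0.3) subset.

**What the generator does not emulate:** read-level sequencing (no FASTQ, no
error or fragment-length models), GC/length biases, correlated programs,
partially shared programs across compartments, isoform structure within
clusters, or quiescent stem cells. Passing tests therefore demonstrate that
the pipeline's logic and statistics behave correctly under the designs'
idealised composition shifts — not that it would reach the same numbers on
real libraries, where unmodelled biases and softer on/off contrasts apply.
All randomness flows from a single integer seed through deterministic
sub-streams; identical seeds give byte-identical outputs.

## The NB differential-expression engine

The engine is a deliberately self-contained, simplified stack whose contract
downstream is only the (direction, FDR, fold-change) triple per contrast;
all contrasts in this design are two-group.

1. **Filtering.** Clusters need CPM ≥ 1 in ≥ 3 samples (both thresholds
   configurable). The filter is idempotent.
2. **Normalisation.** Median-of-ratios size factors against the per-cluster
   geometric-mean pseudo-reference, computed over clusters positive in all
   samples, rescaled to geometric mean one; falls back to column-sum ratios
   when no cluster is everywhere-positive. TMM is deliberately not
   implemented.
3. **Dispersion.** Per-cluster method-of-moments
   `phi_g = max(1e-8, (var - mean)/mean^2)` on normalised counts, with the
   variance pooled within groups when a group structure is supplied
   (residual df `n - G`). Shrinkage toward a common value:
   `phi~_g = (df*phi_g + d0*phi0)/(df + d0)` with prior df `d0 = 10`. The
   common value `phi0` is the **mean of the unfloored** per-cluster
   estimates: flooring truncates the estimator's noise distribution, and at
   small residual df both the median and the mean of floored values are
   biased low, which measurably inflates the type-I rate (0.072 instead of
   ~0.055 at the null-calibration conditions). The unfloored mean is
   unbiased for the common dispersion; its price is sensitivity to
   heavy-tailed estimates from very low-count clusters, which makes `phi0`
   conservative (larger) on heterogeneous matrices — an acceptable direction
   for a screening pipeline.
4. **Exact test.** Counts are equalised to a common effective library by
   rescaling with the size factors and deterministic half-away-from-zero
   rounding. Conditional on a cluster's total `t = S_A + S_B`, group sums
   are NB with sizes `n_A/phi~`, `n_B/phi~` and equal per-sample means; the
   two-sided p sums the probabilities of all group-A totals no more likely
   than the observed one (relative tie tolerance 1e-12). Totals above 2x10^6
   use a Gaussian approximation to the conditional split. `log2FC` uses
   normalised group means with pseudo-count 0.5. This replaces a
   GLM/quasi-likelihood treatment on purpose; multi-factor designs are out
   of scope.
5. **FDR.** Benjamini–Hochberg across the tested clusters of each contrast
   (delegated to statsmodels behind a validating wrapper); `direction` is
   `ns` unless `fdr <= alpha` (default 0.05).
6. **RUV.** Unwanted-variation factors are the leading per-sample singular
   directions of the row-centred `log(count+1)` sub-matrix of negative
   controls; each cluster's log-counts are regressed on the factors and the
   intercept-plus-residual is exponentiated, rounded, floored at zero.
   `k = 0` is the identity. Defaults follow the study: `k = 3` for the
   irradiation dataset, `k = 1` for FACS. When no control set is supplied
   the pipeline uses empirical controls — clusters with first-pass p > 0.5
   in every contrast of the dataset — because the factor model needs genes
   unaffected by the biology. Adjusted counts (rather than factor
   covariates in a GLM) are a documented simplification. Near-identity of
   the adjustment under a batch-free simulation is a property of the *null*
   clusters; clusters with genuine condition signal shift whenever the
   estimated factor chance-aligns with the design, which is unavoidable at
   a dozen samples.

## Category classification

With `U(c)` the up-set and `D(c)` the down-set of contrast `c` at
`fdr <= alpha`:

* `irradiation_depleted = D(12h vs 0h) ∩ D(24h vs 0h) ∩ D(72h vs 0h)` —
  permanent downregulation; transient stress responses drop out.
* `proliferating_intact = U(intact 4C vs 2C)`.
* `germline = proliferating_intact ∩ U(intact4C vs juvenile4C) ∩
  U(intact4C vs head4C)` — enrichment over both gonad-free 4C sorts. Both
  choices the definition leaves open are configurable: whether intact
  4C-vs-2C membership is required (default yes) and whether the two
  gonad-free contrasts combine with AND (default) or OR.
* `somatic_neoblast = (U(intact) ∩ U(juvenile) ∩ U(head) 4C-vs-2C) \ germline`.
* `stringent_neoblast = somatic_neoblast ∩ irradiation_depleted` — the
  intersection of the two independent approaches.

Membership uses FDR only; a >2-fold tier is carried as an annotation so both
conventional totals ("N significant, M of them >2-fold") are reportable.
Structural invariants (stringent ⊆ somatic ⊆ complement of germline;
stringent ⊆ depleted) are asserted after every construction. Contrast
orientation is validated from the `A_vs_B` naming convention to prevent
silent sign flips. Lowering `alpha` is monotone for the filter-style sets
(depleted, proliferating, germline) but **not** for the subtractive ones: a
stricter threshold can shrink the germline set and thereby add a cluster to
`somatic_neoblast`.

## Marker enrichment

For a term on `m` of `N` annotated clusters and a category of `n` clusters
containing `k` of them, fold enrichment is `(k/m)/(n/N)` and significance is
Pearson's chi-squared on `[[k, n-k], [m-k, N-n-m+k]]` with Yates' continuity
correction (the convention for these reports), BH-adjusted across the terms
of one term type. The universe `N` is the annotated clusters of that term
type, intersected with the expression-filtered cluster universe when one is
supplied. The continuity correction is conservative by construction, so
null-calibration checks use the `yates=False` flag the API exposes;
degenerate margins (`m = 0` or `n = 0`) yield a missing fold, not an error.
No ontology-graph propagation is done for GO-style terms.

## Clustering and the primary set

Transcript clustering is a thresholded shared-read graph: transcripts join
when `shared/min(total_a, total_b) >= 0.01` within equivalence classes, and
clusters are connected components, deterministically named by their
lexicographically smallest member. This intentionally simplifies
hierarchical read-distance clustering with expression-based splitting; the
classifier consumes any transcript→cluster map, including one from a
full-featured tool. An edge requires actual co-occurrence — at threshold 0
any pair sharing at least one read joins, but disjoint transcripts never do.
The primary set sorts transcripts by mapped-read support (ties by id) and
returns the shortest prefix reaching 90% of all reads; the greedy prefix is
provably the minimum-cardinality such subset, and each read's support is
counted once via its primary assignment.

## Spliced-leader discovery

The census counts each 19-mer once per transcript within the first 100 nt
(presence, not occurrences, so internal repeats cannot outcompete a shared
prefix). Consensus reconstruction keeps k-mers with count ≥ max(10, 1% of
transcripts), seeds at the most frequent (ties lexicographic) and greedily
extends right then left while exactly one frequent neighbour overlaps by
k−1, halting at branches or dead ends; a reporting mode lists all maximal
frequent paths. Classification flags a transcript when a leader *suffix* of
≥ 15 nt aligns ungapped with ≤ 1 mismatch starting within the first 30 nt —
suffix matching because trans-splicing and assembly truncation leave partial
leaders at 5' ends; leftmost match wins, longest at that position. The
frequency threshold and calling rule are engineering choices; at the
defaults the false-positive rate on random 500-nt sequences is below 10^-4.

## Numerical conventions

Dispersion floor 1e-8; fold-change pseudo-count 0.5; deterministic
half-away-from-zero rounding wherever counts are rescaled; tie-breaks by
lexicographic id everywhere an order is needed, so outputs are bit-stable.
The pipeline itself draws no random numbers; only the simulator does, from a
single seed.

## Problem sizes

Default analyses and the acceptance checks run at the study's design scale:
10,000 clusters, irradiation 0/12/24/72 h × 3 replicates and 2C/4C × three
FACS conditions × 3 replicates, 2,000 transcripts with the leader planted on
30%. A full pipeline run at this scale takes well under a minute on one CPU;
calibration checks use 10,000 null clusters.

## Known limitations

The exact test with plug-in shrunken dispersions is approximate for very
small counts; the conservative `phi0` on heterogeneous matrices trades power
for safety; RUV via adjusted counts (not covariates) slightly perturbs the
count distribution; the germline rule's open choices default to the stricter
AND; and none of the dataset-scale figures of the original study are
reproducible without its raw reads — recovery is demonstrated against
simulated ground truth only.
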