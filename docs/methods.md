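# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions a maintainer needs.

## Data model

The common currency is the expression matrix: features (genes or microRNAs)
by post-treatment time points, holding log2 ratios against a single untreated
time-0 control. The pooled-replicate design (one array per time point, RNA
pooled across replicates) means there is no replicate variance model
anywhere; all significance comes from permutations. Where a trajectory is
correlated with something (a model profile, or another feature), the control
ratio 0 is prepended, since both series are identically zero at the control
by construction; with the default six-sample grid this makes every
correlation a 7-point correlation.

## Preprocessing

* Probes are kept when signal > 1.4 × local background (strict inequality)
  in at least one sample; with a zero background any positive signal passes.
  The one-sample rule is a documented choice — requiring all samples would
  discard features that only switch on late.
* Quantile normalization maps every column onto the per-rank cross-column
  mean. Ties within a column receive the mean of the rank means they span,
  which preserves tied inputs as tied outputs but (deliberately) means
  columns with ties do not share the exact sorted multiset.
* Duplicated spots are collapsed by arithmetic mean per feature; ratios are
  log2 against the control column. A +1 offset is applied to the whole
  matrix only when some intensity is exactly zero, so the transform is
  scale-invariant whenever the data allow it.

## Temporal patterns

Changed features pass a linear fold window (genes: > 2 or < 0.5 somewhere;
microRNAs: 1.5 and its reciprocal). The model-profile library enumerates all
integer shapes starting at 0 with per-step change in [−c, c]; the constant
shape is excluded (undefined correlation). With more than `m` candidates, a
greedy maximin selection under the 1 − Pearson-r distance keeps `m`
representatives, seeded deterministically with the largest-norm shape
(lexicographic tie-break). Defaults c = 2, m = 50 are common practice for
short-series profile mining; with seven points the candidate space is 5^6 −
1 = 15 624 shapes.

Assignment maximizes Pearson r between the anchored trajectory and each
shape; ties go to the lowest profile id; zero-variance trajectories stay
unassigned. Significance permutes each feature's measured time points
independently (the control anchor stays at 0), re-assigns everything, and
compares per-profile counts:

    p = (1 + #{rounds with permuted count >= observed}) / (1 + n_perm)

with Benjamini–Hochberg across profiles. **Attainability bound:** this p is
bounded below by 1/(n_perm + 1), so the BH-adjusted value of the k-th best
profile is at least 50/(k (n_perm+1)) with m = 50 profiles. With n_perm =
1000 and the two monotone patterns one expects in this design, the floor is
≈ 0.025; a significance threshold of 0.001 can therefore never fire, and an
n_perm below ≈ 600 makes even 0.05 unreachable. The default profile FDR
threshold is 0.05 for this reason, with n_perm = 1000. Significant profiles
are labeled "up" or "down" by the sign of the mean final log2 ratio of their
members.

## MicroRNA target calling

Candidates are the predicted (miRNA, gene) pairs with both features measured
(optionally restricted to pattern genes and changed microRNAs, as the
pipeline does). Pearson r over the anchored trajectories is computed for all
candidates and only negative pairs are retained — repression predicts
anti-correlation. The null shuffles the measured time order of every miRNA
profile independently each round and recomputes all pair correlations; null
values are pooled across pairs and rounds, giving p-value resolution
1/(n_pairs · n_perm + 1):

    p = (1 + #{null r <= observed r}) / (1 + n_pairs * n_perm)

one-sided toward negative r, BH across pairs, selected iff FDR < 0.01. An
absolute tie tolerance of 1e−9 on the null comparison keeps permutations
that reproduce the observed correlation exactly (e.g. the identity ordering)
on the "at least as extreme" side regardless of float rounding. The
permutation unit (miRNA time order, gene fixed) is a documented choice; on
null data the two sides are distributionally equivalent.

**Power limit.** A 7-point Pearson correlation has null density ∝
(1−r²)^{3/2}: P(r ≤ −0.93) ≈ 2×10⁻³ and P(r ≤ −0.85) ≈ 1.2×10⁻². Selecting
a large fraction of ~500 candidates at FDR < 0.01 therefore requires |r| ≳
0.95. With measurement noise of 0.3 log2 units on both series and repression
strengths k ~ U(0.5, 1), planted pairs have median |r| ≈ 0.90, so
sensitivity at FDR < 0.01 is near zero — not an implementation artifact (an
oracle experiment substituting the exact independence null changes nothing),
but the information content of seven noisy points. At noise 0.1 the same
procedure recovers ≳ 0.9 of planted pairs with perfect precision, and in the
noise-free limit every planted pair is selected. Real smooth time-course
profiles sit near the favorable end of this range; the synthetic default
noise of 0.3 is deliberately conservative.

## Pathway statistics

* `fisher_exact_2x2` sums, over all 2×2 tables with the observed margins,
  the hypergeometric probability of every table no more probable than the
  observed one. Because all such tables share the denominator C(N, c₁), the
  comparison is done on integer numerators — exact, no tie epsilon needed.
* Enrichment intersects each gene set with the background (all measured
  features, not the genome), excludes disjoint sets, and BH-adjusts across
  pathways.
* Pathway activity is the unweighted mean of member log2 ratios per time
  point — a size-invariant linear combination chosen so activities are
  comparable across sets; no external weighting scheme is reproduced. The
  test statistic is the maximum over time of |activity|; the null draws
  random gene sets of the same size from the measured features (a
  competitive null that preserves the statistic's variance), p as the usual
  (1 + exceedances)/(1 + n_perm), BH across pathways, FDR < 0.01. A pathway
  equal to the whole matrix has p = 1 by construction.
* Hierarchical clustering is scipy average-linkage agglomeration on
  Euclidean distances (1 − Jaccard for promoter profiles), deterministic for
  a fixed row order.

## Core nodes

Edge lists (pathway_id, source, target, edge_type) become directed graphs;
self-loops are dropped and duplicate edges collapsed (first edge_type wins).
Significant pathways' graphs are merged by node/edge union, then every node
is scored by relative betweenness centrality — endpoints excluded,
fractional credit across equal-length shortest paths, normalized by
(n−1)(n−2); graphs with fewer than three nodes score all zeros. Nodes
strictly above 0.01, intersected with the called targets when supplied, are
the core microRNA targets. Edges are unweighted; edge_type labels are
annotations only. Merge-then-compute (rather than per-pathway centrality) is
the documented choice.

## Promoter TFBS similarity

Promoters are the −2000..+500 window around the TSS in 0-based half-open
coordinates: [tss−2000, tss+500) on the plus strand, [tss−499, tss+2001)
reverse-complemented on the minus strand, truncated at contig edges, always
reading 5′→3′ with the upstream bases first. PFM counts become probability
weights with a Laplace pseudocount of 1 (no log-odds background model; none
is specified for this analysis style). A window of width w scores the sum of
its per-position weights and matches at

    score >= min_score + f * (max_score - min_score),   f = 0.9

the min–max interpolation being well defined for any weight scale; the
alternative `f * max_score` convention is available via `threshold_mode`.
Both strands are scanned by default, windows containing non-ACGT bases are
skipped, and overlapping matches all count. Similarity is the Jaccard index
on binarized presence (a count-weighted min/max variant is available); joint
absence contributes nothing, which is the property that makes the measure
appropriate for sparse binding-site profiles.

## Synthetic data

The generator emulates a pooled-replicate treatment time course at hours
(1, 2, 4, 8, 12, 24) plus the implicit control — the grid is a design
choice within the stated 1–24 h span. Planted structure:

* temporal genes follow a saturating ramp s(t) = effect · (1 − 2^(−t/τ))/
  (1 − 2^(−t_max/τ)) with τ = t_max/6, peaking exactly at `effect_log2`
  (default 2.0); down-genes are mirror images. 15% up / 6% down by default,
  roughly the 2.5:1 up:down imbalance such treatments show.
* each planted repression gives its miRNA the target's clean profile scaled
  by −k, k ~ U(0.5, 1), before noise — perfect anti-correlation in the
  noise-free limit. One planted miRNA per pair (so n_true_pairs ≤ n_mirnas).
  Decoy predictions (default 20 per miRNA) point at non-temporal genes.
* gene set 0 (1) is drawn from the up (down) genes — the planted active
  pathways; the rest are random null-gene sets. Every pathway's graph is a
  star through its first member (half the members feed the hub, the hub
  feeds the rest), making the hub the unique high-betweenness node.
* two co-expression groups of up to six promoters each share three planted
  motif consensi (inserted at fixed offsets); PFMs are two-level
  (17 vs 1 counts), and with the default width 8 the 90% min–max threshold
  admits exactly the consensus — chosen because width 10 would put
  one-mismatch windows precisely on the threshold boundary.
* noise is i.i.d. Gaussian on log2 ratios (default sd 0.3), the simplest
  model consistent with ratio data.

All randomness flows from one seed through named substreams (CRC-derived
child seeds), so equal configs give byte-identical bundles and any stage can
be re-run in isolation. What the generator does **not** emulate: probe-level
array artifacts, dye/batch effects, autocorrelated noise, sequence-driven
target prediction, overlapping pathway membership, or realistic promoter
base composition. Passing tests therefore demonstrate the statistical
machinery under clean assumptions, not performance on real arrays.

## Problem sizes and determinism

Tests run on bundles of 120–500 genes with 100–1000 permutations; the
acceptance script uses the default 500-gene/50-miRNA design with 1000
permutations, twenty null bundles for calibration, and one bundle per
remaining quantity. Pipeline stages derive their seeds from the run seed by
stage name, report their input/output counts in a machine-readable report,
and hash every output file so bit-level reproducibility is checkable with
`diff` on the manifest.

## Known limitations

* Permutation p-values are bounded below by the pooled resolution; very
  small FDR thresholds interact with that floor as described above.
* The activity statistic ignores gene–gene correlation within a set; its
  competitive null is exchangeable only under the no-structure hypothesis.
* The Jaccard similarity treats every matrix equally; motif redundancy
  (near-identical PWMs) inflates similarity.
* Promoter scanning has no background model, so AT/GC-rich matrices have
  different effective stringencies at the same score fraction.
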