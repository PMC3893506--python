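# tempomir

Integrative time-course analysis of mRNA and microRNA expression.

`tempomir` is for analysts working with short treatment time courses (a
handful of post-treatment samples against one untreated control) measured on
both an mRNA and a microRNA array. It answers, in one reproducible chain:
which genes follow a coherent temporal pattern, which of those are plausibly
repressed by a microRNA, what the result means at the pathway level, and
whether the co-expressed genes share promoter architecture.

## What it computes

* **Temporal patterns.** Genes whose linear fold ratio exceeds 2 (or falls
  below 0.5) at some time point are assigned to the integer model profile
  maximizing the Pearson correlation of the log2 trajectory (control 0
  prepended). Profiles start at level 0 and change by at most *c* units per
  step; of the (2c+1)^(T−1) candidates, *m* representatives are kept by
  greedy maximin 1−r dissimilarity. Per-profile membership counts get an
  empirical permutation p-value, p = (1 + #{permuted count ≥ observed}) /
  (1 + n_perm), with Benjamini–Hochberg adjustment across profiles.
* **MicroRNA target calling.** For every predicted (miRNA, gene) pair
  (miRDB-style two-column table), the Pearson correlation r of the two
  trajectories is kept when negative, then tested one-sidedly against a
  pooled null: every miRNA profile's time order is shuffled per round and
  all pair correlations recomputed, p = (1 + #{null r ≤ observed r}) /
  (1 + n_pairs·n_perm), BH-adjusted; pairs with FDR < 0.01 are the called
  targets.
* **Pathway statistics.** Fisher's exact test (two-sided, exact integer
  arithmetic) with Benjamini–Hochberg FDR for gene-set enrichment; pathway
  activity as the mean member log2 ratio per time point, with a permutation
  null over random equal-size gene sets; hierarchical clustering of activity
  profiles.
* **Core nodes.** Directed pathway graphs are merged and nodes scored by
  relative betweenness centrality C_B(v) = Σ σ_st(v)/σ_st normalized by
  (n−1)(n−2); nodes above 0.01, intersected with the called targets, are the
  core microRNA targets.
* **Promoter similarity.** Promoters (−2000..+500 bp around the TSS, strand
  aware) are scanned with probability-scale position weight matrices at a
  90% min–max score threshold on both strands; genes are compared by the
  Jaccard index of binding-site presence (joint absence carries no weight)
  and clustered.
* **Synthetic studies.** `tempomir.generate_dataset` builds a complete input
  bundle — expression matrices, prediction table, GMT gene sets, edge lists,
  promoter FASTA/BED, JASPAR-style PFMs — with planted ground truth for
  every stage, byte-reproducible from one seed. `null_dataset` gives the
  matched no-effect bundle for calibration.

## Worked example

```bash
python examples/04_mirna_targets.py
```

```
1050 predicted pairs, 560 anti-correlated
46 pairs selected at FDR < 0.01; strongest:
 gene_id mirna_id         r   p_perm      fdr  selected
gene0231   mir017 -0.997078 0.000005 0.002789      True
gene0439   mir045 -0.996840 0.000012 0.002789      True
gene0094   mir043 -0.996008 0.000023 0.002789      True
gene0016   mir036 -0.995251 0.000034 0.002789      True
gene0179   mir040 -0.994951 0.000043 0.002789      True
planted repressions recovered: 46/50; false calls: 0
```

The bundle plants 50 microRNA→gene repressions (each miRNA profile is a
negated, scaled copy of its target's clean trajectory plus noise) among
1000 decoy predictions. At noise 0.1 log2 units the permutation FDR recovers
46 of 50 planted pairs with no false calls: `r` is the observed correlation,
`p_perm` its pooled-null empirical p-value, and `fdr` the BH-adjusted value
used for selection. The other scripts in `examples/` walk through
preprocessing, temporal patterns, pathway statistics, core nodes, promoter
similarity and the full pipeline (`tempomir simulate` / `tempomir run` on
the command line do the same from a shell).

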