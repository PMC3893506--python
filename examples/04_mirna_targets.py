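"""Call microRNA targets by anti-correlated expression.

Predicted (microRNA, gene) pairs with negative Pearson correlation over
the time course are tested against a pooled permutation null (each
microRNA profile's time order shuffled) and selected at FDR < 0.01.
"""

from tempomir import SyntheticConfig, correlate_pairs, generate_dataset, permutation_fdr

bundle = generate_dataset(SyntheticConfig(seed=42, noise_sd=0.1))
pairs = correlate_pairs(bundle.gene_expr, bundle.mirna_expr, bundle.predictions)
print(f"{len(bundle.predictions)} predicted pairs, {len(pairs)} anti-correlated")

result = permutation_fdr(
    pairs, bundle.gene_expr, bundle.mirna_expr, n_perm=1000, fdr_cut=0.01, seed=42
)
selected = result[result.selected]
print(f"{len(selected)} pairs selected at FDR < 0.01; strongest:")
print(selected.head(5).to_string(index=False))

truth = set(zip(bundle.truth.true_pairs.mirna_id, bundle.truth.true_pairs.gene_id))
called = set(zip(selected.mirna_id, selected.gene_id))
print(f"planted repressions recovered: {len(called & truth)}/{len(truth)}; "
      f"false calls: {len(called - truth)}")
# At this noise level (0.1 log2 units) the anti-correlation signal is
# strong; at higher noise a 7-point correlation loses power rapidly.
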