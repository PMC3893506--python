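import numpy as np
import pandas as pd
import pytest

from tempomir.motifs import (
    PromoterRecord,
    TFBSProfile,
    extract_promoters,
    jaccard_matrix,
    pwm_from_counts,
    reverse_complement,
    scan_pwm,
    tfbs_profile_matrix,
)


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestExtractPromoters:
    def test_plus_strand_window(self, rng):
        contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        out = extract_promoters({"chr1": contig}, bed([("chr1", 2000, 2001, "g", 0, "+")]))
        assert out[0].sequence == contig[0:2500]

    def test_plus_strand_truncated_at_contig_start(self, rng):
        contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        out = extract_promoters({"chr1": contig}, bed([("chr1", 100, 101, "g", 0, "+")]))
        assert out[0].sequence == contig[0:600]
        assert len(out[0].sequence) == 600

    def test_minus_strand_window_is_reverse_complement(self, rng):
        contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])
        out = extract_promoters({"chr1": contig}, bed([("chr1", 1000, 1001, "g", 0, "-")]))
        assert out[0].sequence == reverse_complement(contig[501:3001])

    def test_minus_strand_equals_mirrored_plus_extraction(self):
        # on a reverse-complement-palindromic contig, the minus-strand window
        # at the mirrored TSS reads identically to the plus-strand window
        half = "ACGTTTGCACCGGTAA" * 200
        contig = half + reverse_complement(half)
        L = len(contig)
        tss_plus = 2300
        tss_minus = L - 1 - tss_plus
        plus = extract_promoters({"c": contig}, bed([("c", tss_plus, tss_plus + 1, "g", 0, "+")]))
        minus = extract_promoters({"c": contig}, bed([("c", tss_minus, tss_minus + 1, "g", 0, "-")]))
        assert plus[0].sequence == minus[0].sequence

    def test_missing_chromosome_names_record(self):
        with pytest.raises(KeyError, match="gX"):
            extract_promoters({"chr1": "ACGT"}, bed([("chr2", 10, 11, "gX", 0, "+")]))


class TestPwmFromCounts:
    def test_degenerate_column_without_pseudocount(self):
        pwm = pwm_from_counts(np.array([[10], [0], [0], [0]]), "m", pseudocount=0)
        np.testing.assert_allclose(pwm.weights[:, 0], [1, 0, 0, 0])

    def test_uniform_counts_give_quarter_weights(self):
        pwm = pwm_from_counts(np.full((4, 3), 5.0), "m")
        np.testing.assert_allclose(pwm.weights, 0.25)

    def test_laplace_pseudocount(self):
        pwm = pwm_from_counts(np.array([[3], [1], [0], [0]]), "m", pseudocount=1)
        np.testing.assert_allclose(pwm.weights[:, 0], [4 / 8, 2 / 8, 1 / 8, 1 / 8])

    def test_max_min_scores_are_column_extreme_sums(self):
        pwm = pwm_from_counts(np.array([[3, 0], [1, 0], [0, 2], [0, 2]]), "m", 0)
        assert pwm.max_score == pytest.approx(3 / 4 + 1 / 2)
        assert pwm.min_score == pytest.approx(0.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.empty((4, 0)))


def brute_force_scan(seq, pwm, fraction, both_strands):
    """Oracle: plain per-window python scoring."""
    threshold = pwm.min_score + fraction * (pwm.max_score - pwm.min_score)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    count = 0
    strands = [seq, reverse_complement(seq)] if both_strands else [seq]
    for s in strands:
        for start in range(len(s) - pwm.width + 1):
            window = s[start: start + pwm.width]
            if any(b not in idx for b in window):
                continue
            score = sum(pwm.weights[idx[b], j] for j, b in enumerate(window))
            if score >= threshold - 1e-12:
                count += 1
    return count


class TestScanPwm:
    def test_width_one_motif_both_strands(self):
        pwm = pwm_from_counts(np.array([[5], [0], [0], [0]]), "A", pseudocount=0)
        assert scan_pwm("ACA", pwm, 0.9).count == 2  # revcomp TGT has no A

    def test_uniform_pwm_matches_everywhere(self):
        pwm = pwm_from_counts(np.full((4, 2), 1.0), "u", pseudocount=0)
        res = scan_pwm("ACGTA", pwm, 1.0, both_strands=False)
        assert res.count == 4

    def test_n_windows_skipped(self):
        pwm = pwm_from_counts(np.array([[5], [0], [0], [0]]), "A", pseudocount=0)
        assert scan_pwm("NNN", pwm, 0.9).count == 0

    def test_short_sequence_yields_zero(self):
        pwm = pwm_from_counts(np.full((4, 5), 1.0), "u")
        assert scan_pwm("ACG", pwm).count == 0

    def test_max_threshold_mode(self):
        pwm = pwm_from_counts(np.array([[8, 0], [0, 8], [0, 0], [0, 0]]), "AC", 0)
        assert scan_pwm("ACAC", pwm, 1.0, both_strands=False, threshold_mode="max").count == 2

    def test_matches_brute_force_on_random_cases(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(40):
            seq = "".join(bases[rng.integers(0, 5, size=int(rng.integers(10, 60)))])
            width = int(rng.integers(1, 6))
            counts = rng.integers(0, 10, size=(4, width)).astype(float)
            counts[rng.integers(0, 4), :] += 1  # avoid all-zero columns
            pwm = pwm_from_counts(counts, "m", pseudocount=1)
            frac = float(rng.uniform(0.5, 1.0))
            both = bool(rng.integers(0, 2))
            assert (
                scan_pwm(seq, pwm, frac, both_strands=both).count
                == brute_force_scan(seq, pwm, frac, both)
            )


class TestTfbsProfileMatrix:
    def make_promoters(self, seqs):
        return [PromoterRecord(f"g{i}", f"c{i}", 0, "+", s) for i, s in enumerate(seqs)]

    def test_cells_equal_independent_scans(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 50)]) for _ in range(3)]
        pwms = [
            pwm_from_counts(rng.integers(0, 9, size=(4, 4)).astype(float) + 1, f"m{j}")
            for j in range(2)
        ]
        profile = tfbs_profile_matrix(self.make_promoters(seqs), pwms, 0.8)
        for i, seq in enumerate(seqs):
            for j, pwm in enumerate(pwms):
                assert profile.counts.iloc[i, j] == scan_pwm(seq, pwm, 0.8).count

    def test_empty_pwm_list(self):
        profile = tfbs_profile_matrix(self.make_promoters(["ACGT"]), [])
        assert profile.counts.shape == (1, 0)

    def test_planted_consensus_detected(self, rng):
        bases = np.array(list("ACGT"))
        counts = np.ones((4, 8))
        consensus_idx = rng.integers(0, 4, 8)
        counts[consensus_idx, np.arange(8)] = 17
        pwm = pwm_from_counts(counts, "planted", pseudocount=1)
        background = "".join(bases[rng.integers(0, 4, 300)])
        seq = background[:100] + pwm.consensus + background[100:]
        profile = tfbs_profile_matrix(self.make_promoters([seq]), [pwm], 0.9)
        assert profile.counts.iloc[0, 0] >= 1

    def test_duplicate_gene_ids_rejected(self):
        proms = [
            PromoterRecord("g", "c1", 0, "+", "ACGT"),
            PromoterRecord("g", "c2", 0, "+", "ACGT"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            tfbs_profile_matrix(proms, [])


class TestJaccardMatrix:
    def profile(self, mat, genes):
        return TFBSProfile(
            pd.DataFrame(mat, index=genes, columns=[f"m{j}" for j in range(len(mat[0]))])
        )

    def test_identical_presence_sets(self):
        p = self.profile([[2, 1, 0], [1, 3, 0]], ["a", "b"])
        assert jaccard_matrix(p).loc["a", "b"] == 1.0

    def test_subset_overlap(self):
        p = self.profile([[1, 1, 1], [1, 0, 0]], ["a", "b"])
        assert jaccard_matrix(p).loc["a", "b"] == pytest.approx(1 / 3)

    def test_joint_absence_ignored(self):
        p1 = self.profile([[1, 1, 0], [1, 0, 0]], ["a", "b"])
        p2 = self.profile([[1, 1, 0, 0, 0], [1, 0, 0, 0, 0]], ["a", "b"])
        pd.testing.assert_frame_equal(jaccard_matrix(p1), jaccard_matrix(p2))

    def test_empty_profile_gene(self):
        p = self.profile([[0, 0], [1, 1]], ["a", "b"])
        out = jaccard_matrix(p)
        assert out.loc["a", "b"] == 0.0 and out.loc["a", "a"] == 1.0

    def test_symmetric_unit_diagonal_bounded(self, rng):
        mat = rng.integers(0, 3, size=(8, 6))
        p = self.profile(mat, [f"g{i}" for i in range(8)])
        out = jaccard_matrix(p)
        np.testing.assert_allclose(out, out.T)
        np.testing.assert_allclose(np.diag(out), 1.0)
        assert ((out.to_numpy() >= 0) & (out.to_numpy() <= 1)).all()

    def test_weighted_variant_uses_counts(self):
        p = self.profile([[2, 0], [1, 0]], ["a", "b"])
        out = jaccard_matrix(p, weighted=True)
        assert out.loc["a", "b"] == pytest.approx(1 / 2)

    def test_group_separation_on_planted_promoters(self, clean_bundle):
        # co-expression groups share planted motifs: within-group similarity
        # must dominate and clustering must split the groups cleanly
        from tempomir.pathways import hierarchical_cluster

        groups = clean_bundle.truth.motif_groups
        genes = groups["gene_id"].tolist()
        promoters = [p for p in clean_bundle.promoters if p.gene_id in set(genes)]
        profile = tfbs_profile_matrix(promoters, clean_bundle.pwms, 0.9)
        sim = jaccard_matrix(profile)
        by_group = groups.groupby("group")["gene_id"].apply(list)
        within, between = [], []
        for i in genes:
            for j in genes:
                if i >= j:
                    continue
                same = any(i in g and j in g for g in by_group)
                (within if same else between).append(sim.loc[i, j])
        assert np.mean(within) > np.mean(between)
        tree = hierarchical_cluster(1.0 - sim.loc[genes, genes])
        leaves = tree.leaves
        first_half = set(leaves[: len(by_group.iloc[0])])
        assert first_half in (set(by_group.iloc[0]), set(by_group.iloc[1]))
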