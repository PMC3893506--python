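import numpy as np
import pandas as pd
import pytest

from tempomir import (
    SyntheticConfig,
    generate_dataset,
    null_dataset,
    read_bundle,
    write_bundle,
)
from tempomir.datasets import ConfigError


class TestSyntheticConfig:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"noise_sd": -0.1}, "noise_sd"),
            ({"frac_up": 0.8, "frac_down": 0.5}, "frac_up"),
            ({"time_points_h": (2, 1)}, "time_points_h"),
            ({"time_points_h": (0, 1)}, "time_points_h"),
            ({"n_genes": -1}, "n_genes"),
            ({"n_mirnas": 2, "n_true_pairs": 5}, "n_true_pairs"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SyntheticConfig(**kwargs)

    def test_default_time_grid_plus_control_gives_seven_points(self):
        cfg = SyntheticConfig()
        assert len(cfg.time_points_h) == 6  # plus the implicit time-0 control
        assert cfg.time_labels == ["1h", "2h", "4h", "8h", "12h", "24h"]


class TestGenerateDataset:
    def test_noise_free_up_gene_is_monotone_with_peak(self, clean_bundle):
        truth = clean_bundle.truth.temporal_genes
        for gene in truth.query("direction == 'up'")["gene_id"]:
            row = clean_bundle.gene_expr.loc[gene].to_numpy()
            assert (np.diff(row) >= -1e-12).all()
            assert row.max() == pytest.approx(clean_bundle.config.effect_log2)

    def test_noise_free_down_gene_mirrors_up(self, clean_bundle):
        truth = clean_bundle.truth.temporal_genes
        up = truth.query("direction == 'up'")["gene_id"].iloc[0]
        down = truth.query("direction == 'down'")["gene_id"].iloc[0]
        np.testing.assert_allclose(
            clean_bundle.gene_expr.loc[down].to_numpy(),
            -clean_bundle.gene_expr.loc[up].to_numpy(),
        )

    def test_noise_free_pair_is_perfectly_anticorrelated(self, clean_bundle):
        for row in clean_bundle.truth.true_pairs.itertuples(index=False):
            g = clean_bundle.gene_expr.loc[row.gene_id]
            m = clean_bundle.mirna_expr.loc[row.mirna_id]
            assert np.corrcoef(g, m)[0, 1] == pytest.approx(-1.0)

    def test_true_pairs_appear_in_predictions(self, small_bundle):
        predicted = set(
            zip(small_bundle.predictions.pairs.mirna_id, small_bundle.predictions.pairs.gene_id)
        )
        planted = set(
            zip(small_bundle.truth.true_pairs.mirna_id, small_bundle.truth.true_pairs.gene_id)
        )
        assert planted <= predicted

    def test_truth_references_only_measured_ids(self, small_bundle):
        genes = set(small_bundle.gene_expr.index)
        mirnas = set(small_bundle.mirna_expr.index)
        assert set(small_bundle.truth.temporal_genes.gene_id) <= genes
        assert set(small_bundle.truth.true_pairs.gene_id) <= genes
        assert set(small_bundle.truth.true_pairs.mirna_id) <= mirnas
        pathway_genes = set().union(*small_bundle.pathways.gene_sets.values())
        assert pathway_genes <= genes

    def test_decoys_point_at_non_temporal_genes(self, small_bundle):
        planted = set(
            zip(small_bundle.truth.true_pairs.mirna_id, small_bundle.truth.true_pairs.gene_id)
        )
        temporal = set(small_bundle.truth.temporal_genes.gene_id)
        for row in small_bundle.predictions.pairs.itertuples(index=False):
            if (row.mirna_id, row.gene_id) not in planted:
                assert row.gene_id not in temporal

    def test_same_seed_same_bundle_bytes(self, tmp_path, small_config):
        m1 = write_bundle(generate_dataset(small_config), tmp_path / "a")
        m2 = write_bundle(generate_dataset(small_config), tmp_path / "b")
        assert m1.keys() == m2.keys()
        for key in m1:
            assert m1[key].read_bytes() == m2[key].read_bytes()

    def test_different_seed_differs(self, tmp_path, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        b1, b2 = generate_dataset(small_config), generate_dataset(other)
        assert not b1.gene_expr.equals(b2.gene_expr)


class TestNullDataset:
    def test_truth_tables_empty(self):
        nb = null_dataset(SyntheticConfig(n_genes=50, n_mirnas=5, n_true_pairs=5, seed=3))
        assert len(nb.truth.true_pairs) == 0
        assert len(nb.truth.temporal_genes) == 0
        assert len(nb.truth.active_pathways) == 0

    def test_noise_free_null_is_identically_zero(self):
        nb = null_dataset(SyntheticConfig(n_genes=30, n_mirnas=5, n_true_pairs=5, noise_sd=0.0, seed=3))
        assert (nb.gene_expr.to_numpy() == 0).all()
        assert (nb.mirna_expr.to_numpy() == 0).all()

    def test_null_pair_correlations_match_independence_oracle(self):
        # Monte-Carlo oracle (1e5 draws) for mean |r| of two 7-point series
        # sharing the control anchor 0: 0.361 (frozen from the oracle below)
        oracle_rng = np.random.default_rng(0)
        x = np.hstack([np.zeros((100_000, 1)), oracle_rng.normal(size=(100_000, 6))])
        y = np.hstack([np.zeros((100_000, 1)), oracle_rng.normal(size=(100_000, 6))])
        zx = x - x.mean(1, keepdims=True)
        zx /= zx.std(1, keepdims=True)
        zy = y - y.mean(1, keepdims=True)
        zy /= zy.std(1, keepdims=True)
        oracle_mean = np.abs((zx * zy).mean(1)).mean()
        assert oracle_mean == pytest.approx(0.361, abs=0.005)

        nb = null_dataset(SyntheticConfig(seed=5))
        g = nb.gene_expr.to_numpy()
        m = nb.mirna_expr.to_numpy()
        pick = np.random.default_rng(1)
        gi = pick.integers(0, len(g), 1000)
        mi = pick.integers(0, len(m), 1000)
        ax = np.hstack([np.zeros((1000, 1)), g[gi]])
        ay = np.hstack([np.zeros((1000, 1)), m[mi]])
        ax -= ax.mean(1, keepdims=True)
        ax /= ax.std(1, keepdims=True)
        ay -= ay.mean(1, keepdims=True)
        ay /= ay.std(1, keepdims=True)
        assert np.abs((ax * ay).mean(1)).mean() == pytest.approx(oracle_mean, abs=0.05)


class TestWriteBundle:
    def test_manifest_lists_all_artifact_kinds(self, tmp_path, small_bundle):
        manifest = write_bundle(small_bundle, tmp_path)
        assert len(manifest) >= 8
        for path in manifest.values():
            assert path.exists()

    def test_expression_round_trip(self, tmp_path, small_bundle):
        write_bundle(small_bundle, tmp_path)
        back = read_bundle(tmp_path)
        pd.testing.assert_frame_equal(
            back["gene_expr"], small_bundle.gene_expr, atol=1e-9
        )
        pd.testing.assert_frame_equal(
            back["mirna_expr"], small_bundle.mirna_expr, atol=1e-9
        )

    def test_full_round_trip_of_structures(self, tmp_path, small_bundle):
        write_bundle(small_bundle, tmp_path)
        back = read_bundle(tmp_path)
        assert back["pathways"].gene_sets == small_bundle.pathways.gene_sets
        assert len(back["predictions"]) == len(small_bundle.predictions)
        assert back["genome"] == small_bundle.genome
        assert len(back["pwms"]) == len(small_bundle.pwms)
        np.testing.assert_allclose(
            back["pwms"][0].weights, small_bundle.pwms[0].weights
        )
        pd.testing.assert_frame_equal(
            back["pathway_edges"], small_bundle.pathway_edges
        )

    def test_empty_bundle_writes_valid_files(self, tmp_path):
        nb = null_dataset(
            SyntheticConfig(n_genes=0, n_mirnas=0, n_true_pairs=0, n_pathways=0, n_pwms=0)
        )
        manifest = write_bundle(nb, tmp_path)
        back = read_bundle(tmp_path)
        assert len(back["gene_expr"]) == 0
        assert len(back["predictions"]) == 0
        assert len(manifest) >= 8

    def test_promoters_round_trip_through_extraction(self, small_bundle):
        # extracting from the written genome+TSS reproduces full promoters
        for rec in small_bundle.promoters[:10]:
            assert len(rec.sequence) == small_bundle.config.promoter_len
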