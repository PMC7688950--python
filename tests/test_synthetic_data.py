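import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tripflow.barcode_calling import hamming
from tripflow.pool_decoding import CapacityError, make_design
from tripflow.synthetic_data import (
    BARCODE_ALPHABET,
    GroundTruth,
    SyntheticConfig,
    generate_truth,
    simulate_barcode_reads,
    simulate_epigenome,
    simulate_flow_events,
    simulate_pool_counts,
    simulate_screen_dataset,
    simulate_trip_reads,
    write_dataset,
)

TINY = dict(n_tf_tracks=2, n_states=3, chrom_lengths=(("chr1", 1_000_000),))


class TestConfig:
    def test_capacity_invariant(self):
        with pytest.raises(CapacityError):
            SyntheticConfig(n_clones=20, n_pools=5, signature_weight=2, **TINY)

    def test_weight_below_pools(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_clones=1, n_pools=4, signature_weight=4, **TINY)

    def test_positive_counts(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_clones=0, **TINY)

    def test_error_rate_range(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_clones=2, per_base_error_rate=1.0, **TINY)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        raw = {
            "n_clones": 5, "seed": 3, "n_tf_tracks": 2, "n_states": 3,
            "chrom_lengths": [["chr1", 500000]],
        }
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(raw))
        cfg = SyntheticConfig.from_yaml(p)
        assert cfg.n_clones == 5
        assert cfg.chrom_lengths == (("chr1", 500000),)


class TestGenerateTruth:
    def test_determinism(self):
        cfg = SyntheticConfig(n_clones=15, seed=1, **TINY)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        assert t1.barcodes == t2.barcodes
        assert t1.sites == t2.sites
        assert t1.expression == t2.expression
        pd.testing.assert_frame_equal(t1.features, t2.features, check_exact=True)

    def test_null_effects_identical_expression(self):
        cfg = SyntheticConfig(
            n_clones=12, seed=2, n_tf_effects_mean=0, n_tf_effects_noise=0,
            n_state_effects_mean=0, n_state_effects_noise=0,
            residual_sd_mean=0.0, residual_sd_noise=0.0, **TINY,
        )
        truth = generate_truth(cfg)
        assert len(set(truth.expression.values())) == 1

    def test_single_effect_perfect_rank_correlation(self):
        cfg = SyntheticConfig(
            n_clones=30, seed=3,
            tf_effects_mean=(1.0, 0.0), tf_effects_noise=(0.0, 0.0),
            state_effects_mean=(0.0, 0.0, 0.0), state_effects_noise=(0.0, 0.0, 0.0),
            residual_sd_mean=0.0, residual_sd_noise=0.0, **TINY,
        )
        truth = generate_truth(cfg)
        feat = truth.features["enr_TF00"]
        means = pd.Series(truth.log10_mean).loc[feat.index]
        rho = stats.spearmanr(feat, means).statistic
        assert rho == pytest.approx(1.0)

    def test_mean_cv2_anticorrelation(self):
        cfg = SyntheticConfig(
            n_clones=60, seed=4, n_tf_effects_mean=0, n_tf_effects_noise=0,
            n_state_effects_mean=0, n_state_effects_noise=0,
            residual_sd_mean=0.3, residual_sd_noise=0.05, **TINY,
        )
        truth = generate_truth(cfg)
        m = pd.Series(truth.log10_mean)
        c = pd.Series(truth.log10_cv2).loc[m.index]
        assert stats.spearmanr(m, c).statistic < -0.5

    def test_barcode_alphabet_and_distance(self, small_truth):
        barcodes = list(small_truth.barcodes.values())
        assert all(set(b) <= set(BARCODE_ALPHABET) for b in barcodes)
        assert all(len(b) == 16 for b in barcodes)
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1:]:
                assert hamming(a, b) > 2

    def test_sites_in_bounds(self, small_truth, small_config):
        lengths = dict(small_config.chrom_lengths)
        for chrom, pos, strand in small_truth.sites.values():
            assert 0 <= pos < lengths[chrom]
            assert strand in "+-"

    def test_lognormal_params_match_targets(self, small_truth):
        for clone, (mu, sigma) in small_truth.expression.items():
            assert sigma > 0 and np.isfinite(mu)
            mean = np.exp(mu + sigma**2 / 2)
            cv2 = np.exp(sigma**2) - 1
            assert np.log10(mean) == pytest.approx(small_truth.log10_mean[clone], abs=1e-9)
            assert np.log10(cv2) == pytest.approx(small_truth.log10_cv2[clone], abs=1e-9)

    def test_json_round_trip(self, small_truth, tmp_path):
        p = tmp_path / "truth.json"
        small_truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back.barcodes == small_truth.barcodes
        assert back.sites == small_truth.sites
        assert back.expression == small_truth.expression
        pd.testing.assert_frame_equal(back.features, small_truth.features)


class TestBarcodeReads:
    def test_noiseless_reads_equal_truth(self):
        cfg = SyntheticConfig(
            n_clones=3, seed=5, per_base_error_rate=0.0, reads_per_barcode=100,
            **TINY,
        )
        truth = generate_truth(cfg)
        reads = simulate_barcode_reads(truth, cfg)
        assert len(reads) == 300  # conservation
        assert {r.sequence for r in reads} == set(truth.barcodes.values())

    def test_mutation_fraction_binomial(self):
        cfg = SyntheticConfig(
            n_clones=10, seed=6, per_base_error_rate=0.01, reads_per_barcode=1000,
            **TINY,
        )
        truth = generate_truth(cfg)
        reads = simulate_barcode_reads(truth, cfg)
        true_set = set(truth.barcodes.values())
        n = len(reads)
        mutated = sum(r.sequence not in true_set for r in reads)
        p = 1 - 0.99**16
        sd = np.sqrt(n * p * (1 - p))
        assert abs(mutated - n * p) <= 3 * sd

    def test_qualities_reflect_error_rate(self):
        cfg = SyntheticConfig(
            n_clones=2, seed=7, per_base_error_rate=0.01, reads_per_barcode=5,
            **TINY,
        )
        reads = simulate_barcode_reads(generate_truth(cfg), cfg)
        assert all(q == 20 for r in reads for q in r.qualities)


class TestPoolCounts:
    def test_noiseless_counts_only_in_signature(self, small_truth, small_config):
        design = make_design(
            small_config.n_clones, 18, 4, scheme="balanced",
            clone_ids=small_config.clone_ids,
        )
        pools = simulate_pool_counts(small_truth, design, small_config)
        for clone in small_config.clone_ids:
            row = pools.table.counts.loc[small_truth.barcodes[clone]]
            nonzero = frozenset(int(p) for p, v in row.items() if v > 0)
            assert nonzero == design.assignments[clone]
            assert row.sum() == small_config.reads_per_barcode

    def test_all_pool_depths_positive(self, small_truth, small_config):
        design = make_design(
            small_config.n_clones, 18, 4, scheme="balanced",
            clone_ids=small_config.clone_ids,
        )
        pools = simulate_pool_counts(small_truth, design, small_config)
        assert (pools.table.pool_depths > 0).all()

    def test_merged_pair_union(self):
        cfg = SyntheticConfig(
            n_clones=40, seed=8, merged_pair_rate=0.2, reads_per_barcode=500,
            **TINY,
        )
        truth = generate_truth(cfg)
        design = make_design(40, 18, 4, scheme="balanced", clone_ids=cfg.clone_ids)
        pools = simulate_pool_counts(truth, design, cfg)
        assert len(pools.merged_pairs) == 8
        for barcode, a, b in pools.merged_pairs:
            union = design.assignments[a] | design.assignments[b]
            assert len(union) <= 8
            row = pools.table.counts.loc[barcode]
            nonzero = frozenset(int(p) for p, v in row.items() if v > 0)
            assert nonzero == union
            # the partner clone's own barcode is gone
            assert truth.barcodes[b] not in pools.table.counts.index

    def test_double_barcode_injection(self):
        cfg = SyntheticConfig(
            n_clones=30, seed=9, double_barcode_rate=0.1, **TINY,
        )
        truth = generate_truth(cfg)
        design = make_design(30, 18, 4, scheme="balanced", clone_ids=cfg.clone_ids)
        pools = simulate_pool_counts(truth, design, cfg)
        assert len(pools.double_barcodes) == 3
        for clone, extra in pools.double_barcodes.items():
            row = pools.table.counts.loc[extra]
            nonzero = frozenset(int(p) for p, v in row.items() if v > 0)
            assert nonzero == design.assignments[clone]


class TestTripReads:
    def test_noiseless_reads_at_true_sites(self, small_truth, small_config):
        reads = simulate_trip_reads(small_truth, small_config)
        assert set(reads["replicate"]) == {1, 2}
        for clone, (chrom, pos, strand) in small_truth.sites.items():
            sub = reads[reads["barcode"] == small_truth.barcodes[clone]]
            assert (sub["chrom"] == chrom).all()
            assert (sub["pos"] == pos).all()
            assert (sub["strand"] == strand).all()

    def test_discordant_fraction_binomial(self):
        cfg = SyntheticConfig(
            n_clones=100, seed=10, trip_discordant_fraction=0.1,
            trip_reads_per_barcode=5, **TINY,
        )
        truth = generate_truth(cfg)
        reads = simulate_trip_reads(truth, cfg)
        n_moved = 0
        for clone, (chrom, pos, strand) in truth.sites.items():
            rep2 = reads[
                (reads["barcode"] == truth.barcodes[clone]) & (reads["replicate"] == 2)
            ]
            if not ((rep2["chrom"] == chrom) & (rep2["pos"] == pos)).all():
                n_moved += 1
        assert n_moved == 10  # deterministic count of injected discordants


class TestFlowEvents:
    def test_degenerate_sigma_gives_tiny_cv2(self, small_config):
        truth = generate_truth(small_config)
        clone = "clone0000"
        truth.expression[clone] = (5.0, 1e-6)
        cfg = SyntheticConfig(**{**small_config.__dict__, "n_flow_replicates": 1})
        ev = simulate_flow_events(truth, cfg)
        from tripflow.expression_stats import gate_events, summarize

        well = ev[(ev.clone_id == clone) & (~ev.is_control)]
        assert summarize(gate_events(well)["clover"]).cv2 < 1e-9

    def test_event_schema_and_counts(self, small_truth, small_config):
        ev = simulate_flow_events(small_truth, small_config)
        n = small_config.cells_per_clone
        assert len(ev) == small_config.n_clones * small_config.n_flow_replicates * n
        assert (ev[["fsc", "ssc", "clover", "irfp"]] >= 0).all().all()
        frac_ctrl = ev["is_control"].mean()
        assert frac_ctrl == pytest.approx(small_config.control_fraction, abs=1e-6)


class TestEpigenome:
    def test_segmentation_partitions_every_chromosome(self, small_truth, small_config):
        _, seg = simulate_epigenome(small_truth, small_config)
        lengths = dict(small_config.chrom_lengths)
        for chrom, grp in seg.intervals.groupby("chrom"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == lengths[chrom]
            assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()

    def test_tracks_cover_genome(self, small_truth, small_config):
        tracks, _ = simulate_epigenome(small_truth, small_config)
        assert len(tracks) == small_config.n_tf_tracks
        for t in tracks:
            for chrom, length in small_config.chrom_lengths:
                assert len(t.values[chrom]) == -(-length // t.bin_size)
                assert (t.values[chrom] >= 0).all()

    def test_deterministic(self, small_config):
        t1, s1 = simulate_epigenome(None, small_config)
        t2, s2 = simulate_epigenome(None, small_config)
        np.testing.assert_array_equal(t1[0].values["chr1"], t2[0].values["chr1"])
        pd.testing.assert_frame_equal(s1.intervals, s2.intervals)


class TestScreenDataset:
    def test_planted_effects_shape(self):
        X, y, planted = simulate_screen_dataset(50, 30, 4, seed=0)
        assert X.shape == (50, 30)
        assert len(planted) == 4
        assert set(planted) <= set(X.columns)

    def test_deterministic(self):
        a = simulate_screen_dataset(20, 10, 2, seed=5)
        b = simulate_screen_dataset(20, 10, 2, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_series_equal(a[1], b[1])
        assert a[2] == b[2]


def test_write_dataset_produces_all_inputs(tmp_path):
    cfg = SyntheticConfig(
        n_clones=5, seed=30, reads_per_barcode=20, trip_reads_per_barcode=5,
        cells_per_clone=200, **TINY,
    )
    paths = write_dataset(cfg, tmp_path / "out")
    for key in ("truth", "reads", "design", "pool_counts", "trip_rep1",
                "trip_rep2", "flow_events", "tracks", "states"):
        assert paths[key].exists(), key
    back = GroundTruth.from_json(paths["truth"])
    assert len(back.barcodes) == 5
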