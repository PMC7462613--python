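import numpy as np
import pandas as pd
import pytest

from sortscan.counting import count_barcodes
from sortscan.synthetic import (
    EffectModel,
    SimConfig,
    simulate_barcodes,
    simulate_reads,
    simulate_sort,
    simulate_truth,
    write_fastq,
)


class TestConfigValidation:
    def test_overlapping_tmds_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(tmd_segments=((10, 30), (25, 40)))

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(cells_sorted=0)

    def test_bad_mixture_weights(self):
        with pytest.raises(ValueError):
            EffectModel(mixture_weights=(0.5, 0.5, 0.5))


class TestSimulateTruth:
    def test_deterministic(self, small_config):
        a = simulate_truth(small_config).variants
        b = simulate_truth(small_config).variants
        pd.testing.assert_frame_equal(a, b)

    def test_synonymous_near_one_nonsense_near_zero(self, small_config):
        truth = simulate_truth(small_config).variants
        syn = truth[truth.mut_class == "synonymous"].true_abundance
        non = truth[truth.mut_class == "nonsense"].true_abundance
        assert abs(syn.mean() - 1.0) < 0.1
        assert abs(non.mean()) < 0.1

    def test_zero_tmd_low_fraction_matches_mixture_weight(self):
        """With no TMDs the low-component rate is the background weight."""
        config = SimConfig(seed=3, tmd_segments=())
        truth = simulate_truth(config).variants
        mis = truth[(truth.mut_class == "missense") & ~truth.is_active_site]
        low_frac = (mis.true_abundance < 0.25).mean()
        w_low = config.effect_model.mixture_weights[2]
        n = len(mis)
        se = np.sqrt(w_low * (1 - w_low) / n)
        assert abs(low_frac - w_low) < 3 * se

    def test_region_labels_match_segments(self, default_config):
        truth = simulate_truth(default_config).variants
        tm = set()
        for s, e in default_config.tmd_segments:
            tm.update(range(s, e + 1))
        in_tm = truth[truth.position.isin(tm)]
        out_tm = truth[~truth.position.isin(tm)]
        assert (in_tm.region_label == "TM").all()
        assert set(out_tm.region_label) <= {"cytoplasmic", "lumenal"}

    def test_active_sites_low_activity_wt_abundance(self, default_config):
        truth = simulate_truth(default_config)
        site_rows = truth.variants[
            truth.variants.is_active_site
            & (truth.variants.mut_class == "missense")
        ]
        assert len(truth.active_site_positions) == default_config.effect_model.n_active_sites
        assert site_rows.groupby("position").size().min() >= 4
        assert site_rows.true_activity.mean() < 0.3
        assert site_rows.true_abundance.mean() > 0.7


class TestSimulateSort:
    def test_total_cells_conserved(self, small_config):
        truth = simulate_truth(small_config)
        sort = simulate_sort(truth, small_config)
        totals = sort.cell_counts.sum(axis=(1, 2))
        assert (totals == small_config.cells_sorted).all()

    def test_identical_values_split_uniformly(self):
        config = SimConfig(
            seed=5, n_positions=20, tmd_segments=(), n_synonymous=5, n_nonsense=5,
            cells_sorted=100_000, cell_noise_sd=1e-9, n_replicates=1,
            library_skew_concentration=1e6,
        )
        truth = simulate_truth(config)
        truth.variants["true_abundance"] = 1.0
        sort = simulate_sort(truth, config)
        bin_totals = sort.cell_counts[0].sum(axis=1)
        # noise is the only tie-breaker, so quartile gates cut equal mass
        assert np.allclose(bin_totals / bin_totals.sum(), 0.25, atol=0.01)

    def test_two_groups_separate_at_median(self):
        """Low group lands in bins 1-2, high group in bins 3-4."""
        config = SimConfig(
            seed=11, n_positions=40, tmd_segments=(), n_synonymous=5, n_nonsense=5,
            cells_sorted=50_000, cell_noise_sd=0.01, n_replicates=2,
            library_skew_concentration=1e6,
        )
        truth = simulate_truth(config)
        n = len(truth.variants)
        truth.variants["true_abundance"] = np.where(np.arange(n) % 2 == 0, 0.0, 1.0)
        sort = simulate_sort(truth, config)
        low = np.arange(n) % 2 == 0
        for rep in range(2):
            low_cells = sort.cell_counts[rep][:, low]
            high_cells = sort.cell_counts[rep][:, ~low]
            # multinomial jitter in group totals lets a sliver of the larger
            # group spill across the median gate; the split is otherwise clean
            assert low_cells[2:].sum() <= 0.01 * low_cells.sum()
            assert high_cells[:2].sum() <= 0.01 * high_cells.sum()

    def test_gates_are_pooled_quartiles(self, small_config):
        truth = simulate_truth(small_config)
        sort = simulate_sort(truth, small_config)
        assert sort.gates.shape == (small_config.n_replicates, 3)
        assert (np.diff(sort.gates, axis=1) > 0).all()

    def test_warns_when_cells_below_variants(self, small_config):
        truth = simulate_truth(small_config)
        import dataclasses

        tiny = dataclasses.replace(small_config, cells_sorted=10)
        with pytest.warns(UserWarning, match="dropout"):
            simulate_sort(truth, tiny)

    def test_empty_truth_error(self, small_config):
        truth = simulate_truth(small_config)
        truth.variants = truth.variants.iloc[:0]
        with pytest.raises(ValueError):
            simulate_sort(truth, small_config)


@pytest.fixture(scope="module")
def setup(small_config):
    truth = simulate_truth(small_config)
    barcode_map = simulate_barcodes(truth, small_config)
    sort = simulate_sort(truth, small_config)
    reads = simulate_reads(sort, barcode_map, small_config)
    return truth, barcode_map, sort, reads


class TestSimulateReads:
    def test_depth_conserved(self, setup, small_config):
        _, _, _, reads = setup
        per_bin = reads.groupby(["replicate", "bin"])["count"].sum()
        assert (per_bin == small_config.reads_per_bin).all()

    def test_every_variant_barcoded(self, setup):
        truth, barcode_map, _, _ = setup
        assert set(barcode_map["variant"]) == set(truth.variants["variant"])

    def test_barcodes_unique(self, setup):
        _, barcode_map, _, _ = setup
        assert barcode_map["barcode"].is_unique

    def test_fastq_round_trip_exact(self, setup, small_config, tmp_path):
        """Error rate 0: counting the emitted FASTQ reproduces the table."""
        _, barcode_map, _, reads = setup
        paths = write_fastq(reads, tmp_path, small_config, error_rate=0.0)
        lookup = dict(zip(barcode_map["barcode"], barcode_map["variant"]))
        variant_of = barcode_map.set_index("barcode")["variant"]
        for path in paths:
            rep, bin_label = path.stem.rsplit("_bin", 1)
            table = count_barcodes(path, lookup, rep, int(bin_label))
            emitted = (
                reads[(reads.replicate == rep) & (reads["bin"] == int(bin_label))]
                .assign(variant=lambda d: d.barcode.map(variant_of))
                .groupby("variant")["count"]
                .sum()
            )
            assert table.n_filtered_quality == 0
            assert table.n_unmapped_barcodes == 0
            assert dict(emitted[emitted > 0]) == table.counts

    def test_depth_scaling_of_frequency_error(self):
        """Doubling depth shrinks the frequency SE by ~1/sqrt(2)
        (binomial sampling); checked over 20 sequencing realizations."""
        config = SimConfig(
            seed=2, n_positions=12, tmd_segments=(), n_synonymous=3, n_nonsense=3,
            cells_sorted=5_000, reads_per_bin=2_000, n_replicates=1,
        )
        truth = simulate_truth(config)
        barcode_map = simulate_barcodes(truth, config)
        sort = simulate_sort(truth, config)
        true_freq = sort.cell_counts[0].sum(axis=0) / config.cells_sorted

        def freq_sd(depth_config, stream_base):
            freqs = []
            for k in range(20):
                reads = simulate_reads(
                    sort, barcode_map, depth_config, stream=stream_base + k
                )
                per_variant = (
                    reads.merge(barcode_map[["barcode", "variant"]], on="barcode")
                    .groupby("variant")["count"].sum()
                    .reindex(truth.variants["variant"])
                    .fillna(0.0)
                )
                freqs.append(per_variant.to_numpy() / per_variant.sum())
            return np.std(freqs, axis=0, ddof=1)

        import dataclasses

        sd1 = freq_sd(config, 100)
        sd2 = freq_sd(dataclasses.replace(config, reads_per_bin=4_000), 200)
        common = true_freq > 0.01  # well-observed variants only
        ratio = np.mean(sd2[common] / sd1[common])
        assert abs(ratio - 1 / np.sqrt(2)) < 0.25 / np.sqrt(2)

    def test_bitwise_reproducibility(self, small_config):
        truth = simulate_truth(small_config)
        bm = simulate_barcodes(truth, small_config)
        r1 = simulate_reads(simulate_sort(truth, small_config), bm, small_config)
        r2 = simulate_reads(simulate_sort(truth, small_config), bm, small_config)
        pd.testing.assert_frame_equal(r1, r2)
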