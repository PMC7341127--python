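"""Panel-scale eQTL mapping, FDR thresholding and hotspot detection."""

import math

import numpy as np
import pandas as pd
import pytest

from riailmap import (
    classify_eqtl,
    detect_hotspots,
    hotspot_permutation_check,
    map_expression_panel,
    permutation_fdr_threshold,
    poisson_critical_count,
    simulate_expression_panel,
)
from riailmap.eqtl import genome_bins
from riailmap.linkage import lod_scan


def poisson_critical_oracle(lam, n_bins, percentile=0.99):
    """Direct CDF summation: smallest k with sum_{i<=k} e^-lam lam^i/i! >= q."""
    q = 1.0 - (1.0 - percentile) / n_bins
    cdf, k = 0.0, -1
    while cdf < q:
        k += 1
        cdf += math.exp(-lam) * lam**k / math.factorial(k)
    return k


def make_records(chroms, cms, lods=None, classification="distant"):
    n = len(chroms)
    return pd.DataFrame(
        {
            "probe": [f"p{i}" for i in range(n)],
            "peak_chrom": chroms,
            "peak_cm": cms,
            "lod": lods if lods is not None else [10.0] * n,
            "classification": [classification] * n,
        }
    )


class TestClassification:
    @pytest.mark.parametrize(
        "peak_chrom,peak_bp,probe_chrom,start,expected",
        [
            ("I", 2_000_000, "I", 1_000_001, "local"),   # 999,999 bp apart
            ("I", 2_000_000, "I", 1_000_000, "local"),   # exactly 1 Mb
            ("I", 2_000_000, "I", 999_999, "distant"),   # 1,000,001 bp apart
            ("I", 500, "II", 500, "distant"),            # same coordinate, other chrom
        ],
    )
    def test_one_megabase_rule(self, peak_chrom, peak_bp, probe_chrom, start, expected):
        assert classify_eqtl(peak_chrom, peak_bp, probe_chrom, start) == expected

    def test_symmetric_under_coordinate_reversal(self):
        # distance is absolute: swapping which side of the probe the peak falls on
        assert classify_eqtl("I", 1_000_000, "I", 1_500_000) == classify_eqtl(
            "I", 2_000_000, "I", 1_500_000
        )


class TestExpressionScan:
    def test_block_scan_matches_per_probe_loop(self, rng):
        from riailmap import generate_marker_map, simulate_riail_genotypes

        mmap = generate_marker_map(2, 25, 50.0)
        panel = simulate_riail_genotypes(mmap, 100, seed=31)
        expr = pd.DataFrame(
            rng.standard_normal((100, 50)),
            index=panel.lines,
            columns=[f"probe_{j:05d}" for j in range(50)],
        )
        from riailmap.eqtl import _max_lod_per_probe

        max_lod, argmax = _max_lod_per_probe(panel.allele_matrix(), expr.to_numpy(), block=7)
        for j in range(50):
            scan = lod_scan(panel, expr.iloc[:, j])
            lods = scan.table["lod"].to_numpy()
            assert max_lod[j] == pytest.approx(np.nanmax(lods), abs=1e-10)
            assert argmax[j] == int(np.nanargmax(lods))

    def test_planted_eqtl_recovered_on_causal_chromosome(self, riail_panel):
        expr, pos, truth = simulate_expression_panel(
            riail_panel, 100, local_fraction=0.5, effect_size=1.5, seed=17
        )
        records = map_expression_panel(riail_panel, expr, pos, threshold=4.0)
        marker_chrom = riail_panel.marker_map.set_index("marker")["chrom"]
        signal = truth[truth["cls"] == "local"].set_index("probe")
        found = records.set_index("probe")
        recovered = [
            p for p in signal.index
            if p in found.index
            and found.loc[p, "peak_chrom"] == marker_chrom[signal.loc[p, "causal_marker"]]
        ]
        assert len(recovered) >= 0.95 * len(signal)

    def test_null_panel_yields_no_records_at_high_threshold(self, riail_panel):
        expr, pos, _ = simulate_expression_panel(riail_panel, 50, local_fraction=0.0, seed=9)
        records = map_expression_panel(riail_panel, expr, pos, threshold=6.0)
        assert len(records) <= 1

    def test_misaligned_lines_rejected(self, riail_panel, rng):
        expr = pd.DataFrame(
            rng.standard_normal((10, 5)), index=[f"x{i}" for i in range(10)],
            columns=[f"p{i}" for i in range(5)],
        )
        pos = pd.DataFrame({"probe": expr.columns, "chrom": "I", "start": 1})
        with pytest.raises(ValueError, match="align"):
            map_expression_panel(riail_panel, expr, pos, threshold=3.0)


class TestFDRThreshold:
    def test_deterministic_under_seed(self, small_panel):
        expr, _, _ = simulate_expression_panel(
            small_panel, 60, local_fraction=0.2, effect_size=1.0, seed=2
        )
        t1 = permutation_fdr_threshold(small_panel, expr, n_perm=3, seed=5)
        t2 = permutation_fdr_threshold(small_panel, expr, n_perm=3, seed=5)
        assert t1 == t2

    def test_null_panel_threshold_near_grid_top(self, small_panel):
        expr, _, _ = simulate_expression_panel(small_panel, 80, local_fraction=0.0, seed=3)
        threshold, table = permutation_fdr_threshold(
            small_panel, expr, n_perm=5, seed=1, full=True
        )
        low = table[table["threshold"] < 3.5]
        assert (low["fdr"] > 0.5).mean() > 0.8  # FDR near 1 below extreme thresholds
        assert np.isnan(threshold) or threshold > 3.5

    def test_signal_panel_keeps_fdr_below_target(self, riail_panel):
        expr, _, truth = simulate_expression_panel(
            riail_panel, 200, local_fraction=0.2, effect_size=0.8, seed=4
        )
        threshold = permutation_fdr_threshold(riail_panel, expr, n_perm=10, seed=4)
        from riailmap.eqtl import _max_lod_per_probe

        max_lod, _ = _max_lod_per_probe(riail_panel.allele_matrix(), expr.to_numpy())
        reported = truth.loc[max_lod >= threshold, "cls"]
        fdr = (reported == "null").mean()
        assert fdr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / max(len(reported), 1))

    def test_empty_grid_rejected(self, small_panel, rng):
        expr = pd.DataFrame(
            rng.standard_normal((small_panel.n_lines, 5)), index=small_panel.lines,
            columns=[f"p{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="grid"):
            permutation_fdr_threshold(small_panel, expr, grid=np.array([]), seed=0)


class TestHotspots:
    def test_critical_count_matches_direct_summation(self):
        for lam, n_bins in [(3.91, 60), (1.0, 66), (10.0, 20), (0.5, 100)]:
            assert poisson_critical_count(lam, n_bins) == poisson_critical_oracle(lam, n_bins)
            assert poisson_critical_count(lam, n_bins) >= lam

    def test_bins_cover_genome_and_conserve_counts(self, riail_panel):
        rng = np.random.default_rng(0)
        mmap = riail_panel.marker_map
        idx = rng.integers(0, len(mmap), 200)
        records = make_records(
            mmap["chrom"].to_numpy()[idx], mmap["cm"].to_numpy()[idx]
        )
        scan = detect_hotspots(records, mmap)
        assert scan.bins["count"].sum() == len(records)
        assert scan.n_bins == 66  # 6 chromosomes x 11 bins for 50 cM at 5 cM

    def test_planted_hotspot_flagged_and_null_not(self, riail_panel):
        mmap = riail_panel.marker_map
        n_bins = len(genome_bins(mmap))
        rng = np.random.default_rng(42)
        flagged_planted, flagged_null = 0, 0
        for _ in range(100):
            idx = rng.integers(0, len(mmap), 230)
            null_rec = make_records(mmap["chrom"].to_numpy()[idx], mmap["cm"].to_numpy()[idx])
            hot_rec = make_records(["III"] * 50, [22.0] * 50)
            planted = pd.concat([null_rec, hot_rec], ignore_index=True)
            scan = detect_hotspots(planted, mmap)
            hot_bin = scan.bins[
                (scan.bins["chrom"] == "III") & (scan.bins["start_cm"] == 20.0)
            ]
            others = scan.bins.drop(hot_bin.index)
            flagged_planted += bool(hot_bin["significant"].iloc[0]) and not others["significant"].any()
            null_scan = detect_hotspots(null_rec, mmap)
            flagged_null += null_scan.bins["significant"].any()
        assert flagged_planted >= 95
        assert flagged_null <= 5

    def test_lod_floor_monotone(self, riail_panel):
        mmap = riail_panel.marker_map
        rng = np.random.default_rng(1)
        idx = rng.integers(0, len(mmap), 150)
        records = make_records(
            mmap["chrom"].to_numpy()[idx],
            mmap["cm"].to_numpy()[idx],
            lods=rng.uniform(2, 12, 150),
        )
        prev = detect_hotspots(records, mmap).bins["count"]
        for floor in (4, 6, 8):
            cur = detect_hotspots(records, mmap, lod_floor=floor).bins["count"]
            assert (cur <= prev).all()
            prev = cur

    def test_lambda_all_option_uses_every_record(self, riail_panel):
        mmap = riail_panel.marker_map
        rng = np.random.default_rng(2)
        idx = rng.integers(0, len(mmap), 100)
        records = make_records(mmap["chrom"].to_numpy()[idx], mmap["cm"].to_numpy()[idx])
        records.loc[:49, "classification"] = "local"
        distant_only = detect_hotspots(records, mmap)
        every = detect_hotspots(records, mmap, lambda_all=True)
        assert every.lam == pytest.approx(2 * distant_only.lam)

    def test_invalid_bin_width_rejected(self, riail_panel):
        records = make_records(["I"], [10.0])
        with pytest.raises(ValueError):
            detect_hotspots(records, riail_panel.marker_map, bin_cm=0.0)


class TestPermutationCheck:
    def test_uniform_null_rarely_spurious(self, riail_panel):
        mmap = riail_panel.marker_map
        rng = np.random.default_rng(3)
        idx = rng.integers(0, len(mmap), 250)
        records = make_records(mmap["chrom"].to_numpy()[idx], mmap["cm"].to_numpy()[idx])
        counts = hotspot_permutation_check(records, mmap, n_datasets=20, seed=6)
        assert len(counts) == 20
        assert np.mean(counts) < 1.0

    def test_zero_datasets_empty(self, riail_panel):
        records = make_records(["I"], [10.0])
        assert hotspot_permutation_check(records, riail_panel.marker_map, n_datasets=0) == []

    def test_seeded_reproducibility(self, riail_panel):
        mmap = riail_panel.marker_map
        rng = np.random.default_rng(4)
        idx = rng.integers(0, len(mmap), 100)
        records = make_records(mmap["chrom"].to_numpy()[idx], mmap["cm"].to_numpy()[idx])
        a = hotspot_permutation_check(records, mmap, n_datasets=5, seed=9)
        b = hotspot_permutation_check(records, mmap, n_datasets=5, seed=9)
        assert a == b
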