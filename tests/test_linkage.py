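"""LOD scan, permutation threshold, forward search and QTL annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riailmap import (
    annotate_qtl,
    forward_search,
    lod_from_r,
    lod_scan,
    permutation_threshold,
    simulate_trait,
)
from riailmap.linkage import LODScan, variance_explained_from_lod
from riailmap.sim import GenotypePanel, generate_marker_map


def naive_lod_scan(panel, trait):
    """Independent per-marker oracle: corrcoef loop over markers."""
    y = np.asarray(trait, dtype=float)
    out = []
    for marker in panel.markers:
        g = panel.genotype_at(marker).to_numpy()
        ok = ~np.isnan(g) & ~np.isnan(y)
        n = ok.sum()
        if n < 3 or np.ptp(g[ok]) == 0:
            out.append(np.nan)
            continue
        r = np.corrcoef(g[ok], y[ok])[0, 1]
        out.append(-n * np.log(max(1 - r**2, 1e-16)) / (2 * np.log(10)))
    return np.array(out)


class TestLODFormula:
    def test_printed_value(self):
        # n=100, R=0.5 evaluates to 6.247 at printed precision
        assert lod_from_r(0.5, 100) == pytest.approx(6.247, abs=5e-4)

    def test_zero_correlation_gives_zero(self):
        assert lod_from_r(0.0, 50) == 0.0

    def test_perfect_correlation_capped_finite(self):
        lod = lod_from_r(1.0, 100)
        assert np.isfinite(lod)
        assert lod == pytest.approx(-100 * np.log(1e-16) / (2 * np.log(10)))

    def test_variance_explained_inverts_lod(self):
        # round-trip: R^2 -> LOD -> variance explained
        for r in (0.1, 0.3, 0.5, 0.9):
            lod = lod_from_r(r, 100)
            assert variance_explained_from_lod(lod, 100) == pytest.approx(r**2, abs=1e-10)
        assert variance_explained_from_lod(6.247, 100) == pytest.approx(0.25, abs=1e-4)


class TestLODScan:
    def test_matches_naive_oracle(self, rng):
        mmap = generate_marker_map(2, 25, 50.0)
        from riailmap import simulate_riail_genotypes

        panel = simulate_riail_genotypes(mmap, 100, seed=21)
        trait = pd.Series(rng.standard_normal(100), index=panel.lines)
        scan = lod_scan(panel, trait)
        expected = naive_lod_scan(panel, trait)
        np.testing.assert_allclose(scan.table["lod"], expected, atol=1e-10)

    def test_pairwise_complete_with_missing_genotypes(self, rng):
        mmap = generate_marker_map(1, 10, 50.0)
        from riailmap import simulate_riail_genotypes

        panel = simulate_riail_genotypes(mmap, 80, missing_rate=0.15, seed=3)
        trait = pd.Series(rng.standard_normal(80), index=panel.lines)
        scan = lod_scan(panel, trait)
        np.testing.assert_allclose(scan.table["lod"], naive_lod_scan(panel, trait), atol=1e-10)
        assert scan.table["n"].min() < 80  # n varies per marker

    def test_affine_invariance(self, small_panel, rng):
        trait = pd.Series(rng.standard_normal(small_panel.n_lines), index=small_panel.lines)
        base = lod_scan(small_panel, trait).table["lod"]
        shifted = lod_scan(small_panel, 3.0 * trait - 7.0).table["lod"]
        np.testing.assert_allclose(base, shifted, atol=1e-10)

    def test_monomorphic_marker_reported_missing(self):
        mmap = generate_marker_map(1, 3, 50.0)
        geno = pd.DataFrame(
            np.array([[0, 0, 1], [1, 0, 0], [0, 0, 1], [1, 0, 0]]),
            index=list("abcd"), columns=mmap["marker"],
        )
        panel = GenotypePanel(geno, mmap)
        scan = lod_scan(panel, pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert np.isnan(scan.table["lod"].iloc[1])
        assert np.isfinite(scan.table["lod"].iloc[0])

    def test_all_missing_trait_rejected(self, small_panel):
        trait = pd.Series(np.nan, index=small_panel.lines)
        with pytest.raises(ValueError):
            lod_scan(small_panel, trait)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(r=st.floats(-0.999, 0.999), n=st.integers(3, 1000))
    def test_lod_nonnegative_and_even_in_r(self, r, n):
        lod = lod_from_r(r, n)
        assert lod >= 0
        assert lod == pytest.approx(lod_from_r(-r, n), rel=1e-12)


class TestPermutationThreshold:
    def test_planted_qtl_clears_threshold(self, riail_panel):
        trait = simulate_trait(riail_panel, [(riail_panel.markers[100], 1.0)], 0.6, seed=8)
        thr = permutation_threshold(riail_panel, trait, n_perm=200, seed=8)
        assert lod_scan(riail_panel, trait).max_lod() > 2 * thr

    def test_alpha_one_returns_minimum_of_maxima(self, small_panel, rng):
        trait = pd.Series(rng.standard_normal(small_panel.n_lines), index=small_panel.lines)
        thr = permutation_threshold(small_panel, trait, n_perm=100, alpha=1.0, seed=1)
        from riailmap.linkage import max_lod_permutations

        maxima = max_lod_permutations(small_panel, trait, 100, seed=1)
        assert thr == pytest.approx(maxima.min())

    def test_distribution_invariant_to_trait_relabeling(self, small_panel, rng):
        trait = pd.Series(rng.standard_normal(small_panel.n_lines), index=small_panel.lines)
        shuffled = pd.Series(
            trait.to_numpy()[rng.permutation(small_panel.n_lines)], index=small_panel.lines
        )
        t1 = permutation_threshold(small_panel, trait, n_perm=300, seed=5)
        t2 = permutation_threshold(small_panel, shuffled, n_perm=300, seed=5)
        assert t1 == pytest.approx(t2, abs=0.3)

    def test_low_n_perm_warns(self, small_panel, rng):
        trait = pd.Series(rng.standard_normal(small_panel.n_lines), index=small_panel.lines)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_threshold(small_panel, trait, n_perm=50, seed=1)


class TestAnnotate:
    def _toy_scan(self, lods):
        mmap = generate_marker_map(1, len(lods), 50.0)
        table = mmap.copy()
        table["n"] = 100
        table["r"] = np.sqrt(1 - 10 ** (-2 * np.asarray(lods, float) / 100))
        table["lod"] = lods
        return LODScan(trait="toy", table=table), mmap

    def _toy_panel_trait(self, n_markers):
        from riailmap import simulate_riail_genotypes

        mmap = generate_marker_map(1, n_markers, 50.0)
        panel = simulate_riail_genotypes(mmap, 20, seed=2)
        trait = pd.Series(np.arange(20.0), index=panel.lines)
        return panel, trait

    def test_interval_bounds_are_first_markers_below_drop(self):
        scan, _ = self._toy_scan([1, 2, 5, 2, 1])
        panel, trait = self._toy_panel_trait(5)
        ann = annotate_qtl(scan, scan.table["marker"][2], panel, trait)
        assert ann.ci_left == scan.table["marker"][1]
        assert ann.ci_right == scan.table["marker"][3]

    def test_monotone_profile_bounded_by_chromosome_end(self):
        scan, _ = self._toy_scan([1, 2, 3, 4, 5])
        panel, trait = self._toy_panel_trait(5)
        ann = annotate_qtl(scan, scan.table["marker"][4], panel, trait)
        assert ann.ci_right == scan.table["marker"][4]
        assert ann.ci_left == scan.table["marker"][2]  # first with LOD < 3.5

    def test_variance_explained_round_trips_peak_r2(self, riail_panel):
        trait = simulate_trait(riail_panel, [(riail_panel.markers[50], 1.0)], 0.5, seed=3)
        scan = lod_scan(riail_panel, trait)
        peak = scan.peak()
        ann = annotate_qtl(scan, peak["marker"], riail_panel, trait)
        assert ann.variance_explained == pytest.approx(peak["r"] ** 2, abs=1e-10)

    def test_allelic_effect_signs_match_parent_of_resistance(self, riail_panel):
        marker = riail_panel.markers[50]
        trait = simulate_trait(riail_panel, [(marker, 1.0)], 0.9, seed=3)
        scan = lod_scan(riail_panel, trait)
        ann = annotate_qtl(scan, scan.peak()["marker"], riail_panel, trait)
        assert ann.allelic_effect > 0
        assert ann.parent_of_resistance == "B"

    def test_unknown_peak_raises(self, small_panel, rng):
        trait = pd.Series(rng.standard_normal(small_panel.n_lines), index=small_panel.lines)
        scan = lod_scan(small_panel, trait)
        with pytest.raises(KeyError):
            annotate_qtl(scan, "nope", small_panel, trait)


class TestForwardSearch:
    def test_null_trait_yields_no_qtl(self, riail_panel, rng):
        trait = pd.Series(rng.standard_normal(riail_panel.n_lines), index=riail_panel.lines)
        qtl = forward_search(riail_panel, trait, n_perm=200, seed=4)
        assert qtl == []

    def test_two_unlinked_qtl_recovered_in_effect_order(self, riail_panel):
        m1 = riail_panel.markers[50]   # chromosome I
        m2 = riail_panel.markers[350]  # chromosome IV
        hits = 0
        for s in range(12):
            trait = simulate_trait(riail_panel, [(m1, 1.0), (m2, 0.6)], 0.6, seed=100 + s)
            qtl = forward_search(riail_panel, trait, n_perm=150, seed=s)
            if len(qtl) < 2:
                continue
            chroms = [q.chrom for q in qtl[:2]]
            if chroms[0] == "I" and chroms[1] == "IV":
                in_ci1 = qtl[0].ci_left_bp <= riail_panel.marker_info(m1)["bp"] <= qtl[0].ci_right_bp
                in_ci2 = qtl[1].ci_left_bp <= riail_panel.marker_info(m2)["bp"] <= qtl[1].ci_right_bp
                if in_ci1 and in_ci2:
                    hits += 1
        assert hits >= 10

    def test_single_qtl_not_split(self, riail_panel):
        false_second = 0
        for s in range(10):
            trait = simulate_trait(riail_panel, [(riail_panel.markers[50], 1.0)], 0.5, seed=200 + s)
            qtl = forward_search(riail_panel, trait, n_perm=150, seed=s)
            assert len(qtl) >= 1
            false_second += len(qtl) > 1
        assert false_second <= 2

    def test_huge_threshold_returns_empty(self, riail_panel):
        trait = simulate_trait(riail_panel, [(riail_panel.markers[50], 1.0)], 0.9, seed=1)
        assert forward_search(riail_panel, trait, threshold=1e6) == []

    def test_max_qtl_caps_search(self, riail_panel):
        trait = simulate_trait(
            riail_panel,
            [(riail_panel.markers[i], 1.0) for i in (50, 250, 450)],
            0.8,
            seed=5,
        )
        qtl = forward_search(riail_panel, trait, threshold=3.0, max_qtl=2)
        assert len(qtl) == 2
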