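"""Correlation-LOD scans, permutation thresholds, forward search, and
the two-locus interaction machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zincmap import linkage
from zincmap.synthetic import CrossSpec, PhenotypeSpec, simulate_cross, simulate_phenotypes
from .oracles import regression_lod


class TestLodFormula:
    def test_zero_correlation_zero_lod(self):
        assert linkage.lod_from_r(0.0, 100) == 0.0

    def test_direct_evaluation(self):
        # -100 * ln(0.75) / (2 ln 10)
        assert linkage.lod_from_r(0.5, 100) == pytest.approx(6.2469, abs=1e-4)

    def test_perfect_correlation_capped(self, small_cross):
        y = small_cross.geno[:, 5].copy()
        with pytest.warns(UserWarning, match="capped"):
            scan = linkage.lod_scan(small_cross, y)
        n = small_cross.n_strains
        assert scan["lod"].max() == pytest.approx((n / 2) * np.log10(1 / linkage.LOD_EPS))

    def test_equals_regression_likelihood_ratio(self, rng):
        """Correlation LOD == regression LR LOD to near machine precision."""
        for _ in range(100):
            n = int(rng.integers(20, 200))
            g = rng.integers(0, 2, n).astype(float)
            if g.std() == 0:
                continue
            y = rng.normal(0, 1, n) + rng.normal(0, 1) * g
            r = np.corrcoef(g, y)[0, 1]
            assert linkage.lod_from_r(r, n) == pytest.approx(
                regression_lod(g, y), abs=1e-10
            )


class TestLodScan:
    def test_constant_phenotype_all_zero(self, small_cross):
        with pytest.warns(UserWarning, match="constant phenotype"):
            scan = linkage.lod_scan(small_cross, np.ones(small_cross.n_strains))
        assert (scan["lod"] == 0).all()

    def test_allele_swap_leaves_lod_flips_sign(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains) + small_cross.geno[:, 10]
        a = linkage.lod_scan(small_cross, y)
        swapped = linkage.CrossGenotypes(
            strains=small_cross.strains, markers=small_cross.markers,
            geno=1.0 - small_cross.geno,
        )
        b = linkage.lod_scan(swapped, y)
        assert np.allclose(a["lod"], b["lod"], atol=1e-10)
        assert np.allclose(a["r"], -b["r"], atol=1e-10)

    def test_strain_order_invariance(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains) + small_cross.geno[:, 10]
        perm = rng.permutation(small_cross.n_strains)
        reordered = linkage.CrossGenotypes(
            strains=small_cross.strains[perm], markers=small_cross.markers,
            geno=small_cross.geno[perm],
        )
        a = linkage.lod_scan(small_cross, y)
        b = linkage.lod_scan(reordered, y[perm])
        assert np.allclose(a["lod"], b["lod"], atol=1e-10)

    def test_missing_genotypes_use_pairwise_complete(self, small_cross, rng):
        geno = small_cross.geno.copy()
        geno[:10, 3] = np.nan
        cross = linkage.CrossGenotypes(
            strains=small_cross.strains, markers=small_cross.markers, geno=geno
        )
        y = rng.normal(0, 1, cross.n_strains)
        scan = linkage.lod_scan(cross, y)
        assert scan["n"].iloc[3] == cross.n_strains - 10
        assert scan["lod"].iloc[3] == pytest.approx(
            regression_lod(geno[:, 3], y), abs=1e-10
        )


class TestPermutationThreshold:
    def test_bit_exact_reproducibility(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains)
        a = linkage.permutation_threshold(small_cross, y, n_perm=120, seed=7)
        b = linkage.permutation_threshold(small_cross, y, n_perm=120, seed=7)
        assert a == b

    def test_monotone_in_quantile(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains)
        t10 = linkage.permutation_threshold(small_cross, y, n_perm=150, alpha=0.10, seed=3)
        t05 = linkage.permutation_threshold(small_cross, y, n_perm=150, alpha=0.05, seed=3)
        t01 = linkage.permutation_threshold(small_cross, y, n_perm=150, alpha=0.01, seed=3)
        assert t10 <= t05 <= t01

    def test_too_few_permutations_rejected(self, small_cross):
        with pytest.raises(ValueError):
            linkage.permutation_threshold(small_cross, np.zeros(small_cross.n_strains), n_perm=50)


class TestForwardSearch:
    def test_infinite_threshold_no_qtl(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains) + 2 * small_cross.geno[:, 10]
        res = linkage.forward_search(small_cross, y, threshold=np.inf)
        assert res.peaks == []

    def test_zero_threshold_first_peak_is_global_max(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains) + small_cross.geno[:, 40]
        scan = linkage.lod_scan(small_cross, y)
        res = linkage.forward_search(small_cross, y, threshold=0.8, seed=0)
        assert len(res.peaks) >= 1
        assert res.peaks[0].marker == scan.loc[scan["lod"].idxmax(), "marker"]

    def test_planted_qtl_detected_and_annotated(self):
        cross = simulate_cross(CrossSpec(n_strains=200, n_chrom=4, markers_per_chrom=40), seed=21)
        y, truth = simulate_phenotypes(cross, PhenotypeSpec(qtl=[(60, 0.35, 1)]), seed=22)
        res = linkage.forward_search(cross, y, n_perm=150, seed=23)
        assert len(res.peaks) >= 1
        peak = res.peaks[0]
        planted = cross.markers.iloc[60]
        assert peak.chrom == planted["chrom"]
        assert peak.ci_left_pos <= planted["pos"] <= peak.ci_right_pos
        assert 0.2 <= peak.var_exp_partial <= 0.55
        assert peak.high_allele == "CB4856"  # positive planted effect
        assert res.total_variance_explained >= peak.var_exp_partial - 1e-9

    def test_ci_markers_within_lod_drop(self, small_cross, rng):
        y = rng.normal(0, 0.8, small_cross.n_strains) + small_cross.geno[:, 15]
        res = linkage.forward_search(small_cross, y, threshold=2.0, seed=1)
        for p in res.peaks:
            scan = linkage.lod_scan(
                small_cross, y, cofactors=[q.marker for q in res.peaks if q.marker != p.marker]
            )
            on_chrom = scan[scan["chrom"] == p.chrom]
            ci = on_chrom[(on_chrom["pos"] >= p.ci_left_pos) & (on_chrom["pos"] <= p.ci_right_pos)]
            assert (ci["lod"] >= p.lod - 1.5 - 1e-9).all()


class TestInteractionAnova:
    def test_pure_interaction_tiny_p(self, rng):
        ga = np.repeat([0.0, 1.0], 50)
        gb = np.tile([0.0, 1.0], 50)
        y = ga * gb + rng.normal(0, 0.01, 100)
        assert linkage.interaction_anova(y, ga, gb) < 1e-6

    def test_additive_cell_means_no_interaction(self, rng):
        # 2x2 cell means {0, 1, 1, 2}: perfectly additive
        ga = np.repeat([0.0, 0.0, 1.0, 1.0], 25)
        gb = np.tile(np.repeat([0.0, 1.0], 25), 2)
        y = ga + gb + rng.normal(0, 1, 100)
        p = linkage.interaction_anova(y, ga, gb)
        assert p > 0.001

    def test_null_p_uniform(self):
        """Under a purely additive model the interaction p-value is U(0,1)."""
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ga = r.integers(0, 2, 120).astype(float)
            gb = r.integers(0, 2, 120).astype(float)
            if min(ga.std(), gb.std()) == 0:
                continue
            y = ga + gb + r.normal(0, 1, 120)
            try:
                ps.append(linkage.interaction_anova(y, ga, gb))
            except ValueError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_cell_error(self):
        ga = np.array([0.0, 0.0, 1.0, 1.0])
        gb = np.array([0.0, 0.0, 0.0, 0.0])
        y = np.zeros(4)
        with pytest.raises(ValueError):
            linkage.interaction_anova(y, ga, np.array([0.0, 1.0, 0.0, 0.0]))


class TestScanTwo:
    def test_interaction_lod_nonnegative(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains)
        res = linkage.scan_two(small_cross, y, n_perm=0, grid_max=30)
        assert (res.pairs["lod_int"] >= 0).all()
        assert (res.pairs["lod_full"] >= res.pairs["lod_add"] - 1e-9).all()

    def test_planted_epistasis_found(self):
        hits = 0
        runs = 10
        for seed in range(runs):
            r = np.random.default_rng(1000 + seed)
            cross = simulate_cross(CrossSpec(n_strains=250, n_chrom=4, markers_per_chrom=15), seed=r)
            ga, gb = cross.geno[:, 5], cross.geno[:, 35]  # different chromosomes
            signal = (ga - 0.5) * (gb - 0.5)
            signal = signal / signal.std() * np.sqrt(0.2)
            y = signal + r.normal(0, np.sqrt(0.8), cross.n_strains)
            res = linkage.scan_two(cross, y, n_perm=0, grid_max=60)
            top = res.pairs.loc[res.pairs["lod_int"].idxmax()]
            planted = {cross.markers["marker"].iloc[5], cross.markers["marker"].iloc[35]}
            hits += {top["marker_a"], top["marker_b"]} == planted
        assert hits >= 8

    def test_threshold_and_chrom_pair_summary(self, small_cross, rng):
        y = rng.normal(0, 1, small_cross.n_strains)
        res = linkage.scan_two(small_cross, y, n_perm=100, seed=5, grid_max=20)
        assert np.isfinite(res.interaction_threshold)
        summary = res.chrom_pair_maxima()
        assert summary["max_lod_int"].max() == pytest.approx(res.pairs["lod_int"].max())
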