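"""Variant filtering, LD pruning, kinship, mixed-model scan, thresholds
and region calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import hadamard

from zincmap import gwas
from zincmap.synthetic import WildPanelSpec, simulate_wild_panel
from .oracles import brute_force_ld_prune


def make_vm(dosage, chrom=None):
    dosage = np.asarray(dosage, dtype=float)
    n, M = dosage.shape
    chrom = chrom if chrom is not None else ["I"] * M
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, M + 1) * 100,
        "ref": "A", "alt": "T",
    })
    return gwas.VariantMatrix(
        strains=np.array([f"s{i}" for i in range(n)]),
        variants=variants, dosage=dosage,
    )


class TestFilterVariants:
    def test_rare_and_monomorphic_removed(self, rng):
        n = 81
        common = np.zeros((n, 1))
        common[:40] = 1.0
        rare = np.zeros((n, 1)); rare[0] = 1.0  # MAF 1/81 < 0.05
        mono = np.zeros((n, 1))
        vm = make_vm(np.hstack([common, rare, mono]))
        out = gwas.filter_variants(vm, maf_min=0.05)
        assert out.n_variants == 1

    def test_missing_call_removed_in_strict_mode(self):
        col = np.tile([0.0, 1.0], 5)
        d = np.column_stack([col, col.copy()])
        d[0, 1] = np.nan
        out = gwas.filter_variants(make_vm(d), maf_min=0.05)
        assert out.n_variants == 1

    def test_empty_result_error(self):
        with pytest.raises(ValueError):
            gwas.filter_variants(make_vm(np.zeros((10, 2))))


class TestLdPrune:
    def test_duplicated_variant_leaves_one(self, rng):
        g = rng.integers(0, 2, (30, 1)).astype(float)
        vm = make_vm(np.hstack([g, g]))
        out = gwas.ld_prune(vm, r2_max=0.8)
        assert out.n_variants == 1

    def test_orthogonal_variants_all_survive(self):
        H = hadamard(16)[:, 1:9]
        vm = make_vm((H + 1) / 2.0)
        out = gwas.ld_prune(vm, r2_max=0.1)
        assert out.n_variants == 8

    def test_matches_brute_force_oracle(self):
        """Windowed matrix pruner equals an independently coded O(M^2)
        pairwise pruner on a block-LD panel."""
        r = np.random.default_rng(31)
        n, M = 60, 300
        # blocks of 5 correlated variants
        base = r.integers(0, 2, (n, M // 5)).astype(float)
        cols = []
        for b in range(M // 5):
            for _ in range(5):
                noise = r.random(n) < 0.1
                cols.append(np.where(noise, 1 - base[:, b], base[:, b]))
        dosage = np.column_stack(cols)
        vm = make_vm(dosage)
        kept = gwas.ld_prune(vm, r2_max=0.5, window=40, step=10)
        oracle = brute_force_ld_prune(dosage, vm.maf(), r2_max=0.5, window=40, step=10)
        got = set(map(tuple, kept.variants[["chrom", "pos"]].to_numpy()))
        want = set(map(tuple, vm.variants.iloc[oracle][["chrom", "pos"]].to_numpy()))
        assert got == want


class TestKinship:
    def test_identical_strains_share_diagonal_value(self, rng):
        g = rng.integers(0, 2, (1, 50)).astype(float)
        d = np.vstack([g, g, rng.integers(0, 2, (4, 50)).astype(float)])
        A = gwas.kinship_additive(make_vm(d))
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-10)
        assert A[0, 1] == pytest.approx(A[1, 1], abs=1e-10)

    def test_opposite_strains_most_negative(self, rng):
        g = rng.integers(0, 2, (1, 50)).astype(float)
        d = np.vstack([g, 1 - g, rng.integers(0, 2, (4, 50)).astype(float)])
        A = gwas.kinship_additive(make_vm(d))
        assert A[0, 1] == min(A[0, :])

    def test_symmetric(self, rng):
        d = rng.integers(0, 2, (20, 100)).astype(float)
        A = gwas.kinship_additive(make_vm(d))
        assert np.max(np.abs(A - A.T)) == 0

    def test_recovers_true_founder_sharing(self):
        """Empirical kinship correlates with the generator's true
        identity-by-descent (fraction of loci from a shared founder)."""
        r = np.random.default_rng(77)
        n, M, F = 60, 5000, 8
        founders = r.integers(0, 2, (F, M)).astype(float)
        # each strain: mosaic of founder blocks of length 250
        assign = r.integers(0, F, (n, M // 250))
        dosage = np.zeros((n, M))
        ibd = np.zeros((n, n))
        blocks = np.repeat(np.arange(M // 250), 250)
        for i in range(n):
            dosage[i] = founders[assign[i][blocks], np.arange(M)]
        for i in range(n):
            for j in range(n):
                ibd[i, j] = np.mean(assign[i] == assign[j])
        A = gwas.kinship_additive(make_vm(dosage))
        iu = np.triu_indices(n, 1)
        assert np.corrcoef(A[iu], ibd[iu])[0, 1] >= 0.9


class TestEffectiveTests:
    def test_orthogonal_design_counts_all(self):
        H = hadamard(16)[:, 1:11]
        vm = make_vm((H + 1) / 2.0)
        assert gwas.effective_tests(vm).n_eff == 10

    def test_identical_variants_count_one(self, rng):
        g = rng.integers(0, 2, (30, 1)).astype(float)
        vm = make_vm(np.tile(g, (1, 12)))
        assert gwas.effective_tests(vm).n_eff == 1

    def test_block_design(self):
        # 10 mutually orthogonal block bases, each duplicated 10 times:
        # the correlation matrix is block diagonal with rank-1 blocks
        H = (hadamard(16)[:, 1:11] + 1) / 2.0
        cols = [H[:, b] for b in range(10) for _ in range(10)]
        vm = make_vm(np.column_stack(cols))
        assert gwas.effective_tests(vm).n_eff == 10

    def test_zero_variance_variant_error(self):
        with pytest.raises(ValueError):
            gwas.effective_tests(make_vm(np.hstack([
                np.ones((10, 1)), np.tile([0.0, 1.0], (5, 1)).reshape(10, 1)
            ])))


class TestMixedModelScan:
    def test_identity_kinship_equals_ols(self, rng):
        n, M = 60, 200
        d = rng.integers(0, 2, (n, M)).astype(float)
        keep = (d.std(axis=0) > 0)
        d = d[:, keep]
        vm = make_vm(d)
        y = rng.normal(0, 1, n)
        scan = gwas.mixed_model_scan(vm, np.eye(n), y)
        # OLS per marker
        for j in rng.choice(d.shape[1], 20, replace=False):
            g = d[:, j]
            r = np.corrcoef(g, y)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert scan.variants["score"].iloc[j] == pytest.approx(-np.log10(p), abs=1e-6)

    def test_planted_perfect_signal_tops_scan(self, rng):
        vm, y, truth = simulate_wild_panel(WildPanelSpec(n_variants=300, causal_frac=0.0,
                                                         polygenic_frac=0.0), seed=41)
        vm = gwas.filter_variants(vm)
        y = vm.dosage[:, 17] + rng.normal(0, 0.01, vm.n_strains)
        K = gwas.kinship_additive(vm)
        scan = gwas.mixed_model_scan(vm, K, y)
        assert scan.variants["score"].idxmax() == 17

    def test_strain_reordering_invariance(self, rng):
        vm, y, _ = simulate_wild_panel(WildPanelSpec(n_strains=40, n_variants=150), seed=42)
        vm = gwas.filter_variants(vm)
        K = gwas.kinship_additive(vm)
        a = gwas.mixed_model_scan(vm, K, y)
        perm = rng.permutation(vm.n_strains)
        vm2 = gwas.VariantMatrix(strains=vm.strains[perm], variants=vm.variants,
                                 dosage=vm.dosage[perm])
        b = gwas.mixed_model_scan(vm2, K[np.ix_(perm, perm)], y[perm])
        assert np.allclose(a.variants["score"], b.variants["score"], atol=1e-6)

    def test_missing_calls_dropped_per_variant(self, rng):
        vm, y, _ = simulate_wild_panel(WildPanelSpec(n_strains=50, n_variants=100), seed=43)
        d = vm.dosage.copy()
        d[:5, 7] = np.nan
        vm2 = gwas.VariantMatrix(strains=vm.strains, variants=vm.variants, dosage=d)
        K = gwas.kinship_additive(vm)
        scan = gwas.mixed_model_scan(vm2, K, y)
        assert np.isfinite(scan.variants["score"].iloc[7])


class TestThresholdsAndRegions:
    def test_bonferroni_from_printed_marker_count(self):
        # -log10(0.05 / 64,046) for the full wild-panel marker set
        assert -np.log10(0.05 / 64046) == pytest.approx(6.11, abs=0.005)

    def test_eigen_threshold_below_bonferroni(self, rng):
        vm, y, _ = simulate_wild_panel(WildPanelSpec(n_strains=50, n_variants=200), seed=44)
        vm = gwas.filter_variants(vm)
        scan = gwas.mixed_model_scan(vm, gwas.kinship_additive(vm), y)
        n_eff = gwas.effective_tests(vm).n_eff
        scan = gwas.call_regions(scan, n_eff)
        assert scan.eigen <= scan.bonferroni

    def test_no_hits_empty_regions(self):
        scan = gwas.GwaScan(
            variants=pd.DataFrame({"chrom": ["I"] * 10, "pos": range(1, 11),
                                   "score": np.zeros(10)}),
            bonferroni=5.0,
        )
        assert gwas.call_regions(scan, n_eff=5).regions == []

    def test_single_hit_padded_and_clipped(self):
        M = 500
        score = np.zeros(M)
        score[200] = 10.0
        scan = gwas.GwaScan(
            variants=pd.DataFrame({"chrom": ["I"] * M, "pos": np.arange(1, M + 1) * 10,
                                   "score": score}),
            bonferroni=8.0,
        )
        out = gwas.call_regions(scan, n_eff=100, pad=150)
        assert out.regions == [("I", (200 - 150 + 1) * 10, (200 + 150 + 1) * 10)]
        # hit near the chromosome start clips at the first variant
        score2 = np.zeros(M); score2[3] = 10.0
        scan2 = gwas.GwaScan(
            variants=pd.DataFrame({"chrom": ["I"] * M, "pos": np.arange(1, M + 1) * 10,
                                   "score": score2}),
            bonferroni=8.0,
        )
        assert gwas.call_regions(scan2, n_eff=100, pad=150).regions[0][1] == 10


class TestVarianceExplainedByClass:
    def test_full_determination(self):
        y = np.repeat([0.0, 1.0, 2.0], 10)
        labels = np.repeat(["a", "b", "c"], 10)
        r2, p = gwas.variance_explained_by_class(y, labels)
        assert r2 == pytest.approx(1.0)

    def test_null_expectation(self):
        """Random labels: E[R^2] ~ (k-1)/(n-1)."""
        r2s = []
        k, n = 3, 61
        for seed in range(300):
            r = np.random.default_rng(seed)
            y = r.normal(0, 1, n)
            labels = np.repeat(["a", "b", "c"], [20, 20, 21])
            r2, _ = gwas.variance_explained_by_class(y, labels)
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx((k - 1) / (n - 1), abs=0.01)

    def test_planted_class_effect_recovered(self):
        r2s = []
        for seed in range(50):
            vm, y, truth = simulate_wild_panel(
                WildPanelSpec(n_variants=200, causal_frac=0.10, polygenic_frac=0.2),
                seed=seed,
            )
            r2, _ = gwas.variance_explained_by_class(y, np.array(truth["classes"]))
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx(0.10, abs=0.05)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            gwas.variance_explained_by_class(np.arange(6.0), np.repeat("a", 6))
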