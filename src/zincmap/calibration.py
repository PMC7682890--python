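"""End-to-end calibration and recovery experiments on synthetic panels.

Each function runs one self-contained experiment against the
synthetic-data generators and returns the measured quantity: statistical
agreement of the two LOD formulations, genome-wide error-rate
calibration of the permutation threshold, planted-QTL confidence-
interval coverage, mediation-screen recovery, mixed-model type-I error
under population structure, neutrality of Tajima's D on coalescent
replicates, and neighbor-joining consistency on additive distances.
Every experiment is a pure function of its seed.

Problem sizes default to the desk-scale study emulation (250 strains,
500-1,000 markers, 81-strain wild panels, 17-probe screens).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import gwas, linkage, mediate, popgen, strain_stats
from .synthetic import (
    CrossSpec,
    MediationSpec,
    PhenotypeSpec,
    WildPanelSpec,
    simulate_cross,
    simulate_expression,
    simulate_neutral_haplotypes,
    simulate_phenotypes,
    simulate_wild_panel,
)


def lod_agreement(n_instances: int = 1000, seed: int = 0) -> float:
    """Max |correlation LOD - regression likelihood-ratio LOD| over random
    genotype/phenotype instances.  The regression route is computed here
    from residual sums of squares, independently of the correlation
    formula."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(20, 300))
        g = rng.integers(0, 2, n).astype(float)
        if g.std() == 0:
            continue
        y = rng.normal(0, 1, n) + rng.normal(0, 1) * g
        r = np.corrcoef(g, y)[0, 1]
        lod_corr = linkage.lod_from_r(r, n)
        X = np.column_stack([np.ones(n), g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss0 = float(np.sum((y - y.mean()) ** 2))
        rss1 = float(np.sum((y - X @ beta) ** 2))
        lod_reg = (n / 2.0) * np.log10(rss0 / rss1)
        worst = max(worst, abs(lod_corr - lod_reg))
    return worst


def gwer_calibration(n_sims: int = 200, n_perm: int = 200, alpha: float = 0.05,
                     seed: int = 0, spec: CrossSpec = CrossSpec()) -> float:
    """Fraction of pure-noise simulations whose genome-wide max LOD
    exceeds their own permutation threshold (should be ~ alpha)."""
    hits = 0
    for ss in np.random.SeedSequence(seed).spawn(n_sims):
        r = np.random.default_rng(ss)
        cross = simulate_cross(spec, seed=r)
        y = r.normal(0, 1, cross.n_strains)
        thr = linkage.permutation_threshold(cross, y, n_perm=n_perm, alpha=alpha, seed=r)
        scan = linkage.lod_scan(cross, y)
        hits += scan["lod"].max() > thr
    return hits / n_sims


def qtl_recovery(n_runs: int = 50, frac: float = 0.25, n_perm: int = 200,
                 seed: int = 0) -> dict:
    """Forward search on a planted single-QTL panel (250 strains, ~500
    markers over 6 chromosomes): confidence-interval coverage of the
    planted marker and the mean estimated variance explained."""
    spec = CrossSpec(markers_per_chrom=84)
    covered = 0
    var_exp = []
    for ss in np.random.SeedSequence(seed).spawn(n_runs):
        r = np.random.default_rng(ss)
        cross = simulate_cross(spec, seed=r)
        idx = int(r.integers(0, cross.n_markers))
        while np.var(cross.geno[:, idx]) == 0:
            idx = int(r.integers(0, cross.n_markers))
        y, _ = simulate_phenotypes(cross, PhenotypeSpec(qtl=[(idx, frac, 1)]), seed=r)
        res = linkage.forward_search(cross, y, n_perm=n_perm, seed=r)
        planted = cross.markers.iloc[idx]
        for p in res.peaks:
            if p.chrom == planted["chrom"] and p.ci_left_pos <= planted["pos"] <= p.ci_right_pos:
                covered += 1
                var_exp.append(p.var_exp_partial)
                break
    return {"coverage": covered / n_runs,
            "mean_var_exp": float(np.mean(var_exp)) if var_exp else float("nan")}


def mediation_recovery(n_runs: int = 25, n_sim: int = 200, seed: int = 0) -> dict:
    """One planted mediator among 17 probes (120 strains): how often the
    screen ranks it first, and the ACME error in bootstrap-SE units."""
    rank1 = 0
    se_units = []
    for ss in np.random.SeedSequence(seed).spawn(n_runs):
        r = np.random.default_rng(ss)
        cross = simulate_cross(CrossSpec(n_strains=120, markers_per_chrom=20), seed=r)
        mspec = MediationSpec(a=1.0, b=1.0, noise_m=0.5, noise_y=0.5, n_probes=17)
        probes, y, truth = simulate_expression(cross, 50, mspec, seed=r)
        table, _ = mediate.mediation_screen(
            y, probes, cross.geno[:, 50], n_sim=n_sim, seed=int(r.integers(2**31))
        )
        rank1 += table["acme"].idxmax() == "mediator"
        est = table.loc["mediator"]
        se = (est["ci_high"] - est["ci_low"]) / 3.92
        se_units.append(abs(est["acme"] - truth["acme"]) / se)
    return {"rank1_rate": rank1 / n_runs, "mean_acme_err_se": float(np.mean(se_units))}


def mixed_model_calibration(n_panels: int = 4, seed: int = 0) -> dict:
    """Null type-I error of the mixed-model scan on structured panels
    (two diverged subpopulations, polygenic phenotype, no causal class),
    against the inflation of unadjusted per-marker OLS."""
    spec = WildPanelSpec(n_strains=100, n_variants=1500, divergence=0.2,
                         causal_frac=0.0, polygenic_frac=0.3, subpop_frac=0.3)
    mm_p, ols_p = [], []
    for ss in np.random.SeedSequence(seed).spawn(n_panels):
        r = np.random.default_rng(ss)
        vm, y, _ = simulate_wild_panel(spec, seed=r)
        vm = gwas.filter_variants(vm)
        K = gwas.kinship_additive(vm)
        scan = gwas.mixed_model_scan(vm, K, y)
        mm_p.append(10 ** (-scan.variants["score"].to_numpy()))
        X = vm.dosage
        n = len(y)
        Z = X - X.mean(axis=0)
        yc = y - y.mean()
        rnum = Z.T @ yc / np.sqrt((Z**2).sum(axis=0) * (yc**2).sum())
        t = rnum * np.sqrt((n - 2) / (1 - rnum**2))
        ols_p.append(2 * stats.t.sf(np.abs(t), n - 2))
    mm_p = np.concatenate(mm_p)
    ols_p = np.concatenate(ols_p)
    return {"mm_type1": float((mm_p < 0.05).mean()),
            "ols_type1": float((ols_p < 0.05).mean())}


def neutral_tajima(n_reps: int = 500, n: int = 20, theta: float = 10.0,
                   seed: int = 0) -> float:
    """Mean Tajima's D over neutral coalescent replicates (expected ~ 0)."""
    root = np.random.default_rng(seed)
    ds = []
    for _ in range(n_reps):
        H, _ = simulate_neutral_haplotypes(n, theta, seed=root)
        d = popgen.tajimas_d(H.sum(axis=0), n)
        if np.isfinite(d):
            ds.append(d)
    return float(np.mean(ds))


def nj_consistency(n_trees: int = 20, seed: int = 0) -> dict:
    """Neighbor joining on exact additive 6-taxon distance matrices:
    Robinson-Foulds distance to the generating topology (0 for a
    consistent implementation) and the worst three-point pendant-length
    error."""
    import dendropy

    rng = np.random.default_rng(seed)
    max_rf = 0
    for _ in range(n_trees):
        labels = [f"t{i}" for i in range(6)]
        nodes = [f"{l}:{rng.uniform(0.2, 2.0):.4f}" for l in labels]
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
            a, b = nodes.pop(int(i)), nodes.pop(int(j))
            nodes.append(f"({a},{b}):{rng.uniform(0.2, 2.0):.4f}")
        newick = f"({nodes[0]},{nodes[1]});"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        D = np.zeros((6, 6))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    D[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
        est = popgen.nj_from_distances(D, labels)
        tns = tree.taxon_namespace
        t2 = dendropy.Tree.get(data=str(est), schema="newick", taxon_namespace=tns)
        tree.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(tree, t2)
        max_rf = max(max_rf, rf)

    D3 = np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0]])
    t3 = popgen.nj_from_distances(D3, ["A", "B", "C"])
    lengths = {t.name: t.length for t in t3.tips()}
    err3 = max(abs(lengths["A"] - 1), abs(lengths["B"] - 1), abs(lengths["C"] - 3))
    return {"max_rf": int(max_rf), "three_point_error": float(err3)}


def heritability_recovery(n_runs: int = 20, n_strains: int = 50,
                          n_reps: int = 10, seed: int = 0) -> float:
    """Mean REML H^2 across simulated panels with equal strain and
    residual variance (truth 0.5)."""
    ests = []
    for ss in np.random.SeedSequence(seed).spawn(n_runs):
        r = np.random.default_rng(ss)
        groups = np.repeat(np.arange(n_strains), n_reps)
        vals = r.normal(0, 1, n_strains)[groups] + r.normal(0, 1, len(groups))
        est = strain_stats.estimate_heritability(vals, groups, n_boot=0, seed=0)
        ests.append(est.h2)
    return float(np.mean(ests))
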