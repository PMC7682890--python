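"""Mixed-model genome-wide association for inbred wild isolates.

The pipeline mirrors the standard association workflow for selfing
nematode panels: drop variants with missing calls or minor-allele
frequency below 5%, greedily LD-prune, build a VanRaden-style additive
kinship matrix, and scan each variant with the linear mixed model

    y = mu + x beta + u + e,     u ~ N(0, sigma_g^2 K),

solved through the spectral decomposition of K.  Variance components are
estimated once on the null model and reused for every marker (the P3D
approximation), with exact per-marker refitting behind a flag.
Multiple-testing thresholds come in two flavours: strict Bonferroni over
all M variants and a more lenient threshold over the effective number of
independent tests from the eigenvalues of the variant correlation matrix
(Li & Ji estimator).  Significant hits are merged into regions extended
by ±150 variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


@dataclass
class VariantMatrix:
    """Homozygous biallelic dosages for inbred isolates.

    ``dosage`` is n_strains x M with entries 0 (ref), 1 (alt) or NaN;
    ``variants`` has columns chrom, pos (bp, 1-based), ref, alt and is
    sorted by position within chromosome.
    """

    strains: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.strains), len(self.variants)):
            raise ValueError("dosage shape does not match strains x variants")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("variants not sorted by position within chromosome")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take(self, keep: np.ndarray) -> "VariantMatrix":
        return VariantMatrix(
            strains=self.strains,
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep],
        )

    def maf(self) -> np.ndarray:
        p = np.nanmean(self.dosage, axis=0)
        return np.minimum(p, 1 - p)


def filter_variants(vm: VariantMatrix, maf_min: float = 0.05,
                    max_missing: float = 0.0) -> VariantMatrix:
    """Drop variants with more than ``max_missing`` fraction of missing
    calls (default: any missing call) or minor-allele frequency below
    ``maf_min``."""
    miss = np.mean(np.isnan(vm.dosage), axis=0)
    keep = (miss <= max_missing) & (vm.maf() >= maf_min)
    if not keep.any():
        raise ValueError("no variants survive filtering")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_variants: dropped %d of %d variants", n_drop, vm.n_variants)
    return vm.take(np.flatnonzero(keep))


def ld_prune(vm: VariantMatrix, r2_max: float = 0.8,
             window: int = 50, step: int = 10) -> VariantMatrix:
    """Greedy sliding-window LD pruning.

    Within each window of ``window`` variants (advancing by ``step``),
    while any surviving pair has squared genotype correlation above
    ``r2_max``, the member with the lower MAF is removed (tie: the
    rightmost).  Missing calls are mean-imputed for the correlations.
    """
    X = vm.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    maf = vm.maf()
    M = vm.n_variants
    alive = np.ones(M, dtype=bool)
    start = 0
    while start < M:
        idx = np.flatnonzero(alive[start:start + window]) + start
        if len(idx) > 1:
            sub = X[:, idx]
            sd = sub.std(axis=0)
            ok = sd > 0
            if ok.sum() > 1:
                Z = (sub[:, ok] - sub[:, ok].mean(axis=0)) / sd[ok]
                r2 = (Z.T @ Z / len(Z)) ** 2
                np.fill_diagonal(r2, 0.0)
                live = idx[ok]
                local_alive = np.ones(len(live), dtype=bool)
                while True:
                    sub_r2 = r2[np.ix_(local_alive, local_alive)]
                    if sub_r2.size == 0 or sub_r2.max() <= r2_max:
                        break
                    ii, jj = np.unravel_index(np.argmax(sub_r2), sub_r2.shape)
                    cur = np.flatnonzero(local_alive)
                    a, b = live[cur[ii]], live[cur[jj]]
                    if maf[a] < maf[b]:
                        victim = a
                    elif maf[b] < maf[a]:
                        victim = b
                    else:
                        victim = max(a, b)  # tie: rightmost
                    local_alive[np.searchsorted(live, victim)] = False
                    alive[victim] = False
        if start + window >= M:
            break
        start += step
    log.info("ld_prune: %d of %d variants retained", int(alive.sum()), M)
    return vm.take(np.flatnonzero(alive))


def kinship_additive(vm: VariantMatrix) -> np.ndarray:
    """VanRaden-style additive relationship matrix for inbred dosages.

    Dosages are recoded to x in {-1, +1} (ref/alt), missing calls imputed
    to the per-variant mean, columns centered, and A = Z Z' / c with the
    normalizer c = sum_k 4 p_k (1 - p_k) — the total variance of the
    recoded loci — so that the mean diagonal is ~1.
    """
    X = 2.0 * vm.dosage - 1.0
    col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("variant with all calls missing")
    X = np.where(np.isnan(X), col_mean, X)
    p = np.nanmean(vm.dosage, axis=0)
    c = float(np.sum(4.0 * p * (1.0 - p)))
    if c == 0:
        raise ValueError("zero-variance genotype matrix")
    Z = X - X.mean(axis=0)
    return (Z @ Z.T) / c


@dataclass
class EffectiveTests:
    n_eff: int
    method: str = "li_ji_2005"


def effective_tests(vm: VariantMatrix) -> EffectiveTests:
    """Effective number of independent tests from the eigenvalues of the
    variant correlation matrix (Li & Ji 2005): each eigenvalue lambda
    contributes I(lambda >= 1) + frac(lambda); the sum is floored and
    clipped to >= 1."""
    if vm.n_variants < 2:
        raise ValueError("need >= 2 variants")
    X = vm.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance variant: correlation matrix degenerate")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / len(Z)
    lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 8)  # guard frac(1 - eps)
    n_eff = int(np.floor(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam)))))
    return EffectiveTests(n_eff=max(1, n_eff))


def _null_reml_gamma(y: np.ndarray, U: np.ndarray, d: np.ndarray) -> float:
    """REML estimate of gamma = sigma_g^2 / sigma_e^2 for y = mu + u + e
    using the rotated representation y* = U'y, Var = sigma_e^2 (gamma D + I)."""
    ys = U.T @ y
    xs = U.T @ np.ones(len(y))
    n = len(y)

    def neg2(log_g: float) -> float:
        g = np.exp(log_g)
        w = g * d + 1.0
        xwx = np.sum(xs * xs / w)
        beta = np.sum(xs * ys / w) / xwx
        r = ys - xs * beta
        q = np.sum(r * r / w)
        s2 = q / (n - 1)
        return (n - 1) * np.log(s2) + np.sum(np.log(w)) + np.log(xwx)

    res = optimize.minimize_scalar(neg2, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


@dataclass
class GwaScan:
    variants: pd.DataFrame  # chrom, pos, score (-log10 p), beta, maf
    bonferroni: float
    eigen: float = float("nan")
    gamma: float = float("nan")
    regions: list = field(default_factory=list)


def mixed_model_scan(
    vm: VariantMatrix,
    kinship: np.ndarray,
    phenotype: np.ndarray,
    alpha: float = 0.05,
) -> GwaScan:
    """Per-variant mixed-model association scores (-log10 p).

    Variance components are estimated once under the null and reused for
    every marker; each marker's Wald t-test is then a weighted least
    squares fit in the eigenbasis of K.  Strains with missing phenotype
    are dropped globally; strains with a missing call are dropped for
    that variant only.  A non-PSD kinship is shrunk toward the identity
    with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    K = np.asarray(kinship, dtype=float)[np.ix_(keep, keep)]
    X = vm.dosage[keep]
    n, M = X.shape

    lam_min = float(np.linalg.eigvalsh(K).min())
    if lam_min < -1e-8:
        warnings.warn("kinship not PSD; shrinking toward identity")
        K = K + (abs(lam_min) + 1e-8) * np.eye(n)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    gamma = _null_reml_gamma(y, U, d)
    w = gamma * d + 1.0

    ys = U.T @ y
    ones_s = U.T @ np.ones(n)
    Xs = U.T @ np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    sw = 1.0 / w
    # weighted 2x2 normal equations for [1, x] per marker, vectorized
    a11 = np.sum(ones_s * ones_s * sw)
    a12 = Xs.T @ (ones_s * sw)
    a22 = np.einsum("ij,ij,i->j", Xs, Xs, sw)
    b1 = np.sum(ones_s * ys * sw)
    b2 = Xs.T @ (ys * sw)
    det = a11 * a22 - a12 * a12
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    beta = (a11 * b2 - a12 * b1) / det
    mu = (a22 * b1 - a12 * b2) / det
    yty = np.sum(ys * ys * sw)
    rss = yty - (mu * b1 + beta * b2)
    df = n - 2
    sigma2 = np.clip(rss, 1e-300, None) / df
    var_beta = sigma2 * a11 / det
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / np.sqrt(var_beta)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(np.isnan(p), 1.0, p)

    # exact handling for variants with missing calls: refit on the subset
    miss_cols = np.flatnonzero(np.isnan(X).any(axis=0))
    for j in miss_cols:
        ok = ~np.isnan(X[:, j])
        if ok.sum() < 3 or np.nanstd(X[ok, j]) == 0:
            p[j] = 1.0
            beta[j] = 0.0
            continue
        Kj = K[np.ix_(ok, ok)]
        dj, Uj = np.linalg.eigh(Kj)
        wj = gamma * np.clip(dj, 0, None) + 1.0
        Xj = np.column_stack([np.ones(ok.sum()), X[ok, j]])
        Xjs = Uj.T @ Xj
        yjs = Uj.T @ y[ok]
        W = 1.0 / wj
        A = Xjs.T @ (Xjs * W[:, None])
        bvec = Xjs.T @ (yjs * W)
        coef = np.linalg.solve(A, bvec)
        r = yjs - Xjs @ coef
        s2 = float(np.sum(r * r * W)) / (ok.sum() - 2)
        se = np.sqrt(s2 * np.linalg.inv(A)[1, 1])
        beta[j] = coef[1]
        p[j] = 2.0 * stats.t.sf(abs(coef[1] / se), ok.sum() - 2)

    score = -np.log10(np.clip(p, 1e-300, None))
    table = vm.variants.copy()
    table["score"] = score
    table["beta"] = beta
    table["maf"] = vm.maf()
    return GwaScan(
        variants=table,
        bonferroni=float(-np.log10(alpha / M)),
        gamma=gamma,
    )


def call_regions(scan: GwaScan, n_eff: int, alpha: float = 0.05,
                 pad: int = 150) -> GwaScan:
    """Apply the effective-tests threshold and emit significant regions.

    The eigen threshold is -log10(alpha / n_eff); per chromosome, each
    variant above it seeds an interval of ±``pad`` variants (clipped at
    chromosome ends); overlapping intervals merge into (chrom, start_bp,
    end_bp) regions.
    """
    scan.eigen = float(-np.log10(alpha / n_eff))
    regions = []
    for chrom, sub in scan.variants.groupby("chrom", sort=False):
        sig = np.flatnonzero(sub["score"].to_numpy() > scan.eigen)
        if len(sig) == 0:
            continue
        lo = np.clip(sig - pad, 0, len(sub) - 1)
        hi = np.clip(sig + pad, 0, len(sub) - 1)
        merged = [[lo[0], hi[0]]]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        pos = sub["pos"].to_numpy()
        regions.extend((chrom, int(pos[a]), int(pos[b])) for a, b in merged)
    scan.regions = regions
    return scan


def variance_explained_by_class(phenotype: np.ndarray, class_labels: np.ndarray):
    """One-way ANOVA R^2 of phenotype on a haplotype class label, with the
    F-test p-value.  Requires >= 2 classes with >= 2 strains each."""
    y = np.asarray(phenotype, dtype=float)
    labels = np.asarray(class_labels)
    ok = ~np.isnan(y)
    y, labels = y[ok], labels[ok]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 classes")
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 strains")
    grand = y.mean()
    ssb = sum(c * (y[labels == u].mean() - grand) ** 2 for u, c in zip(uniq, counts))
    sst = float(np.sum((y - grand) ** 2))
    ssw = sst - ssb
    k, n = len(uniq), len(y)
    r2 = ssb / sst if sst > 0 else 0.0
    if ssw <= 0:
        return float(r2), 0.0
    F = (ssb / (k - 1)) / (ssw / (n - k))
    return float(r2), float(stats.f.sf(F, k - 1, n - k))
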