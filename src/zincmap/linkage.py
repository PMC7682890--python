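"""Single-marker linkage mapping on a biallelic recombinant-inbred panel.

The mapping statistic is the correlation LOD score

    LOD = -n * ln(1 - r^2) / (2 * ln 10)

where ``r`` is the Pearson correlation between the numeric genotype at a
marker (0 = N2 allele, 1 = CB4856 allele) and the strain phenotypes, and
``n`` is the number of strains with both observed.  This equals the
likelihood-ratio LOD of a single-marker linear regression.  Genome-wide
significance is controlled by permuting phenotypes against the whole
genotype matrix; QTL are accumulated by a forward search that conditions
each new scan on the markers already declared (cofactors).  Detected peaks
are annotated with 1.5-LOD-drop confidence intervals evaluated on the
peak's chromosome, per-QTL variance explained, and allelic effect
direction.  A two-dimensional scan tests every marker pair for an
interaction LOD beyond the additive two-locus model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LOD_EPS = 1e-12  # |r| = 1 cap: LOD = (n/2) * log10(1 / LOD_EPS)


@dataclass
class CrossGenotypes:
    """Strains x biallelic markers with a physical map.

    ``geno`` holds numeric allele codes (0 = A/N2, 1 = B/CB4856, NaN =
    missing) with one row per strain and one column per marker.  ``markers``
    has columns ``marker``, ``chrom``, ``pos`` (bp, 1-based), sorted by
    (chromosome, position).
    """

    strains: np.ndarray
    markers: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains)
        self.geno = np.asarray(self.geno, dtype=float)
        if self.geno.shape != (len(self.strains), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        if self.markers["marker"].duplicated().any():
            raise ValueError("duplicate marker identifiers")
        # markers must arrive sorted within chromosome
        for _, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("markers not sorted by position within chromosome")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker!r}")
        return int(idx[0])


def lod_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Correlation LOD: ``-n ln(1 - r^2) / (2 ln 10)``, capped at |r| = 1."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    one_minus = np.clip(1.0 - r * r, LOD_EPS, None)
    capped = (1.0 - r * r) < LOD_EPS
    if np.any(capped):
        warnings.warn("perfect marker-phenotype correlation; LOD capped", stacklevel=2)
    return -n * np.log(one_minus) / (2.0 * np.log(10.0))


def _residualize(y: np.ndarray, cof: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, cof]; missing cofactor calls are mean-imputed."""
    n = len(y)
    if cof.size == 0:
        return y - np.nanmean(y)
    cof = np.atleast_2d(np.asarray(cof, dtype=float))
    if cof.shape[0] != n:
        cof = cof.T
    col_mean = np.nanmean(cof, axis=0)
    cof = np.where(np.isnan(cof), col_mean, cof)
    X = np.column_stack([np.ones(n), cof])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _pairwise_scan(geno: np.ndarray, Y: np.ndarray):
    """Pairwise-complete Pearson r between each genotype column and each
    phenotype column, with per-pair n.  NaNs in ``geno`` are excluded per
    marker; ``Y`` must already be complete (rows with missing phenotype
    dropped by the caller).  Returns (r, n) of shape (M, P)."""
    W = (~np.isnan(geno)).astype(float)
    G0 = np.where(np.isnan(geno), 0.0, geno)
    m = W.sum(axis=0)[:, None]  # (M, 1)
    Sg = G0.sum(axis=0)[:, None]
    Sgg = (G0 * G0).sum(axis=0)[:, None]
    Sy = W.T @ Y  # (M, P)
    Syy = W.T @ (Y * Y)
    Sgy = G0.T @ Y
    cov = m * Sgy - Sg * Sy
    vg = m * Sgg - Sg * Sg
    vy = m * Syy - Sy * Sy
    denom = vg * vy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.sqrt(np.clip(denom, 1e-300, None)), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return r, np.broadcast_to(m, r.shape)


def lod_scan(
    cross: CrossGenotypes,
    phenotype: np.ndarray,
    cofactors: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Genome scan: per-marker correlation LOD of phenotype vs genotype.

    ``cofactors`` name markers whose genotypes are regressed out of the
    phenotype before correlating (marker-regression analogue of adding a
    QTL to the model).  Returns a DataFrame with columns marker, chrom,
    pos, r, n, lod.  Markers with zero genotype variance score 0.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < 10:
        raise ValueError("need >= 10 strains with non-missing phenotype")
    geno = cross.geno[keep]
    y = y[keep]
    if np.nanstd(y) == 0:
        warnings.warn("constant phenotype: all LOD scores are 0")
        out = cross.markers.copy()
        out["r"] = 0.0
        out["n"] = int(keep.sum())
        out["lod"] = 0.0
        return out
    if cofactors:
        cof_idx = [cross.marker_index(m) for m in cofactors]
        y = _residualize(y, geno[:, cof_idx])
    r, n = _pairwise_scan(geno, y[:, None])
    out = cross.markers.copy()
    out["r"] = r[:, 0]
    out["n"] = n[:, 0].astype(int)
    out["lod"] = lod_from_r(r[:, 0], n[:, 0])
    return out


def permutation_threshold(
    cross: CrossGenotypes,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    block: int = 200,
) -> float:
    """(1-alpha) quantile of the permutation null of the genome-wide max LOD.

    Whole phenotype vectors are permuted against the genotype matrix, which
    preserves the linkage structure among markers; the genome-wide maximum
    LOD of each permutation forms the null distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    geno = cross.geno[keep]
    y = y[keep]
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        Y = np.empty((len(y), b))
        for j in range(b):
            Y[:, j] = rng.permutation(y)
        r, n = _pairwise_scan(geno, Y)
        lod = lod_from_r(r, n)
        maxima[done : done + b] = lod.max(axis=0)
        done += b
    return float(np.quantile(maxima, 1.0 - alpha))


@dataclass
class QtlPeak:
    trait: str
    marker: str
    chrom: object
    pos: int
    lod: float
    ci_left_marker: str
    ci_right_marker: str
    ci_left_pos: int
    ci_right_pos: int
    var_exp_partial: float
    var_exp_marginal: float
    high_allele: str  # allele class with the larger trait value: "N2" or "CB4856"
    drop: float = 1.5


@dataclass
class ForwardSearchResult:
    peaks: list[QtlPeak]
    threshold: float
    scans: list[pd.DataFrame] = field(default_factory=list)
    total_variance_explained: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.peaks])


def forward_search(
    cross: CrossGenotypes,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    threshold: float | None = None,
    max_iter: int = 20,
    trait: str = "trait",
) -> ForwardSearchResult:
    """Iterative QTL detection by conditional rescanning.

    The permutation threshold is computed once from the unconditioned
    phenotype.  At each round the genome is scanned with all previously
    declared QTL as cofactors; if the maximum LOD exceeds the threshold
    that marker joins the model, otherwise the search stops.  Ties at the
    maximum go to the leftmost marker in map order.
    """
    y = np.asarray(phenotype, dtype=float)
    if threshold is None:
        threshold = permutation_threshold(cross, y, n_perm=n_perm, alpha=alpha, seed=seed)
    cofactors: list[str] = []
    scans: list[pd.DataFrame] = []
    for it in range(max_iter + 1):
        if it == max_iter:
            raise RuntimeError(f"forward search exceeded {max_iter} iterations")
        scan = lod_scan(cross, y, cofactors=cofactors)
        scans.append(scan)
        best = int(np.argmax(scan["lod"].to_numpy()))  # argmax -> leftmost tie
        if scan["lod"].iloc[best] <= threshold or not np.isfinite(threshold):
            break
        cofactors.append(scan["marker"].iloc[best])
    peaks, total_r2 = annotate_peaks(cross, y, cofactors, trait=trait)
    return ForwardSearchResult(
        peaks=peaks, threshold=threshold, scans=scans, total_variance_explained=total_r2
    )


def _complete_design(cross: CrossGenotypes, y: np.ndarray, idx: list[int]):
    keep = ~np.isnan(y)
    G = cross.geno[keep][:, idx]
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    return G, y[keep]


def annotate_peaks(
    cross: CrossGenotypes,
    phenotype: np.ndarray,
    peak_markers: list[str],
    drop: float = 1.5,
    trait: str = "trait",
) -> tuple[list[QtlPeak], float]:
    """Confidence intervals, variance explained, and effect direction.

    For each peak the genome is rescanned conditioning on all *other*
    peaks; the CI is the contiguous run of markers on the peak's chromosome
    whose conditional LOD stays within ``drop`` of the peak.  Variance
    explained is reported both as the squared partial correlation given the
    other peaks and as the marginal single-marker R^2; the total is the R^2
    of the joint additive model.
    """
    y = np.asarray(phenotype, dtype=float)
    if not peak_markers:
        return [], float("nan")
    idx = [cross.marker_index(m) for m in peak_markers]
    G, yc = _complete_design(cross, y, idx)
    n = len(yc)
    X_full = np.column_stack([np.ones(n), G])
    beta, *_ = np.linalg.lstsq(X_full, yc, rcond=None)
    resid_full = yc - X_full @ beta
    rss_full = float(resid_full @ resid_full)
    tss = float(np.sum((yc - yc.mean()) ** 2))
    total_r2 = 1.0 - rss_full / tss

    peaks: list[QtlPeak] = []
    for k, marker in enumerate(peak_markers):
        others = [m for m in peak_markers if m != marker]
        scan = lod_scan(cross, y, cofactors=others)
        mi = cross.marker_index(marker)
        chrom = cross.markers["chrom"].iloc[mi]
        on_chrom = scan[scan["chrom"] == chrom].reset_index(drop=True)
        pk = int(on_chrom.index[on_chrom["marker"] == marker][0])
        peak_lod = float(on_chrom["lod"].iloc[pk])
        cutoff = peak_lod - drop
        lo = pk
        while lo - 1 >= 0 and on_chrom["lod"].iloc[lo - 1] >= cutoff:
            lo -= 1
        hi = pk
        while hi + 1 < len(on_chrom) and on_chrom["lod"].iloc[hi + 1] >= cutoff:
            hi += 1
        if lo == 0 or hi == len(on_chrom) - 1:
            log.info("peak %s: confidence interval reaches a chromosome edge", marker)
        # partial R^2 of this marker given the others
        if others:
            X_red = np.column_stack([np.ones(n), G[:, [j for j in range(len(idx)) if j != k]]])
            beta_r, *_ = np.linalg.lstsq(X_red, yc, rcond=None)
            resid_r = yc - X_red @ beta_r
            rss_red = float(resid_r @ resid_r)
        else:
            rss_red = tss
        partial = max(0.0, 1.0 - rss_full / rss_red) if rss_red > 0 else 0.0
        g = G[:, k]
        r_marg = np.corrcoef(g, yc)[0, 1] if np.std(g) > 0 else 0.0
        peaks.append(
            QtlPeak(
                trait=trait,
                marker=marker,
                chrom=chrom,
                pos=int(cross.markers["pos"].iloc[mi]),
                lod=peak_lod,
                ci_left_marker=on_chrom["marker"].iloc[lo],
                ci_right_marker=on_chrom["marker"].iloc[hi],
                ci_left_pos=int(on_chrom["pos"].iloc[lo]),
                ci_right_pos=int(on_chrom["pos"].iloc[hi]),
                var_exp_partial=partial,
                var_exp_marginal=float(r_marg**2),
                high_allele="CB4856" if beta[1 + k] > 0 else "N2",
                drop=drop,
            )
        )
    return peaks, total_r2


# ---------------------------------------------------------------------------
# Two-dimensional scan


@dataclass
class TwoDimScan:
    pairs: pd.DataFrame  # marker_a, marker_b, chrom_a, chrom_b, lod_full, lod_add, lod_int
    interaction_threshold: float
    grid_markers: list[str]

    def chrom_pair_maxima(self) -> pd.DataFrame:
        return (
            self.pairs.groupby(["chrom_a", "chrom_b"], sort=False)["lod_int"]
            .max()
            .reset_index(name="max_lod_int")
        )


def _thin_grid(cross: CrossGenotypes, grid_max: int) -> np.ndarray:
    M = cross.n_markers
    if M <= grid_max:
        return np.arange(M)
    k = int(np.ceil(M / grid_max))
    return np.arange(0, M, k)


def scan_two(
    cross: CrossGenotypes,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    grid_max: int = 1000,
) -> TwoDimScan:
    """Two-locus epistasis scan over all marker pairs on a (possibly
    thinned) grid.

    For each pair, ``lod_full`` compares y ~ gA + gB + gA:gB to the null
    intercept model and ``lod_add`` compares y ~ gA + gB to the null, both
    as (n/2) log10(RSS0/RSS); ``lod_int`` is their difference (>= 0 by
    model nesting).  The interaction threshold is the (1-alpha) quantile of
    the permuted genome-wide max ``lod_int``.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    grid = _thin_grid(cross, grid_max)
    G = cross.geno[keep][:, grid]
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    yc = y[keep]
    n = len(yc)
    # observed phenotype in column 0, permutations after it
    Y = np.empty((n, 1 + n_perm))
    Y[:, 0] = yc
    for j in range(n_perm):
        Y[:, 1 + j] = rng.permutation(yc)
    Yc = Y - Y.mean(axis=0)
    rss0 = (Yc * Yc).sum(axis=0)
    yty = (Y * Y).sum(axis=0)

    chroms = cross.markers["chrom"].to_numpy()[grid]
    names = cross.markers["marker"].to_numpy()[grid]
    rows = []
    max_int = np.zeros(1 + n_perm)
    ones = np.ones(n)
    for i in range(len(grid)):
        gi = G[:, i]
        for j in range(i + 1, len(grid)):
            gj = G[:, j]
            X_add = np.column_stack([ones, gi, gj])
            X_full = np.column_stack([X_add, gi * gj])
            Qa, Ra = np.linalg.qr(X_add)
            if abs(Ra[2, 2]) < 1e-10:  # collinear pair
                continue
            Qf, Rf = np.linalg.qr(X_full)
            if abs(Rf[3, 3]) < 1e-10:  # interaction column collinear
                continue
            proj_a = Qa.T @ Y
            proj_f = Qf.T @ Y
            rss_add = np.clip(yty - (proj_a * proj_a).sum(axis=0), 1e-300, None)
            rss_full = np.clip(yty - (proj_f * proj_f).sum(axis=0), 1e-300, None)
            lod_full = (n / 2.0) * np.log10(rss0 / rss_full)
            lod_add = (n / 2.0) * np.log10(rss0 / rss_add)
            lod_int = np.maximum(0.0, lod_full - lod_add)
            np.maximum(max_int, lod_int, out=max_int)
            rows.append(
                (names[i], names[j], chroms[i], chroms[j],
                 lod_full[0], lod_add[0], lod_int[0])
            )
    pairs = pd.DataFrame(
        rows,
        columns=["marker_a", "marker_b", "chrom_a", "chrom_b", "lod_full", "lod_add", "lod_int"],
    )
    thr = float(np.quantile(max_int[1:], 1.0 - alpha)) if n_perm > 0 else float("nan")
    return TwoDimScan(pairs=pairs, interaction_threshold=thr, grid_markers=list(names))


def interaction_anova(phenotype: np.ndarray, geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """F-test p-value of the gA:gB term in y ~ gA + gB + gA:gB.

    Both markers must be biallelic with every genotype class populated.
    """
    y = np.asarray(phenotype, dtype=float)
    ga = np.asarray(geno_a, dtype=float)
    gb = np.asarray(geno_b, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(ga) | np.isnan(gb))
    y, ga, gb = y[keep], ga[keep], gb[keep]
    for a in np.unique(ga):
        for b in np.unique(gb):
            if not np.any((ga == a) & (gb == b)):
                raise ValueError(f"empty genotype cell ({a}, {b})")
    n = len(y)
    ones = np.ones(n)
    X_add = np.column_stack([ones, ga, gb])
    X_full = np.column_stack([X_add, ga * gb])
    rss_add = float(np.sum((y - X_add @ np.linalg.lstsq(X_add, y, rcond=None)[0]) ** 2))
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    df2 = n - X_full.shape[1]
    F = (rss_add - rss_full) / (rss_full / df2)
    return float(stats.f.sf(F, 1, df2))
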