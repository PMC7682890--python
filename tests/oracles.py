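"""Independent reference implementations used only to check the package.

Each oracle is deliberately written along a different computational path
from the implementation it checks: regression likelihood-ratio LOD
instead of the correlation formula, explicit pairwise-difference Tajima
windows instead of the vectorized allele-count form, and an O(M^2)
pairwise LD pruner instead of the windowed matrix version.
"""

import numpy as np


def regression_lod(g: np.ndarray, y: np.ndarray) -> float:
    """Likelihood-ratio LOD of the single-marker linear regression,
    (n/2) * log10(RSS0 / RSS1)."""
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    if rss1 <= 0:
        return float("inf")
    return (n / 2.0) * np.log10(rss0 / rss1)


def tajimas_d_window(haplotypes: np.ndarray) -> float:
    """Tajima's D of one window by explicit pairwise differences.

    ``haplotypes`` is n x S (0/1).  Returns NaN when nothing segregates.
    """
    H = np.asarray(haplotypes)
    n, S_all = H.shape
    seg = [j for j in range(S_all) if 0 < H[:, j].sum() < n]
    S = len(seg)
    if S == 0:
        return float("nan")
    # pi as the average number of differences over all sample pairs
    total = 0
    pairs = 0
    for i in range(n):
        for k in range(i + 1, n):
            total += int(np.sum(H[i, seg] != H[k, seg]))
            pairs += 1
    pi_sum = total / pairs  # mean pairwise differences
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))


def brute_force_ld_prune(dosage: np.ndarray, maf: np.ndarray,
                         r2_max: float, window: int, step: int) -> np.ndarray:
    """Pairwise-loop LD pruner with the same window/tie semantics as the
    package: windows over original variant indices advancing by step;
    within each window the worst surviving pair above r2_max loses its
    lower-MAF member (tie: rightmost).  Returns the surviving indices."""
    X = dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    M = X.shape[1]
    alive = [True] * M

    def corr2(a, b):
        xa, xb = X[:, a], X[:, b]
        if xa.std() == 0 or xb.std() == 0:
            return 0.0
        return float(np.corrcoef(xa, xb)[0, 1] ** 2)

    start = 0
    while start < M:
        members = [j for j in range(start, min(start + window, M)) if alive[j]]
        while True:
            best, pair = 0.0, None
            for ii in range(len(members)):
                for jj in range(ii + 1, len(members)):
                    if not (alive[members[ii]] and alive[members[jj]]):
                        continue
                    r2 = corr2(members[ii], members[jj])
                    if r2 > best:
                        best, pair = r2, (members[ii], members[jj])
            if pair is None or best <= r2_max:
                break
            a, b = pair
            if maf[a] < maf[b]:
                victim = a
            elif maf[b] < maf[a]:
                victim = b
            else:
                victim = max(a, b)
            alive[victim] = False
        if start + window >= M:
            break
        start += step
    return np.flatnonzero(alive)
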