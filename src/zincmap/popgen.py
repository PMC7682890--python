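"""Region-level population genetics: sliding-window Tajima's D and
neighbor-joining relatedness trees.

Tajima's D contrasts two estimators of the scaled mutation rate theta —
mean pairwise diversity (pi) and the Watterson estimator S/a1 — within
sliding physical windows (10 kb window, 1 kb step by default):

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))

with the Tajima (1989) constants a1..e2 determined by the number of
sampled haplotypes.  D near zero is consistent with neutrality; windows
with no segregating sites have no defined D and are emitted as missing.

Strain relatedness over a region is summarized by a neighbor-joining
tree built from pairwise Hamming distances (proportion of differing
calls over shared non-missing sites), midpoint rooted, written as
Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def tajima_constants(n: int) -> dict:
    """Tajima (1989) constants for a sample of n haplotypes."""
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alt_counts: np.ndarray, n: int) -> float:
    """Tajima's D from per-site alternate-allele counts among n haplotypes.

    Sites with count 0 or n are ignored (not segregating); returns NaN
    when no site segregates.
    """
    j = np.asarray(alt_counts, dtype=float)
    j = j[(j > 0) & (j < n)]
    S = len(j)
    if S == 0:
        return float("nan")
    pi = float(np.sum(2.0 * j * (n - j) / (n * (n - 1))))
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi - S / c["a1"]) / np.sqrt(var))


def tajimas_d_windows(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    start: int | float | None = None,
    end: int | float | None = None,
    window: int = 10_000,
    step: int = 1_000,
) -> pd.DataFrame:
    """Sliding-window Tajima's D over a physical region.

    ``haplotypes`` is n x S (rows = haplotypes, columns = sites, entries
    0/1); ``positions`` are the site coordinates.  Windows are
    left-aligned at ``start``, advance by ``step``, and the last window is
    right-truncated at ``end``.  Each window row reports [start, end]
    (inclusive), S, pi and D (NaN when S = 0).
    """
    H = np.asarray(haplotypes)
    pos = np.asarray(positions, dtype=float)
    n = H.shape[0]
    if n < 4:
        raise ValueError("need >= 4 haplotypes for a meaningful D")
    if start is None:
        start = pos.min()
    if end is None:
        end = pos.max()
    alt = H.sum(axis=0).astype(float)
    rows = []
    w_start = float(start)
    while w_start <= end:
        w_end = min(w_start + window - 1, end)
        in_win = (pos >= w_start) & (pos <= w_end)
        j = alt[in_win]
        j = j[(j > 0) & (j < n)]
        S = int(len(j))
        pi = float(np.sum(2.0 * j * (n - j) / (n * (n - 1)))) if S else 0.0
        D = tajimas_d(j, n) if S else float("nan")
        rows.append((w_start, w_end, S, pi, D))
        if w_end >= end:
            break
        w_start += step
    return pd.DataFrame(rows, columns=["start", "end", "S", "pi", "D"])


# ---------------------------------------------------------------------------
# Neighbor joining


def hamming_distances(calls: np.ndarray, labels: list[str]):
    """Pairwise proportion of differing calls over shared non-missing
    sites.  ``calls`` is n_strains x n_sites with NaN for missing."""
    X = np.asarray(calls, dtype=float)
    n = X.shape[0]
    obs = ~np.isnan(X)
    D = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            shared = obs[i] & obs[k]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"strains {labels[i]!r} and {labels[k]!r} share no observed sites"
                )
            D[i, k] = D[k, i] = float(np.mean(X[i, shared] != X[k, shared]))
    return D


@dataclass
class StrainTree:
    newick: str
    leaves: list[str]

    def skbio(self):
        from io import StringIO

        from skbio import TreeNode

        return TreeNode.read(StringIO(self.newick))


def nj_from_distances(D: np.ndarray, labels: list[str]):
    """Unrooted neighbor-joining tree (skbio TreeNode) from a distance
    matrix; negative branch lengths are set to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(labels) < 3:
        raise ValueError("need >= 3 strains")
    dm = DistanceMatrix(np.asarray(D, dtype=float), ids=[str(s) for s in labels])
    return nj(dm, neg_as_zero=True)


def nj_tree(calls: np.ndarray, labels: list[str]) -> StrainTree:
    """Neighbor-joining tree from a variant matrix restricted to a region.

    Distances are Hamming proportions over shared non-missing sites; the
    tree is midpoint rooted and negative branch lengths are clamped to
    zero.
    """
    D = hamming_distances(calls, labels)
    tree = nj_from_distances(D, labels)
    tree = tree.root_at_midpoint()
    newick = str(tree).strip()
    return StrainTree(newick=newick, leaves=[str(s) for s in labels])


def interval_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    if end < start:
        raise ValueError("end < start")
    return int(end) - int(start) + 1


def parse_region(region: str):
    """Parse a 'chrom:start-end' region string (1-based inclusive)."""
    chrom, span = region.split(":")
    start, end = span.replace(",", "").split("-")
    return chrom, int(start), int(end)
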