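"""Broad-sense heritability and pairwise strain comparisons.

Broad-sense heritability is the fraction of phenotypic variance among
wells that is attributable to strain identity,

    H^2 = sigma^2_strain / (sigma^2_strain + sigma^2_residual),

estimated by REML under the one-way random-effects model
``value = mu + strain + e``.  The REML profile over the variance ratio
has a cheap closed form for this model (group-wise Sherman-Morrison),
which makes a nonparametric strain-level bootstrap for the confidence
interval affordable; the profile estimator is cross-checked against
statsmodels MixedLM in the test suite.

Pairwise strain differences are tested with Tukey's HSD on a one-way
ANOVA of phenotype on strain, annotated with the conventional star
notation; Bonferroni-adjusted p-values are exposed alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

STAR_THRESHOLDS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]


def stars(p: float) -> str:
    for cut, label in STAR_THRESHOLDS:
        if p < cut:
            return label
    return "ns"


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    ci_low: float
    ci_high: float
    n_strains: int
    n_wells: int
    sigma2_strain: float
    sigma2_resid: float


def _oneway_reml(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML variance components (sigma2_strain, sigma2_resid) of
    value = mu + strain(random) + e, by profiling the ratio
    gamma = sigma2_strain / sigma2_resid."""
    codes, _ = pd.factorize(groups)
    k = codes.max() + 1
    n_i = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=values, minlength=k)
    means = sums / n_i
    ssw = float(np.sum((values - means[codes]) ** 2))
    N = len(values)

    def neg2_reml(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        w = 1.0 + n_i * g
        wt = n_i / w
        mu = np.sum(wt * means) / np.sum(wt)
        q = ssw + np.sum(n_i * (means - mu) ** 2 / w)
        s2e = q / (N - 1)
        return (N - 1) * np.log(s2e) + np.sum(np.log(w)) + np.log(np.sum(wt))

    res = optimize.minimize_scalar(neg2_reml, bounds=(-30.0, 30.0), method="bounded")
    gamma = float(np.exp(res.x))
    # recompute components at the optimum
    w = 1.0 + n_i * gamma
    wt = n_i / w
    mu = np.sum(wt * means) / np.sum(wt)
    q = ssw + np.sum(n_i * (means - mu) ** 2 / w)
    s2e = q / (N - 1)
    # boundary: gamma pinned at the lower bound means sigma2_strain ~ 0
    if res.x <= -29.99:
        gamma = 0.0
    s2s = gamma * s2e
    return float(s2s), float(s2e)


def estimate_heritability(
    values: np.ndarray,
    strains: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    trait: str = "trait",
) -> HeritabilityEstimate:
    """H^2 with a percentile CI from bootstrapping strains with replacement.

    Requires >= 2 strains and >= 2 replicates for at least one strain.
    Negative component estimates are clamped to zero (warned); a trait
    with zero total variance is an error.
    """
    values = np.asarray(values, dtype=float)
    strains = np.asarray(strains)
    ok = ~np.isnan(values)
    values, strains = values[ok], strains[ok]
    uniq = np.unique(strains)
    if len(uniq) < 2:
        raise ValueError("need >= 2 strains")
    if np.var(values) == 0:
        raise ValueError("total variance is zero; heritability undefined")
    s2s, s2e = _oneway_reml(values, strains)
    if s2s < 0 or s2e < 0:
        warnings.warn("negative variance component clamped to 0")
        s2s, s2e = max(s2s, 0.0), max(s2e, 0.0)
    h2 = s2s / (s2s + s2e)

    rng = np.random.default_rng(seed)
    by_strain = {s: values[strains == s] for s in uniq}
    boots = []
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        v = np.concatenate([by_strain[s] for s in pick])
        g = np.concatenate([np.full(len(by_strain[s]), i) for i, s in enumerate(pick)])
        if np.var(v) == 0:
            continue
        bs, be = _oneway_reml(v, g)
        bs, be = max(bs, 0.0), max(be, 0.0)
        if bs + be > 0:
            boots.append(bs / (bs + be))
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low = ci_high = h2
    return HeritabilityEstimate(
        trait=trait, h2=float(h2), ci_low=float(ci_low), ci_high=float(ci_high),
        n_strains=len(uniq), n_wells=len(values),
        sigma2_strain=s2s, sigma2_resid=s2e,
    )


def tukey_pairwise(values: np.ndarray, strains: np.ndarray) -> pd.DataFrame:
    """All pairwise strain differences with Tukey-HSD adjusted p-values.

    Returns a DataFrame with strain_a, strain_b, diff, p_adj (studentized
    range), p_bonferroni (pooled t-test times the number of pairs, capped
    at 1), and stars from the Tukey p.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    strains = np.asarray(strains)
    uniq, counts = np.unique(strains, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 strains with >= 2 replicates each")
    ssw = sum(np.var(values[strains == s], ddof=0) * (values[strains == s]).size
              for s in uniq)
    if ssw == 0:
        raise ValueError("zero within-group variance everywhere; p undefined")

    res = pairwise_tukeyhsd(values, strains)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out = pd.DataFrame({
        "strain_a": frame["group1"],
        "strain_b": frame["group2"],
        "diff": frame["meandiff"].astype(float),
        "p_adj": frame["p-adj"].astype(float),
    })
    # Bonferroni-adjusted pooled-variance t-tests over the same pairs
    n_pairs = len(out)
    dfw = len(values) - len(uniq)
    msw = ssw / dfw
    p_bonf = []
    for a, b in zip(out["strain_a"], out["strain_b"]):
        va, vb = values[strains == a], values[strains == b]
        se = np.sqrt(msw * (1 / len(va) + 1 / len(vb)))
        t = (vb.mean() - va.mean()) / se
        p_bonf.append(min(1.0, 2 * stats.t.sf(abs(t), dfw) * n_pairs))
    out["p_bonferroni"] = p_bonf
    out["stars"] = [stars(p) for p in out["p_adj"]]
    return out
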