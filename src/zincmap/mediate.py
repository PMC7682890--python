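"""Mediation of a QTL effect through gene expression.

Two linear models are fit at a QTL peak marker: a mediator model
``m ~ g`` (expression on genotype, coefficient a) and an outcome model
``y ~ g + m`` (phenotype on genotype and expression, genotype coefficient
c' and expression coefficient b).  The indirect effect transmitted
through expression — the average causal mediation effect (ACME) — is the
product a*b; the direct effect (ADE) is c'; in these linear models
ACME + ADE equals the total effect (the coefficient of ``y ~ g``)
exactly on any given sample.  Uncertainty comes from a nonparametric
strain bootstrap: percentile intervals and a two-sided p-value for the
ACME.  A screen runs every candidate probe at the same marker and flags
probes above the 95th percentile of the ACME distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class MediationEstimate:
    probe: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    p_acme: float
    ci_low: float
    ci_high: float
    n: int
    total_near_zero: bool


def _paths(g: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS path coefficients a (g->m), b (m->y | g), c' (g->y | m)."""
    gc = g - g.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sgg = (gc * gc).sum(axis=-1)
    smm = (mc * mc).sum(axis=-1)
    sgm = (gc * mc).sum(axis=-1)
    sgy = (gc * yc).sum(axis=-1)
    smy = (mc * yc).sum(axis=-1)
    a = sgm / sgg
    det = sgg * smm - sgm * sgm
    c_prime = (smm * sgy - sgm * smy) / det
    b = (sgg * smy - sgm * sgy) / det
    total = sgy / sgg
    return a, b, c_prime, total


def mediate(
    phenotype: np.ndarray,
    mediator: np.ndarray,
    genotype: np.ndarray,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    probe: str = "probe",
    min_n: int = 30,
) -> MediationEstimate:
    """Product-of-coefficients mediation estimate with strain bootstrap."""
    y = np.asarray(phenotype, dtype=float)
    m = np.asarray(mediator, dtype=float)
    g = np.asarray(genotype, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(m) | np.isnan(g))
    y, m, g = y[keep], m[keep], g[keep]
    n = len(y)
    if n < min_n:
        raise ValueError(f"need >= {min_n} strains with phenotype, mediator and genotype")
    if np.var(m) == 0:
        raise ValueError("zero variance in mediator")
    if np.var(g) == 0:
        raise ValueError("zero variance in genotype")
    if abs(np.corrcoef(g, m)[0, 1]) > 1 - 1e-12:
        raise ValueError("mediator collinear with genotype; outcome model singular")

    a, b, c_prime, total = _paths(g, m, y)
    acme = float(a * b)
    ade = float(c_prime)
    total = float(total)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_sim, n))
    gb, mb, yb = g[idx], m[idx], y[idx]
    ok = (gb.var(axis=1) > 0) & (mb.var(axis=1) > 0)
    ab, bb, _, _ = _paths(gb[ok], mb[ok], yb[ok])
    acme_b = ab * bb
    acme_b = acme_b[np.isfinite(acme_b)]
    if len(acme_b) == 0:
        raise ValueError("all bootstrap resamples degenerate")
    ci_low, ci_high = np.percentile(acme_b, [2.5, 97.5])
    p_lo = np.mean(acme_b <= 0)
    p_hi = np.mean(acme_b >= 0)
    p_acme = min(1.0, 2.0 * min(p_lo, p_hi))

    near_zero = abs(total) < 1e-8 * max(1.0, np.std(y))
    prop = 0.0 if near_zero else float(np.clip(acme / total, 0.0, 1.0))
    return MediationEstimate(
        probe=probe, acme=acme, ade=ade, total=total, prop_mediated=prop,
        p_acme=float(p_acme), ci_low=float(ci_low), ci_high=float(ci_high),
        n=n, total_near_zero=bool(near_zero),
    )


def mediation_screen(
    phenotype: np.ndarray,
    probes: pd.DataFrame,
    genotype: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Mediate every probe (rows of ``probes``, columns = strains) at one
    marker; flag probes whose ACME exceeds the 95th percentile of the
    ACME distribution across probes.  Per-probe failures become missing
    rows (logged), never a global failure."""
    if len(probes) < 2:
        raise ValueError("need >= 2 probes to screen")
    seeds = np.random.SeedSequence(seed).spawn(len(probes))
    rows = []
    for (name, expr), ss in zip(probes.iterrows(), seeds):
        try:
            est = mediate(
                phenotype, expr.to_numpy(dtype=float), genotype,
                n_sim=n_sim, seed=np.random.default_rng(ss), probe=str(name),
            )
            rows.append(vars(est))
        except ValueError as err:
            log.warning("probe %s skipped: %s", name, err)
            rows.append({"probe": str(name), "acme": np.nan})
    table = pd.DataFrame(rows).set_index("probe")
    cutoff = float(np.nanpercentile(table["acme"], 95))
    table["flagged"] = table["acme"] > cutoff
    return table, cutoff
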