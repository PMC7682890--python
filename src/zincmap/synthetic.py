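"""Synthetic data generators with known ground truth.

Every input class the pipeline consumes can be generated here: a
recombinant-inbred genotype mosaic, additive QTL phenotypes with strain
and assay variance components, per-animal sorter records, expression
traits with a planted mediating probe, a structured wild-isolate panel
with a causal haplotype class, and neutral coalescent haplotypes for
calibrating Tajima's D.  Each generator is a pure function of its
parameters and seed; truth records travel alongside the data so
recovery can be scored.

Defaults are a desk-scale version of the study design they emulate: 6
chromosomes with ~1,000 markers for 250 recombinant strains (the real
panel used 13,003 SNPs on 253 strains), an 81-strain wild panel, and a
17-probe mediation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import VariantMatrix
from .linkage import CrossGenotypes

CHROMS = ["I", "II", "III", "IV", "V", "X"]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class CrossSpec:
    """Recombinant-inbred panel layout.

    ``genetic_length_m`` is the per-chromosome map length in Morgans and
    ``map_expansion`` the factor by which advanced-intercross breeding
    inflates the observed recombination fraction relative to a single
    meiosis (~4 for the emulated panel design).
    """

    n_strains: int = 250
    n_chrom: int = 6
    markers_per_chrom: int = 167
    chrom_length_bp: int = 15_000_000
    genetic_length_m: float = 0.5
    map_expansion: float = 4.0

    def switch_prob(self) -> float:
        """Adjacent-marker recombination probability after map expansion."""
        d = self.genetic_length_m / max(1, self.markers_per_chrom - 1)
        r = 0.5 * (1.0 - np.exp(-2.0 * d))  # Haldane single-meiosis fraction
        return float(min(0.49, self.map_expansion * r))


def simulate_cross(spec: CrossSpec = CrossSpec(), seed=0) -> CrossGenotypes:
    """Fully homozygous recombinant genotypes as two-state Markov mosaics.

    Each strain starts each chromosome on a random parental allele and
    switches between parents at adjacent markers with the expansion-
    scaled recombination probability.
    """
    if spec.markers_per_chrom < 1:
        raise ValueError("need >= 1 marker per chromosome")
    rng = _rng(seed)
    p_switch = spec.switch_prob()
    blocks, marker_rows = [], []
    for c in range(spec.n_chrom):
        chrom = CHROMS[c % len(CHROMS)] if spec.n_chrom <= len(CHROMS) else f"chr{c + 1}"
        m = spec.markers_per_chrom
        first = rng.integers(0, 2, size=(spec.n_strains, 1))
        switches = rng.random((spec.n_strains, m - 1)) < p_switch
        geno = np.concatenate([first, switches], axis=1).cumsum(axis=1) % 2
        blocks.append(geno.astype(float))
        pos = np.linspace(1, spec.chrom_length_bp, m).astype(int)
        marker_rows.extend(
            {"marker": f"{chrom}_{p}", "chrom": chrom, "pos": int(p)} for p in pos
        )
    strains = np.array([f"QX{i:03d}" for i in range(spec.n_strains)])
    return CrossGenotypes(
        strains=strains,
        markers=pd.DataFrame(marker_rows),
        geno=np.concatenate(blocks, axis=1),
    )


@dataclass
class PhenotypeSpec:
    """Additive QTL architecture: each entry of ``qtl`` is (marker index,
    fraction of phenotypic variance, sign)."""

    qtl: list = field(default_factory=list)
    strain_frac: float = 0.0  # non-QTL strain (line) variance fraction
    total_var: float = 1.0


def simulate_phenotypes(cross: CrossGenotypes, spec: PhenotypeSpec = PhenotypeSpec(),
                        seed=0):
    """Strain phenotypes y = sum_i beta_i g_i + line effect + noise.

    Effects are calibrated against the *empirical* genotype variance of
    each QTL marker so the realized variance fraction matches the spec in
    expectation.  Returns (values, truth dict).
    """
    rng = _rng(seed)
    fracs = [q[1] for q in spec.qtl]
    if sum(fracs) + spec.strain_frac > 1.0:
        raise ValueError("variance fractions sum above 1")
    n = cross.n_strains
    y = np.zeros(n)
    truth = {"qtl": [], "strain_frac": spec.strain_frac}
    for marker_idx, frac, sign in spec.qtl:
        g = cross.geno[:, marker_idx]
        vg = np.var(g)
        if vg == 0:
            raise ValueError(f"monomorphic QTL marker {marker_idx}")
        beta = np.sign(sign) * np.sqrt(frac * spec.total_var / vg)
        y += beta * g
        truth["qtl"].append(
            {"marker_idx": int(marker_idx),
             "marker": cross.markers["marker"].iloc[marker_idx],
             "frac": frac, "beta": float(beta)}
        )
    if spec.strain_frac > 0:
        y += rng.normal(0, np.sqrt(spec.strain_frac * spec.total_var), n)
    resid = max(0.0, 1.0 - sum(fracs) - spec.strain_frac) * spec.total_var
    y += rng.normal(0, np.sqrt(resid), n)
    return y, truth


@dataclass
class SorterSpec:
    """Per-animal record generation around strain-and-condition means."""

    n_assays: int = 3
    wells_per_strain: int = 3  # per assay
    animals_per_well: int = 30
    parents_sorted: int = 3
    tof_base: float = 300.0
    ext_per_tof: float = 0.25
    assay_sd: float = 0.1  # lognormal scale of assay offsets
    animal_cv: float = 0.1  # per-animal lognormal noise
    outlier_wells: int = 0
    outlier_factor: float = 3.0


def simulate_sorter_records(strain_effects: dict, spec: SorterSpec = SorterSpec(),
                            seed=0, condition: str = "zinc-500uM"):
    """Per-animal sorter records for strains with known multiplicative
    drug effects (``strain_effects``: strain -> TOF multiplier).

    Returns (records DataFrame, truth) where truth labels the injected
    outlier wells.
    """
    rng = _rng(seed)
    assay_offsets = rng.normal(0, spec.assay_sd, spec.n_assays)
    rows = []
    well_keys = []
    for strain, effect in strain_effects.items():
        for a in range(spec.n_assays):
            for w in range(spec.wells_per_strain):
                well_keys.append((strain, f"assay{a + 1}", "p1", f"{strain}_a{a + 1}_w{w + 1}"))
    outliers = set()
    if spec.outlier_wells:
        pick = rng.choice(len(well_keys), size=spec.outlier_wells, replace=False)
        outliers = {well_keys[i] for i in pick}
    for strain, assay, plate, well in well_keys:
        a = int(assay[5:]) - 1
        mu_tof = spec.tof_base * strain_effects[strain] * np.exp(assay_offsets[a])
        if (strain, assay, plate, well) in outliers:
            mu_tof *= spec.outlier_factor
        # brood size varies around the mean count with the strain effect
        n_animals = max(1, int(rng.poisson(spec.animals_per_well * strain_effects[strain])))
        tof = mu_tof * np.exp(rng.normal(0, spec.animal_cv, n_animals))
        ext = tof * spec.ext_per_tof * np.exp(rng.normal(0, spec.animal_cv, n_animals))
        for t, e in zip(tof, ext):
            rows.append((strain, assay, plate, well, condition, t, e))
    records = pd.DataFrame(
        rows, columns=["strain", "assay", "plate", "well", "condition", "tof", "ext"]
    )
    truth = {"outlier_wells": sorted(outliers), "assay_offsets": assay_offsets.tolist()}
    return records, truth


@dataclass
class MediationSpec:
    """One mediating probe among decoys: m = a g + eps, y = b m + c g + eps'."""

    a: float = 1.0
    b: float = 1.0
    c: float = 0.0  # direct (unmediated) genotype effect
    noise_m: float = 0.5
    noise_y: float = 0.5
    n_probes: int = 17  # total probes including the planted mediator


def simulate_expression(cross: CrossGenotypes, marker_idx: int,
                        spec: MediationSpec = MediationSpec(), seed=0):
    """Expression table (probes x strains) with one planted mediator.

    Returns (probes DataFrame, phenotype, truth).  Decoy probes are
    independent noise.
    """
    rng = _rng(seed)
    g = cross.geno[:, marker_idx]
    n = cross.n_strains
    m = spec.a * g + rng.normal(0, spec.noise_m, n)
    y = spec.b * m + spec.c * g + rng.normal(0, spec.noise_y, n)
    rows = {"mediator": m}
    for i in range(spec.n_probes - 1):
        rows[f"decoy{i + 1:02d}"] = rng.normal(0, 1.0, n)
    probes = pd.DataFrame(rows, index=cross.strains).T
    truth = {"mediator": "mediator", "acme": spec.a * spec.b,
             "marker_idx": int(marker_idx)}
    return probes, y, truth


@dataclass
class WildPanelSpec:
    """Structured wild-isolate panel with a causal haplotype class.

    Per-variant ancestral frequencies are drawn once, then diverged
    between subpopulations by a Balding-Nichols model with fixation index
    ``divergence``.  The phenotype mixes a causal-class effect, a
    polygenic background proportional to the realized kinship, and
    residual noise, with the stated variance fractions.
    """

    n_strains: int = 81
    n_variants: int = 2_000
    n_chrom: int = 6
    n_subpop: int = 2
    divergence: float = 0.2
    causal_frac: float = 0.115  # variance fraction of the haplotype class
    polygenic_frac: float = 0.3
    subpop_frac: float = 0.0  # variance fraction of a subpopulation mean shift
    causal_class_freq: float = 0.25


def simulate_wild_panel(spec: WildPanelSpec = WildPanelSpec(), seed=0):
    """Returns (VariantMatrix, phenotype, truth).

    truth carries the subpopulation labels, the causal class labels, and
    the per-component variance fractions.
    """
    rng = _rng(seed)
    n, M = spec.n_strains, spec.n_variants
    sub = rng.integers(0, spec.n_subpop, n)
    p_anc = rng.uniform(0.1, 0.9, M)
    F = spec.divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(spec.n_subpop, M))
    else:
        p_sub = np.broadcast_to(p_anc, (spec.n_subpop, M)).copy()
    dosage = (rng.random((n, M)) < p_sub[sub]).astype(float)

    per_chrom = int(np.ceil(M / spec.n_chrom))
    chroms, poss = [], []
    for j in range(M):
        c = j // per_chrom
        chroms.append(CHROMS[c % len(CHROMS)])
        poss.append(1 + (j % per_chrom) * 5_000)
    variants = pd.DataFrame({
        "chrom": chroms, "pos": poss,
        "ref": "A", "alt": "T",
    })
    strains = np.array([f"WI{i:03d}" for i in range(n)])
    vm = VariantMatrix(strains=strains, variants=variants, dosage=dosage)

    # causal haplotype class (e.g. functional vs deletion): random assignment
    classes = np.where(rng.random(n) < spec.causal_class_freq, "deletion", "functional")
    z = (classes == "deletion").astype(float)
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)

    X = 2 * dosage - 1
    Z = X - X.mean(axis=0)
    u = Z @ rng.normal(0, 1, M) / np.sqrt(M)
    u = (u - u.mean()) / (u.std() if u.std() > 0 else 1.0)

    # subpopulation mean shift: the confounder a mixed model must absorb
    sub_means = rng.normal(0, 1, spec.n_subpop)
    s_eff = sub_means[sub]
    if s_eff.std() > 0:
        s_eff = (s_eff - s_eff.mean()) / s_eff.std()
    resid_frac = max(0.0, 1.0 - spec.causal_frac - spec.polygenic_frac - spec.subpop_frac)
    y = (np.sqrt(spec.causal_frac) * z
         + np.sqrt(spec.polygenic_frac) * u
         + np.sqrt(spec.subpop_frac) * s_eff
         + rng.normal(0, np.sqrt(resid_frac), n))
    truth = {
        "subpop": sub.tolist(), "classes": classes.tolist(),
        "causal_frac": spec.causal_frac, "polygenic_frac": spec.polygenic_frac,
    }
    return vm, y, truth


def simulate_neutral_haplotypes(n: int = 20, theta: float = 10.0, seed=0,
                                region_length: float = 1.0, rho: float = 0.0):
    """Neutral coalescent haplotypes under the infinite-sites model.

    A Kingman genealogy (haploid sample of ``n``, coalescent time units)
    receives Poisson mutations at total rate theta/2 per unit branch
    length, each at a unique position uniform on [0, region_length).
    ``rho`` is the scaled recombination rate of the whole region (0 for a
    single shared genealogy).  Returns (haplotypes n x S in {0,1},
    positions in [0, region_length)).
    """
    import msprime

    if n < 2:
        raise ValueError("need n >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = _rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0,
        sequence_length=region_length, discrete_genome=False,
        recombination_rate=rho / (2.0 * region_length),
        random_seed=ms_seed,
    )
    if theta > 0:
        ts = msprime.sim_mutations(
            ts, rate=theta / (2.0 * region_length),
            model=msprime.BinaryMutationModel(), discrete_genome=False,
            random_seed=ms_seed + 1,
        )
    H = ts.genotype_matrix().T  # n x S
    pos = np.array([s.position for s in ts.sites()])
    return np.asarray(H, dtype=np.int8), pos
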