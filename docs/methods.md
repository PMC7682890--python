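# Methods

This note documents the statistical models implemented in `zincmap`,
the defaults and their rationale, what the synthetic-data generators do
and do not emulate, and the numerical decisions that affect results.

## Sorter-phenotype processing

Per-animal sorter records (strain, assay, plate, well, condition, TOF,
EXT) are collapsed per well into four traits: `median.TOF`,
`median.EXT`, `median.norm.EXT`, and `norm.n` (animals per parent
sorted, a brood-size proxy).  `median.norm.EXT` is the **median of
per-animal EXT/TOF ratios**, not the ratio of the two medians: the
per-animal ratio is robust to within-well spread in developmental
stage, which dominates the difference between the two definitions.
Records with TOF ≤ 0 are rejected with a warning; a well known to the
design but empty of records is carried as missing, not zero.

Stages are ordered and enforced: `raw → assay_regressed → pruned →
control_regressed → unit_normalized`.

* **Assay regression** fits each trait on the assay factor
  (equivalently, centers within assay level); a single-well level gets
  residual 0.
* **Outlier pruning** offers two single-pass rules (bounds estimated
  once from the full group, then applied — no re-estimation):
  * `sd`: within each (condition, strain) group, drop wells more than
    2 SD from the group mean.  Per-strain rather than global grouping
    was an open choice; per-strain matches the rule's intent of
    removing technical failures against a strain's own replicates.
  * `bamf`: within each condition across strains, fences are
    [Q1 − 2·IQR, Q3 + 2·IQR] with **type-7 (linear-interpolation)
    quantiles**; wells outside are removed only when fewer than 5% of
    distinct strains have any well outside — the exemption protects
    genuine extreme strains in a genetically variable panel.  Note the
    exemption makes the rule inert in panels of ≤ 20 strains, where any
    single strain exceeds 5%; it is designed for RIAIL-scale panels.
  * Groups with < 3 wells are never pruned.  A row flagged for any
    trait is removed whole; pruning removes rows and never edits values.
* **Control regression** fits, per trait and jointly across strains
  (one slope, one intercept), the drug-condition values on the strain's
  mean control value and keeps the residuals: the drug-specific
  response used by every downstream mapping step.
* **Unit normalization** maps min→0, max→1 for display; a constant
  vector is an error.
* **Dose selection** scores each candidate dose by the mean over traits
  of the between-strain over within-strain mean squares from a one-way
  decomposition and returns the maximizer (the criterion that selected
  500 μM zinc in the emulated design).

## Heritability and strain contrasts

Broad-sense heritability uses the one-way random-effects model
y = μ + strain + ε, fit by REML.  For this model the REML profile over
γ = σ²ₛ/σ²ₑ has a closed form via group-wise Sherman–Morrison algebra,
which is what the package implements (it agrees with statsmodels
MixedLM to ~4 decimals in tests but is ~10³ faster, making a
1,000-resample strain-level bootstrap CI affordable).  Negative
component estimates are clamped to zero with a warning.  The CI is the
2.5/97.5 percentile interval over strains resampled with replacement —
a distribution-free choice, since no parametric CI is canonical here.

Pairwise strain comparisons use Tukey's HSD on the one-way ANOVA
(statsmodels), annotated with the conventional stars at
p < 0.05/0.01/0.001/0.0001; Bonferroni-adjusted pooled-t p-values are
reported alongside, defaulting to Tukey for display.

## Linkage mapping

The scan statistic is the correlation LOD,
LOD = −n·ln(1−r²)/(2·ln 10), identical to the likelihood-ratio LOD of
single-marker linear regression (the identity is enforced to 1e-10 in
tests and in the acceptance run).  Conventions:

* Genotypes are coded N2 = 0, CB4856 = 1; residual heterozygous or
  missing calls are missing, and correlations are pairwise-complete
  with per-marker n.
* |r| = 1 is capped at LOD = (n/2)·log₁₀(1/ε), ε = 1e-12, with warning.
* Cofactor conditioning residualizes the phenotype on the cofactor
  genotype columns (missing cofactor calls mean-imputed) before
  correlating — the marker-regression analogue of adding the QTL to the
  model.
* Permutations shuffle whole phenotype vectors against the intact
  genotype matrix, preserving linkage disequilibrium among markers; the
  threshold is the (1−α) empirical quantile of the per-permutation
  genome-wide max LOD.  Thresholds are computed **once per trait**, not
  re-permuted per forward-search iteration.
* The forward search adds the highest-scoring marker above threshold as
  a cofactor and rescans, stopping when nothing exceeds the threshold
  (ties go to the leftmost marker in map order; > 20 iterations aborts).
* Confidence intervals: for each peak, the genome is rescanned with all
  *other* peaks as cofactors and the CI is the contiguous run of
  markers on the peak's chromosome whose conditional LOD stays within
  1.5 of the peak (every CI marker therefore satisfies the drop bound;
  edge-reaching CIs are one-sided and logged).
* Variance explained is reported both ways the quantity is commonly
  meant: the squared partial correlation of the peak given all other
  peaks, and the marginal single-marker R²; the joint additive-model R²
  is the total.  The allelic direction is the sign of the marker
  coefficient in the joint model.

The two-dimensional scan compares, per marker pair, the full model
y ~ gA + gB + gA·gB and the additive model y ~ gA + gB against the
intercept-only null, each as (n/2)·log₁₀(RSS₀/RSS); the interaction
LOD is the difference (≥ 0 by nesting).  Pairs with collinear design
columns are skipped.  The scan may run on a thinned grid (every k-th
marker so the grid is ≤ 1,000 by default) — pair counts grow
quadratically and adjacent markers are nearly redundant.  The
interaction threshold is the 95th percentile of the permuted
genome-wide max interaction LOD, computed by projecting all permuted
phenotypes through each pair's QR factorization at once.  The explicit
two-locus ANOVA reports the F-test p of the interaction term.

## Mediation

At a QTL peak marker g, with expression mediator m and phenotype y, two
OLS fits — m ~ g (coefficient a) and y ~ g + m (coefficients c′ and b) —
give the mediated (indirect) effect a·b, the direct effect c′, and, on
any complete sample, the exact identity a·b + c′ = total effect of
y ~ g.  No treatment–mediator interaction term is included, so the
mediated effect is the same in both genotype classes.  Uncertainty is a
nonparametric strain bootstrap (default 1,000 resamples): percentile CI
and two-sided p for a·b.  The proportion mediated is a·b divided by the
total, clipped to [0, 1] and flagged when the total is near zero.  The
screen mediates every candidate probe at the same marker and flags
those above the 95th percentile of the mediation-estimate distribution;
per-probe failures (constant probes, collinearity) become missing rows,
never a global failure.  eQTL discovery for probe selection reuses the
linkage forward search on expression traits — no separate machinery.

## Mixed-model association

Wild-isolate dosages are homozygous 0/1.  Filtering drops variants with
any missing call (a relaxed `max_missing` is available) or minor-allele
frequency below 5%.  LD pruning is greedy within sliding windows
(defaults window = 50 variants, step = 10, r² > 0.8; these are exposed
because the emulated study did not state them): the worst surviving
pair loses its lower-MAF member, ties to the rightmost.  Kinship is
VanRaden-style: dosages recoded to ±1, mean-imputed, column-centered,
A = ZZᵀ/c with c = Σ 4p(1−p) so the mean diagonal is ~1.

The scan solves y = μ + xβ + u + ε with u ~ N(0, σ²_g K) through the
eigendecomposition of K.  The variance ratio is estimated once by REML
on the null model and reused for every marker (P3D); each marker is
then a weighted least-squares Wald t-test in the rotated basis,
vectorized across markers.  With K = I the scan reduces exactly to
per-marker OLS.  Variants with missing calls are refit exactly on their
observed strains at the null variance ratio.  A non-PSD kinship is
shrunk toward the identity with a warning.  Thresholds: Bonferroni
−log₁₀(α/M) over all M variants, and −log₁₀(α/n_eff) with n_eff the
Li & Ji (2005) effective number of tests — eigenvalues λ of the variant
correlation matrix each contribute 𝟙(λ ≥ 1) + frac(λ) (rounded to 8
decimals first to keep duplicated variants from leaking spurious
fractional parts).  Variants above the effective-tests threshold seed
regions of ±150 variants, clipped at chromosome ends and merged when
overlapping.  The haplotype-class effect is the one-way ANOVA R² of
phenotype on class labels with its F-test p.  A single global kinship
is used (no leave-one-chromosome-out).

## Population genetics

Tajima's D per window is (π − S/a₁)/√(e₁S + e₂S(S−1)) with the
constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ determined by the number of
haplotypes; π is computed from per-site allele counts as
Σ 2j(n−j)/(n(n−1)).  Windows are physical (default 10 kb, stepping
1 kb), left-aligned at the region start and right-truncated at its end;
a window with S = 0 has no defined D and is emitted as missing, never
as 0.  Note D is not exactly mean-zero under neutrality at finite
sample sizes: at n = 20, θ = 10 its expectation is ≈ −0.09, which is
what replicate means converge to.

Neighbor joining runs on pairwise Hamming proportions (differing calls
over shared non-missing sites; two strains sharing no observed site is
an error) via scikit-bio, computing distances directly from the variant
matrix — for equal-length variant strings a multiple alignment step
would be a no-op.  Negative branch lengths are clamped to zero (the
library's policy; additive inputs produce none).  Trees are
midpoint-rooted and serialized as Newick.  Interval lengths are 1-based
inclusive: end − start + 1 (so chrIII:147,076–147,186 is 111 bp).

## Synthetic data generators

Every generator is a pure function of (parameters, seed), with one root
RNG spawned into independent streams so adding a generator never
perturbs another's draws.  Defaults emulate the study design at desk
scale: 6 chromosomes × 167 markers for 250 recombinant strains (the
real panel: 13,003 SNPs × 253 strains), 81-strain wild panels, and
17-probe mediation screens.

* **Cross**: each chromosome of each strain is a two-state Markov
  mosaic; the adjacent-marker switch probability is the Haldane
  recombination fraction of the inter-marker map distance (0.5 M per
  chromosome by default) times a map-expansion factor (default 4)
  approximating the extra effective meioses of advanced-intercross
  inbreeding, capped at 0.49.
* **Phenotypes**: y = Σ βᵢgᵢ + strain effect + ε, with each β
  calibrated against the *empirical* genotype variance so the planted
  variance fraction is realized in expectation; fractions summing above
  1 are rejected.
* **Sorter records**: per-animal TOF is lognormal around a
  strain-by-condition mean with lognormal assay offsets; EXT is
  proportional to TOF with its own noise; per-well animal counts are
  Poisson around the mean brood scaled by the strain effect; outlier
  wells (mean shifted by a set factor) are injected with truth labels.
* **Expression**: one mediator probe m = a·g + ε with phenotype
  y = b·m + c·g + ε′ and independent-noise decoys.
* **Wild panel**: Balding–Nichols subpopulation divergence (default
  F = 0.2, two subpopulations), a causal haplotype class at a planted
  variance fraction (default 0.115), a polygenic background built from
  the panel's own centered genotypes, and an optional explicit
  subpopulation mean shift (`subpop_frac`) — the confounder used to
  demonstrate that the mixed model stays calibrated where OLS does not.
* **Neutral haplotypes**: msprime coalescent (haploid, N = 1, so time
  is in coalescent units) with infinite-sites mutations at rate θ/2 per
  unit branch length and optional scaled recombination ρ.

What the generators deliberately do **not** emulate: realistic
*C. elegans* demography and selfing, marker ascertainment, genotyping
error, hyper-divergent regions, probe cross-hybridization, plate
spatial effects, and contamination.  Passing tests therefore certify
the statistical machinery — error-rate calibration, recovery of planted
effects, oracle identities — not robustness to those real-data
artifacts.

## Problem sizes and runtime choices

The calibration experiments run at the panel sizes above: 200 null
simulations × 200 permutations for the genome-wide error rate, 50 runs
for QTL interval coverage, 25 runs × 17 probes for the mediation
screen, 4 structured panels × 1,500 variants for mixed-model
calibration, 500 coalescent replicates for Tajima's D, and 20 random
6-taxon trees for NJ consistency.  Permutation scans are vectorized as
matrix products against blocks of permuted phenotypes, which is what
makes 40,000 genome scans a matter of seconds.

## Known limitations

* The bamf pruning rule cannot act in small panels (see above).
* P3D underestimates per-marker variance-component uncertainty for
  markers of large effect; exact per-marker refitting is only applied
  to variants with missing calls.
* The forward search admits ~5% false-positive QTL per trait by
  construction of the genome-wide error rate; conditional scans can
  also promote secondary peaks on a detected chromosome.
* Mediation assumes linear models without exposure–mediator
  interaction and no unmeasured mediator–outcome confounding; the
  screen's 95th-percentile cutoff flags ~5% of probes even under a
  global null.
* The NJ implementation clamps negative branch lengths to zero, which
  can shorten path lengths slightly on strongly non-additive distance
  matrices.
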