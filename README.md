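# zincmap

A quantitative-genetics pipeline for mapping natural variation in the
*Caenorhabditis elegans* response to exogenous zinc, built for
researchers who phenotype nematode panels with a large-particle sorter
(COPAS BIOSORT) and map the resulting traits in recombinant-inbred and
wild-isolate panels.

The pipeline covers the full analysis chain:

1. **Sorter-phenotype processing** — collapse per-animal records
   (time-of-flight TOF ≈ length, extinction EXT ≈ optical density) into
   per-well traits (`median.TOF`, `median.EXT`, `median.norm.EXT`,
   `norm.n`), then regress out assay batches, prune outlier wells,
   regress the drug condition on the control to isolate the
   drug-specific response, and unit-normalize for display.
2. **Strain statistics** — broad-sense heritability
   H² = σ²ₛ/(σ²ₛ+σ²ₑ) by REML under a strain random-effects model with a
   strain-level bootstrap CI, and Tukey-HSD pairwise strain contrasts.
3. **Linkage mapping** — single-marker genome scans on a biallelic
   recombinant-inbred panel using the correlation LOD score

       LOD = −n · ln(1 − r²) / (2 · ln 10),

   with r the Pearson correlation of marker genotype (0 = N2 allele,
   1 = CB4856 allele) and phenotype; 5% genome-wide thresholds from
   1,000 phenotype permutations; iterative forward search with detected
   QTL as cofactors; 1.5-LOD-drop confidence intervals; per-QTL variance
   explained; a two-dimensional epistasis scan; and the two-locus
   interaction ANOVA.
4. **Mediation analysis** — for expression probes with an eQTL at a
   phenotype QTL, the indirect (mediated) effect is the product of the
   genotype→expression and expression→phenotype coefficients, with
   bootstrap uncertainty and a 95th-percentile screen cutoff.
5. **Mixed-model GWAS** — wild-isolate association with variant
   filtering (no missing calls, MAF ≥ 5%), LD pruning, VanRaden additive
   kinship, a spectral linear mixed model (P3D), Bonferroni and
   effective-number-of-tests (Li & Ji) thresholds, and ±150-SNV regions.
6. **Population genetics** — sliding-window Tajima's D (10 kb windows,
   1 kb step) and midpoint-rooted neighbor-joining trees from Hamming
   distances over a region's variants.
7. **Synthetic data** — generators for every input class (recombinant
   genotype mosaics, QTL phenotypes, sorter records, expression with a
   planted mediator, structured wild panels, neutral coalescent
   haplotypes), each a pure function of its seed with ground truth
   attached, so the whole pipeline is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study emulation;
each reads the outputs of the previous one from `results/`:

```sh
python analysis/01_simulate_panels.py
python analysis/03_linkage_mapping.py
```

which prints (250 strains × 1,002 markers, two planted QTL of opposite
effect at 20% and 12% of phenotypic variance):

```
5% genome-wide threshold (1000 permutations): LOD 2.89
detected 3 QTL (planted: ['III_2981928', 'V_4518072']):
  III_2981928 (chr III): LOD 14.7, CI 2,891,567-3,072,289 bp, 24.1% variance, CB4856 allele higher
  V_4518072 (chr V): LOD 8.9, CI 4,427,711-4,698,795 bp, 15.3% variance, N2 allele higher
  I_13825301 (chr I): LOD 4.2, CI 13,373,494-14,277,108 bp, 7.5% variance, CB4856 allele higher
joint additive model explains 33.5% of the strain variance
2/2 planted QTL covered by a confidence interval
```

Both planted QTL are recovered at the right markers with opposite
allelic directions (the signature that produces transgressive
recombinant phenotypes); the third, small chromosome-I peak is a
false positive of the kind the 5% genome-wide error rate permits.
`analysis/05_mediation.py` then recovers the planted expression
mediator as the top-ranked of 17 probes, and `analysis/06_gwas.py` maps
the wild-panel trait while estimating how much variance the causal
haplotype class explains.

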