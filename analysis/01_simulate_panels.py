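"""Generate every synthetic panel the downstream analyses consume.

Writes, under results/data/: a 250-strain recombinant-inbred cross
(~1,000 markers on 6 chromosomes) with a two-QTL zinc-response
phenotype, per-animal sorter records for a 12-strain dose-response
design, a 17-probe expression table with a planted mediator, an
81-strain structured wild panel with a causal haplotype class, and
neutral coalescent haplotypes for the Tajima's D calibration.  All
ground truth goes to truth.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from zincmap import io as zio
from zincmap.synthetic import (
    CrossSpec, MediationSpec, PhenotypeSpec, SorterSpec, WildPanelSpec,
    simulate_cross, simulate_expression, simulate_neutral_haplotypes,
    simulate_phenotypes, simulate_sorter_records, simulate_wild_panel,
)

SEED = 20_260_924
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

truth_all = {}

# --- recombinant-inbred cross with two opposite-effect QTL ----------------
cross = simulate_cross(CrossSpec(), seed=SEED)
zio.write_cross(cross, OUT / "cross_geno.csv", OUT / "cross_map.csv")
# chr III-like QTL (resistance from the alt allele) and a chr V-like QTL of
# opposite sign, echoing the transgressive architecture of the mapped trait
qtl = [(int(2.2 * 167), 0.20, +1), (int(4.3 * 167), 0.12, -1)]
pheno, truth = simulate_phenotypes(cross, PhenotypeSpec(qtl=qtl), seed=SEED + 1)
pd.DataFrame({"strain": cross.strains, "median.EXT": pheno}).to_csv(
    OUT / "riail_phenotype.csv", index=False)
truth_all["riail"] = truth
print(f"cross: {cross.n_strains} strains x {cross.n_markers} markers; "
      f"planted QTL at {[t['marker'] for t in truth['qtl']]}")

# --- sorter records: 48 strains, 3 assays, zinc + control ------------------
# enough strains that the IQR-fence 5%-of-strains exemption can operate
rng = np.random.default_rng(SEED + 2)
strains = [f"WI{i:02d}" for i in range(48)]
drug_eff = {s: float(np.exp(rng.normal(0, 0.15))) for s in strains}
sorter_spec = SorterSpec(outlier_wells=2)
drug_records, drug_truth = simulate_sorter_records(
    drug_eff, sorter_spec, seed=SEED + 3, condition="zinc-500uM")
ctrl_records, _ = simulate_sorter_records(
    {s: 1.0 for s in strains}, SorterSpec(), seed=SEED + 4, condition="control")
pd.concat([drug_records, ctrl_records]).to_csv(OUT / "sorter_records.csv", index=False)
truth_all["sorter"] = {"drug_effects": drug_eff,
                       "outlier_wells": [list(w) for w in drug_truth["outlier_wells"]]}
print(f"sorter: {len(drug_records) + len(ctrl_records)} animal records, "
      f"{sorter_spec.outlier_wells} outlier wells injected")

# --- expression with a planted mediator at the first QTL -------------------
probes, med_pheno, med_truth = simulate_expression(
    cross, qtl[0][0], MediationSpec(n_probes=17), seed=SEED + 5)
probes.to_csv(OUT / "expression.csv")
pd.DataFrame({"strain": cross.strains, "median.EXT": med_pheno}).to_csv(
    OUT / "mediation_phenotype.csv", index=False)
truth_all["mediation"] = med_truth
print(f"expression: {len(probes)} probes, planted ACME = {med_truth['acme']}")

# --- structured wild panel --------------------------------------------------
vm, wild_pheno, wild_truth = simulate_wild_panel(WildPanelSpec(), seed=SEED + 6)
pd.DataFrame(vm.dosage, index=vm.strains,
             columns=[f"{c}:{p}" for c, p in zip(vm.variants["chrom"], vm.variants["pos"])]
             ).to_csv(OUT / "wild_dosage.csv", index_label="strain")
vm.variants.to_csv(OUT / "wild_variants.csv", index=False)
pd.DataFrame({"strain": vm.strains, "median.norm.EXT": wild_pheno,
              "sqst5_class": wild_truth["classes"]}).to_csv(
    OUT / "wild_phenotype.csv", index=False)
truth_all["wild"] = {k: wild_truth[k] for k in ("causal_frac", "polygenic_frac")}
print(f"wild panel: {vm.n_strains} isolates x {vm.n_variants} variants, "
      f"causal class fraction {wild_truth['causal_frac']}")

# --- neutral haplotypes for the Tajima calibration --------------------------
H, pos = simulate_neutral_haplotypes(n=20, theta=60.0, seed=SEED + 7,
                                     region_length=600_000, rho=60.0)
np.savetxt(OUT / "neutral_haplotypes.csv", H, fmt="%d", delimiter=",")
np.savetxt(OUT / "neutral_positions.csv", pos, delimiter=",")
print(f"neutral haplotypes: 20 samples, {H.shape[1]} segregating sites")

with open(OUT / "truth.json", "w") as fh:
    json.dump(truth_all, fh, indent=2)
print("wrote results/data/")
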