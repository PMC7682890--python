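"""Sorter records through the trait-processing stages, then heritability
and pairwise strain comparisons.

Reads results/data/sorter_records.csv, runs: well summarization ->
assay regression -> outlier pruning (IQR-fence rule) -> control
regression -> unit normalization, then estimates broad-sense
heritability of the zinc response and Tukey HSD contrasts between
strains.  Writes the staged trait tables and summary CSVs under
results/phenotypes/.
"""

import json
from pathlib import Path

import pandas as pd

from zincmap import io as zio
from zincmap import sorter, strain_stats

DATA = Path("results/data")
OUT = Path("results/phenotypes")
OUT.mkdir(parents=True, exist_ok=True)

records = zio.read_records(DATA / "sorter_records.csv")
truth = json.loads((DATA / "truth.json").read_text())

wells = sorter.summarize_wells(records, parents_sorted=3)
wells.to_csv(OUT / "wells_raw.csv", index=False)

staged = {}
for condition in ("zinc-500uM", "control"):
    sub = wells[wells["condition"] == condition].copy()
    sub.attrs["stage"] = "raw"
    sub = sorter.regress_assay(sub)
    sub = sorter.prune_wells(sub, method="bamf")
    staged[condition] = sub
    sub.to_csv(OUT / f"wells_pruned_{condition}.csv", index=False)

n_removed = (wells["condition"] == "zinc-500uM").sum() - len(staged["zinc-500uM"])
truth_outliers = {tuple(w)[3] for w in truth["sorter"]["outlier_wells"]}
removed_wells = set(wells.loc[wells["condition"] == "zinc-500uM", "well"]) - set(
    staged["zinc-500uM"]["well"])
print(f"pruning removed {n_removed} zinc wells; "
      f"{len(removed_wells & truth_outliers)}/{len(truth_outliers)} were the injected outliers")

response = sorter.regress_control(staged["zinc-500uM"], staged["control"])
response.to_csv(OUT / "zinc_response.csv", index=False)
normalized = sorter.normalize_table(response)
normalized.to_csv(OUT / "zinc_response_unit.csv", index=False)

h2 = strain_stats.estimate_heritability(
    response["median.TOF"].to_numpy(), response["strain"].to_numpy(),
    n_boot=1000, seed=17, trait="median.TOF")
print(f"broad-sense heritability of the zinc response (median.TOF): "
      f"H2 = {h2.h2:.2f} [{h2.ci_low:.2f}, {h2.ci_high:.2f}] "
      f"({h2.n_strains} strains, {h2.n_wells} wells)")
pd.DataFrame([vars(h2)]).to_csv(OUT / "heritability.csv", index=False)

pairs = strain_stats.tukey_pairwise(
    response["median.TOF"].to_numpy(), response["strain"].to_numpy())
pairs.to_csv(OUT / "tukey_pairwise.csv", index=False)
n_sig = (pairs["p_adj"] < 0.05).sum()
print(f"Tukey HSD: {n_sig}/{len(pairs)} strain pairs differ at p < 0.05")
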