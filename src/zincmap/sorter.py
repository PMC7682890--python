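"""Per-well trait processing for large-particle sorter records.

A sorter run yields one record per animal: strain, assay, plate, well,
condition, time-of-flight (TOF, a length proxy) and extinction (EXT, an
optical-density proxy).  These are collapsed into four per-well traits —
median.TOF, median.EXT, median.norm.EXT (the median of per-animal
EXT/TOF) and norm.n (animals per parent sorted, a brood-size proxy) —
which then pass through a fixed sequence of processing stages:

    raw -> assay_regressed -> pruned -> control_regressed -> unit_normalized

Assay regression removes batch offsets; pruning drops outlier wells
(either a 2-SD rule within strain or IQR fences across strains with a 5%
strain exemption); control regression replaces the drug-condition trait
by its residual on the strain's mean control value, which is the
drug-response phenotype used by all mapping stages; unit normalization
rescales to [0, 1] for display.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRAITS = ["median.TOF", "median.EXT", "median.norm.EXT", "norm.n"]
KEYS = ["strain", "assay", "plate", "well", "condition"]
STAGES = ["raw", "assay_regressed", "pruned", "control_regressed", "unit_normalized"]


def _check_stage(table: pd.DataFrame, expected: str) -> None:
    stage = table.attrs.get("stage")
    if stage != expected:
        raise ValueError(f"expected a table at stage {expected!r}, got {stage!r}")


def _with_stage(table: pd.DataFrame, stage: str) -> pd.DataFrame:
    table.attrs["stage"] = stage
    table["stage"] = stage
    return table


def summarize_wells(records: pd.DataFrame, parents_sorted) -> pd.DataFrame:
    """Collapse per-animal records into per-well trait summaries.

    ``parents_sorted`` is either a scalar (same for every well) or a
    DataFrame keyed by the well columns with a ``parents_sorted`` column;
    wells present there but absent from ``records`` yield empty-well rows
    with ``n_animals = 0`` and missing trait values.  Records with
    non-positive TOF are rejected with a warning.
    """
    rec = records.copy()
    bad = rec["tof"] <= 0
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} records with non-positive TOF")
        rec = rec[~bad]
    rec["norm_ext"] = rec["ext"] / rec["tof"]

    grouped = rec.groupby(KEYS, sort=False, as_index=False).agg(
        n_animals=("tof", "size"),
        **{"median.TOF": ("tof", "median"),
           "median.EXT": ("ext", "median"),
           "median.norm.EXT": ("norm_ext", "median")},
    )

    if np.isscalar(parents_sorted):
        if parents_sorted <= 0:
            raise ValueError("parents_sorted must be positive")
        grouped["parents_sorted"] = parents_sorted
    else:
        ps = parents_sorted.copy()
        if (ps["parents_sorted"] <= 0).any():
            raise ValueError("parents_sorted must be positive for every well")
        grouped = ps.merge(grouped, on=KEYS, how="outer")
        empty = grouped["n_animals"].isna()
        if empty.any():
            log.info("%d wells with no surviving records", int(empty.sum()))
        grouped["n_animals"] = grouped["n_animals"].fillna(0).astype(int)
    grouped["norm.n"] = grouped["n_animals"] / grouped["parents_sorted"]
    return _with_stage(grouped, "raw")


def regress_assay(table: pd.DataFrame) -> pd.DataFrame:
    """Replace each trait by its residual on the assay factor.

    A fixed-effect model of trait on assay label is equivalent to
    centering within each assay level; an assay with a single well gets a
    zero residual (logged).
    """
    _check_stage(table, "raw")
    out = table.copy()
    for trait in TRAITS:
        if trait not in out:
            continue
        means = out.groupby("assay")[trait].transform("mean")
        out[trait] = out[trait] - means
    singletons = out.groupby("assay").size()
    if (singletons == 1).any():
        log.info("assay levels with a single well: %s",
                 list(singletons.index[singletons == 1]))
    return _with_stage(out, "assay_regressed")


def prune_wells(table: pd.DataFrame, method: str = "bamf",
                min_group: int = 3, strain_frac: float = 0.05) -> pd.DataFrame:
    """Remove outlier wells; rows only, values are never altered.

    ``sd``: within each (condition, strain) group, per trait, drop wells
    more than two standard deviations from the group mean.  ``bamf``:
    within each condition across strains, per trait, fences are
    [Q1 - 2*IQR, Q3 + 2*IQR] (type-7 quantiles); wells outside are dropped
    only if fewer than ``strain_frac`` of distinct strains have any well
    outside.  Bounds are computed once from the full group (single pass).
    Groups with fewer than ``min_group`` wells are left untouched.  A row
    flagged for any trait is removed.
    """
    _check_stage(table, "assay_regressed")
    out = table.copy()
    drop = pd.Series(False, index=out.index)
    if method == "sd":
        for (cond, strain), sub in out.groupby(["condition", "strain"], sort=False):
            if len(sub) < min_group:
                log.info("sd prune: group (%s, %s) has < %d wells; skipped",
                         cond, strain, min_group)
                continue
            for trait in TRAITS:
                if trait not in sub:
                    continue
                v = sub[trait]
                mu, sd = v.mean(), v.std(ddof=1)
                if sd == 0 or np.isnan(sd):
                    continue
                flagged = sub.index[(v - mu).abs() > 2 * sd]
                drop.loc[flagged] = True
    elif method == "bamf":
        for cond, sub in out.groupby("condition", sort=False):
            if len(sub) < min_group:
                log.info("bamf prune: condition %s has < %d wells; skipped",
                         cond, min_group)
                continue
            for trait in TRAITS:
                if trait not in sub:
                    continue
                v = sub[trait].to_numpy(dtype=float)
                q1, q3 = np.nanquantile(v, [0.25, 0.75])  # type-7 / linear
                iqr = q3 - q1
                outside = (v < q1 - 2 * iqr) | (v > q3 + 2 * iqr)
                outlier_strains = sub.loc[sub.index[outside], "strain"].nunique()
                frac = outlier_strains / sub["strain"].nunique()
                if frac >= strain_frac:
                    log.info("bamf prune: %s/%s exempted (%.1f%% of strains outside)",
                             cond, trait, 100 * frac)
                    continue
                drop.loc[sub.index[outside]] = True
    else:
        raise ValueError(f"unknown pruning method {method!r}")
    if drop.any():
        log.info("pruned %d wells (%s)", int(drop.sum()), method)
    return _with_stage(out[~drop].copy(), "pruned")


def regress_control(drug_table: pd.DataFrame, control_table: pd.DataFrame) -> pd.DataFrame:
    """Drug-response phenotype: residual of the drug value on the strain's
    mean control value, fit jointly across strains (one slope and
    intercept per trait).  Strains absent from the control table are
    dropped with a warning."""
    _check_stage(drug_table, "pruned")
    _check_stage(control_table, "pruned")
    ctrl_means = control_table.groupby("strain")[TRAITS].mean()
    out = drug_table.copy()
    missing = ~out["strain"].isin(ctrl_means.index)
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} drug wells from strains missing in control: "
            f"{sorted(out.loc[missing, 'strain'].unique())}"
        )
        out = out[~missing].copy()
    for trait in TRAITS:
        if trait not in out:
            continue
        x = out["strain"].map(ctrl_means[trait]).to_numpy(dtype=float)
        y = out[trait].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        X = np.column_stack([np.ones(ok.sum()), x[ok]])
        if np.std(x[ok]) == 0:
            resid = y - np.nanmean(y[ok])
        else:
            beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
            resid = y - (beta[0] + beta[1] * x)
        out[trait] = resid
    return _with_stage(out, "control_regressed")


def normalize_unit(values: np.ndarray) -> np.ndarray:
    """Affine rescale sending the smallest value to 0 and the largest to 1."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ValueError("constant vector: unit normalization undefined")
    return (v - lo) / (hi - lo)


def normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply unit normalization to every trait column (display stage)."""
    _check_stage(table, "control_regressed")
    out = table.copy()
    for trait in TRAITS:
        if trait in out:
            out[trait] = normalize_unit(out[trait].to_numpy())
    return _with_stage(out, "unit_normalized")


def select_dose(table: pd.DataFrame, dose_col: str = "dose",
                traits: list[str] | None = None):
    """Pick the dose maximizing between- over within-strain variance.

    At each candidate dose a one-way decomposition per trait gives the
    between-strain mean square over the within-strain mean square; the
    chosen dose maximizes the mean of this ratio across traits.  A dose
    with zero within-strain variance in every trait scores +inf (warned).
    """
    traits = traits or [t for t in TRAITS if t in table]
    doses = table[dose_col].unique()
    if len(doses) == 1:
        return doses[0]
    scores = {}
    for dose in doses:
        sub = table[table[dose_col] == dose]
        ratios = []
        for trait in traits:
            groups = [g.to_numpy(dtype=float) for _, g in sub.groupby("strain")[trait]]
            groups = [g[~np.isnan(g)] for g in groups]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                continue
            n_tot = sum(len(g) for g in groups)
            grand = np.concatenate(groups).mean()
            msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            dfw = n_tot - len(groups)
            msw = ssw / dfw if dfw > 0 else np.nan
            if msw == 0 or np.isnan(msw):
                ratios.append(np.inf)
            else:
                ratios.append(msb / msw)
        if ratios and np.isinf(ratios).all():
            warnings.warn(f"dose {dose}: zero within-strain variance in every trait")
        scores[dose] = np.mean(ratios) if ratios else -np.inf
    return max(scores, key=lambda d: scores[d])
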