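"""Readers and writers for the pipeline's file formats.

Delimited text throughout: per-animal sorter records and trait tables as
CSV/TSV, genotypes as a strains x markers CSV plus a marker map, wild
panels as VCF.  Coordinates are 1-based inclusive internally; exported
interval files are BED (0-based half-open).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import VariantMatrix
from .linkage import CrossGenotypes

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["strain", "assay", "plate", "well", "condition", "tof", "ext"]


def read_records(path, config=None, sep: str = ",") -> pd.DataFrame:
    """Read per-animal sorter records.

    ``config`` maps canonical column names to the file's column names,
    either as a dict or a path to a YAML file with a ``columns`` mapping.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh).get("columns", {})
    df = pd.read_csv(path, sep=sep)
    if config:
        df = df.rename(columns={v: k for k, v in config.items()})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing columns: {missing}")
    return df[RECORD_COLUMNS]


def write_cross(cross: CrossGenotypes, geno_path, map_path) -> None:
    geno = pd.DataFrame(cross.geno, index=cross.strains,
                        columns=cross.markers["marker"])
    geno.to_csv(geno_path, index_label="strain")
    cross.markers.to_csv(map_path, index=False)


def read_cross(geno_path, map_path) -> CrossGenotypes:
    geno = pd.read_csv(geno_path, index_col="strain")
    markers = pd.read_csv(map_path)
    if list(geno.columns) != list(markers["marker"]):
        geno = geno[markers["marker"]]
    return CrossGenotypes(
        strains=geno.index.to_numpy(),
        markers=markers,
        geno=geno.to_numpy(dtype=float),
    )


def read_vcf(path) -> VariantMatrix:
    """Biallelic SNVs from a VCF into homozygous dosages (0 ref / 1 alt).

    Multiallelic and indel records are skipped (count logged); het calls
    in these inbred isolates are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    strains = np.array(vcf.samples)
    rows, cols, skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        gt = rec.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        dos = np.where(gt == 0, 0.0, np.where(gt == 2, 1.0, np.nan))
        rows.append({"chrom": rec.CHROM, "pos": rec.POS,
                     "ref": rec.REF, "alt": rec.ALT[0]})
        cols.append(dos)
    if skipped:
        log.info("read_vcf: skipped %d multiallelic/indel records", skipped)
    if not rows:
        raise ValueError("no biallelic SNVs in VCF")
    return VariantMatrix(
        strains=strains,
        variants=pd.DataFrame(rows),
        dosage=np.column_stack(cols),
    )


def write_regions_bed(regions, path) -> None:
    """Write (chrom, start, end) 1-based inclusive regions as BED
    (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
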