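import numpy as np
import pandas as pd
import pytest

from zincmap.linkage import CrossGenotypes
from zincmap.synthetic import CrossSpec, simulate_cross


@pytest.fixture
def small_cross() -> CrossGenotypes:
    """100 strains x 120 markers on 4 chromosomes."""
    return simulate_cross(CrossSpec(n_strains=100, n_chrom=4, markers_per_chrom=30), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_trait_table(values, strains=None, condition="zinc", assay="assay1", stage="assay_regressed"):
    """Single-trait table (all four trait columns set to the same values)
    at an arbitrary pipeline stage, for exercising pruning rules."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    strains = strains if strains is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame({
        "strain": strains,
        "assay": assay,
        "plate": "p1",
        "well": [f"w{i}" for i in range(n)],
        "condition": condition,
        "median.TOF": values,
        "median.EXT": values,
        "median.norm.EXT": values,
        "norm.n": values,
    })
    df.attrs["stage"] = stage
    df["stage"] = stage
    return df
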