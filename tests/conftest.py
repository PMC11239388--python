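import numpy as np
import pandas as pd
import pytest

from mrkit.harmonize import HarmonizedSet
from mrkit.sumstats_io import CANONICAL_COLUMNS, SumstatsTable

_DEFAULTS = {
    "chrom": "1",
    "pos": 1000,
    "effect_allele": "A",
    "other_allele": "G",
    "eaf": 0.3,
    "beta": 0.1,
    "se": 0.01,
    "pval": 1e-8,
    "n": 100_000,
}


def make_table(rows, trait_label="trait", trait_type="binary") -> SumstatsTable:
    """Build a SumstatsTable from partial row dicts, filling sane defaults."""
    full = []
    for i, row in enumerate(rows):
        r = dict(_DEFAULTS, snp_id=f"rs{i + 1}", **row)
        full.append(r)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    df["snp_id"] = df["snp_id"].astype("string")
    df["chrom"] = df["chrom"].astype("string")
    df["effect_allele"] = df["effect_allele"].astype("string")
    df["other_allele"] = df["other_allele"].astype("string")
    df["pos"] = df["pos"].astype("Int64")
    df["n"] = df["n"].astype("Int64")
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = df[col].astype(float)
    return SumstatsTable(df, trait_label=trait_label, trait_type=trait_type)


def random_harmonized(rng, n_snp, ratio=0.5, noise=0.0) -> HarmonizedSet:
    """A harmonized set whose Wald ratios scatter around ``ratio``."""
    bx = rng.uniform(0.03, 0.2, n_snp) * rng.choice([-1, 1], n_snp)
    sx = rng.uniform(0.002, 0.01, n_snp)
    sy = rng.uniform(0.005, 0.05, n_snp)
    by = ratio * bx + rng.normal(0, noise, n_snp) + rng.normal(0, sy)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
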