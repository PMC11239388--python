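"""Reading, validating, and writing GWAS summary-statistics tables.

The canonical dialect is a tab-delimited UTF-8 file with one header line and
the columns ``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
pval, n``. Missing optional values are written as empty fields and read back
as missing; ``.`` is also accepted on input. Foreign dialects are handled via
a column map from canonical names to the file's own header names.

Per-record validity rules (rows violating them are dropped, with a reason):

* ``se > 0``
* ``pval`` in (0, 1]
* ``effect_allele != other_allele`` and both are non-empty A/C/G/T strings
* ``eaf``, when present, in (0, 1)
* ``snp_id`` unique within the table

Positions are 1-based and treated as opaque coordinates: they are never
compared across tables except within clumping windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

_ALLELE_CHARS = frozenset("ACGT")


def _valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) > 0 and set(a) <= _ALLELE_CHARS


@dataclass
class SumstatsTable:
    """One GWAS trait's per-variant association records.

    ``data`` is a DataFrame with the canonical columns; every row satisfies
    the record invariants. ``dropped`` records the (snp_id, reason) pairs
    removed during validation.
    """

    data: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "binary"
    provenance: str = ""
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> pd.Series:
        return self.data["snp_id"]

    def subset(self, snp_ids) -> "SumstatsTable":
        """Restrict to the given identifiers, preserving the given order."""
        idx = self.data.set_index("snp_id").loc[list(snp_ids)]
        return SumstatsTable(
            idx.reset_index()[CANONICAL_COLUMNS],
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            provenance=self.provenance,
        )


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop rows violating the record invariants; return (clean, dropped).

    The retained-row count plus the dropped-row count always equals the input
    row count.
    """
    dropped: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)

    def flag(mask: np.ndarray, reason: str) -> None:
        for sid in df.loc[mask & keep, "snp_id"].astype(str):
            dropped.append((sid, reason))
        keep[np.asarray(mask)] = False

    sid_missing = df["snp_id"].isna() | (df["snp_id"].astype(str).str.len() == 0)
    flag(sid_missing.to_numpy(), "missing snp_id")
    flag(df["beta"].isna().to_numpy(), "missing beta")
    flag((df["se"].isna() | (df["se"] <= 0)).to_numpy(), "nonpositive SE")
    flag(
        (df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1)).to_numpy(),
        "p-value outside (0,1]",
    )
    ok_ea = df["effect_allele"].map(_valid_allele).astype(bool)
    ok_oa = df["other_allele"].map(_valid_allele).astype(bool)
    flag((~ok_ea | ~ok_oa).to_numpy(), "invalid allele")
    same = (df["effect_allele"] == df["other_allele"]).fillna(False).astype(bool)
    flag(same.to_numpy(), "identical alleles")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    flag(eaf_bad.to_numpy(), "allele frequency outside (0,1)")
    dup = df["snp_id"].duplicated(keep="first").to_numpy()
    flag(dup, "duplicate snp_id")

    return df.loc[keep].reset_index(drop=True), dropped


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "binary",
    trait_label: str = "",
    sep: str = "\t",
) -> SumstatsTable:
    """Read a summary-statistics file into a validated :class:`SumstatsTable`.

    Parameters
    ----------
    path
        Delimited text file with one header line.
    column_map
        Mapping from canonical column names to the file's column names, e.g.
        ``{"snp_id": "rsid", "beta": "b"}``. Unmapped canonical names are
        looked up verbatim.
    trait_type
        ``"binary"`` (betas are log odds ratios) or ``"continuous"``.

    Rows failing the record invariants are dropped, counted, and logged; the
    drop tally is available as ``table.dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"summary-statistics file is empty: {path}")

    raw = pd.read_csv(path, sep=sep, na_values=["", "."], dtype={"chrom": str})
    rename = {}
    column_map = column_map or {}
    for canon in CANONICAL_COLUMNS:
        source = column_map.get(canon, canon)
        if source in raw.columns:
            rename[source] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"mandatory column {canon!r} (mapped from {source!r}) missing from {path}"
            )
    df = raw.rename(columns=rename)
    for canon in CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = pd.NA
    df = df[CANONICAL_COLUMNS].copy()

    df["snp_id"] = df["snp_id"].astype("string")
    df["chrom"] = df["chrom"].astype("string")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype("string").str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")

    clean, dropped = validate_records(df)
    if dropped:
        logger.warning(
            "%s: dropped %d of %d rows during validation", path, len(dropped), len(df)
        )
        for sid, reason in dropped:
            logger.info("dropped %s: %s", sid, reason)
    return SumstatsTable(
        clean,
        trait_label=trait_label or path.stem,
        trait_type=trait_type,
        provenance=str(path),
        dropped=dropped,
    )


def write_sumstats(table: SumstatsTable, path: str | Path) -> Path:
    """Write a table in the canonical tab-delimited dialect.

    Missing optional values (eaf, n, chrom, pos) become empty fields. Reading
    the file back reproduces the table field-for-field.
    """
    path = Path(path)
    df = table.data.reindex(columns=CANONICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path
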