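"""Instrument selection: p-value threshold, greedy LD clumping, F statistics,
and confounder-trait exclusion.

Selection proceeds in three stages, each recording its exclusions:

1. keep variants with ``pval < p_threshold``;
2. greedy LD clumping — repeatedly keep the most significant remaining
   variant (ties broken lexicographically on snp_id) and discard every
   unkept variant on the same chromosome within the window whose squared
   correlation with it meets the threshold;
3. drop variants whose F statistic ``beta**2 / se**2`` falls below ``f_min``
   (F > 10 is the conventional weak-instrument floor).

LD is supplied explicitly as an :class:`LdInfo`; variant pairs absent from it
are treated as unlinked (r² = 0), which makes the procedure reproducible and
reference-panel-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NoInstrumentsError
from .sumstats_io import SumstatsTable

__all__ = [
    "LdInfo",
    "InstrumentSet",
    "ConfounderAnnotation",
    "f_statistic",
    "clump",
    "select_instruments",
    "filter_confounders",
]


class LdInfo:
    """Pairwise squared-correlation (r²) matrix over a set of variants.

    The matrix must be symmetric (within 1e-9), have a unit diagonal, and
    values in [0, 1]. Variants not covered are unlinked by convention.
    """

    def __init__(self, snp_ids, r2: np.ndarray) -> None:
        snp_ids = list(snp_ids)
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(snp_ids), len(snp_ids)):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if len(set(snp_ids)) != len(snp_ids):
            raise ValueError("duplicate snp_ids in LdInfo")
        if not np.allclose(r2, r2.T, atol=1e-9):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-9):
            raise ValueError("r2 matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self.snp_ids = snp_ids
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {sid: i for i, sid in enumerate(snp_ids)}

    @classmethod
    def from_pairs(cls, snp_ids, pairs) -> "LdInfo":
        """Build from an iterable of (id_a, id_b, r2) triples; missing pairs are 0."""
        snp_ids = list(snp_ids)
        index = {sid: i for i, sid in enumerate(snp_ids)}
        m = np.eye(len(snp_ids))
        for a, b, r in pairs:
            if a in index and b in index and a != b:
                m[index[a], index[b]] = r
                m[index[b], index[a]] = r
        return cls(snp_ids, m)

    @classmethod
    def identity(cls, snp_ids) -> "LdInfo":
        snp_ids = list(snp_ids)
        return cls(snp_ids, np.eye(len(snp_ids)))

    def r2_between(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


@dataclass
class ConfounderAnnotation:
    """Local (snp_id, trait_label) lookup table standing in for a web query
    against a trait-association catalog."""

    data: pd.DataFrame  # columns: snp_id, trait_label

    def __post_init__(self) -> None:
        self.data = (
            self.data[["snp_id", "trait_label"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records) -> "ConfounderAnnotation":
        return cls(pd.DataFrame(records, columns=["snp_id", "trait_label"]))

    @classmethod
    def from_tsv(cls, path) -> "ConfounderAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def traits_for(self, snp_id: str) -> list[str]:
        return self.data.loc[self.data["snp_id"] == snp_id, "trait_label"].tolist()


@dataclass
class InstrumentSet:
    """Selected instruments with their F statistics, the thresholds applied,
    and a full exclusion trail (snp_id, reason)."""

    table: SumstatsTable
    f_stats: pd.Series
    p_threshold: float
    r2_threshold: float
    window_kb: float
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return self.table.data["snp_id"].tolist()

    @property
    def n_instruments(self) -> int:
        return len(self.table.data)


def f_statistic(beta, se):
    """Per-variant instrument-strength F statistic, ``beta**2 / se**2``.

    Accepts scalars or arrays; requires strictly positive standard errors.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("f_statistic requires se > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def clump(
    table: SumstatsTable,
    ld: LdInfo | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy LD clumping; returns retained snp_ids in selection order.

    Candidates are ranked by ascending p-value with lexicographic snp_id
    tie-break. Each retained index variant removes every remaining candidate
    on the same chromosome within ``window_kb`` (center-to-center) whose r²
    with it is at or above ``r2_threshold``. Pairs with a missing chromosome
    or position never fall in a window; pairs absent from ``ld`` have r² = 0.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")

    df = table.data
    order = df.sort_values(["pval", "snp_id"], kind="mergesort")
    candidates = list(
        order[["snp_id", "chrom", "pos"]].itertuples(index=False, name=None)
    )
    retained: list[str] = []
    removed: set[str] = set()
    window_bp = window_kb * 1000.0
    for i, (sid, chrom, pos) in enumerate(candidates):
        if sid in removed:
            continue
        retained.append(sid)
        if ld is None:
            continue
        for osid, ochrom, opos in candidates[i + 1:]:
            if osid in removed:
                continue
            if pd.isna(chrom) or pd.isna(ochrom) or chrom != ochrom:
                continue
            if pd.isna(pos) or pd.isna(opos) or abs(float(pos) - float(opos)) > window_bp:
                continue
            if ld.r2_between(sid, osid) >= r2_threshold:
                removed.add(osid)
    return retained


def select_instruments(
    table: SumstatsTable,
    p_threshold: float = 5e-6,
    ld: LdInfo | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    f_min: float = 10.0,
) -> InstrumentSet:
    """Three-stage instrument selection: p filter, LD clump, F filter.

    Raises :class:`NoInstrumentsError` if no variant passes the p-value
    threshold, or if the later stages leave the set empty.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    if table.n_snps == 0:
        raise NoInstrumentsError("exposure table is empty")

    exclusions: list[tuple[str, str]] = []
    df = table.data
    passed = df[df["pval"] < p_threshold]
    for sid in df.loc[df["pval"] >= p_threshold, "snp_id"]:
        exclusions.append((sid, f"pval >= {p_threshold:g}"))
    if passed.empty:
        raise NoInstrumentsError(
            f"no instruments: no variant has pval < {p_threshold:g}"
        )

    stage = SumstatsTable(
        passed.reset_index(drop=True),
        trait_label=table.trait_label,
        trait_type=table.trait_type,
        provenance=table.provenance,
    )
    kept_ids = clump(stage, ld, r2_threshold=r2_threshold, window_kb=window_kb)
    kept_set = set(kept_ids)
    for sid in passed["snp_id"]:
        if sid not in kept_set:
            exclusions.append((sid, f"ld_clump r2 >= {r2_threshold:g}"))

    clumped = stage.subset(kept_ids)
    f = f_statistic(clumped.data["beta"].to_numpy(), clumped.data["se"].to_numpy())
    f = pd.Series(np.atleast_1d(f), index=clumped.data["snp_id"].tolist(), name="F")
    strong = f[f >= f_min].index.tolist()
    for sid, fv in f[f < f_min].items():
        exclusions.append((sid, f"weak instrument F = {fv:.3g} < {f_min:g}"))
    if not strong:
        raise NoInstrumentsError(
            f"no instruments: all clumped variants have F < {f_min:g}"
        )

    return InstrumentSet(
        table=clumped.subset(strong),
        f_stats=f.loc[strong],
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
        exclusions=exclusions,
    )


def filter_confounders(
    inst: InstrumentSet,
    ann: ConfounderAnnotation,
    traits: list[str],
) -> InstrumentSet:
    """Drop instruments annotated to any of the listed confounder traits.

    Each (snp_id, matching trait) pair adds one exclusion row
    ``confounder:<trait>``; an empty annotation leaves the set unchanged.
    """
    if not traits:
        raise ValueError("traits must be a nonempty list")
    trait_set = set(traits)
    flagged = ann.data[ann.data["trait_label"].isin(trait_set)]
    new_exclusions = list(inst.exclusions)
    drop: set[str] = set()
    current = set(inst.snp_ids)
    for sid, trait in flagged[["snp_id", "trait_label"]].itertuples(index=False):
        if sid in current:
            drop.add(sid)
            new_exclusions.append((sid, f"confounder:{trait}"))
    keep = [sid for sid in inst.snp_ids if sid not in drop]
    return InstrumentSet(
        table=inst.table.subset(keep),
        f_stats=inst.f_stats.loc[keep],
        p_threshold=inst.p_threshold,
        r2_threshold=inst.r2_threshold,
        window_kb=inst.window_kb,
        exclusions=new_exclusions,
    )
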