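"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs each variant's exposure and outcome effects expressed for
the same effect allele. For every variant shared by the two tables:

* same allele pair, same orientation — kept as is;
* same allele pair, swapped orientation — outcome beta negated and its
  frequency complemented (``flipped_outcome``);
* complementary-strand pair (e.g. A/G vs T/C) — outcome alleles strand-flipped
  first, then the two rules above;
* palindromic variant (A/T or C/G) — strand and orientation are
  indistinguishable from the allele labels, so orientation is inferred from
  the effect-allele frequencies; if either frequency is missing or falls in
  the ambiguity band ``0.5 ± palindromic_eaf_tol``, the variant is dropped;
* anything else (indels, irreconcilable pairs) — ``dropped_incompatible``.

The default ambiguity half-window of 0.08 (band 0.42–0.58) is the community
standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NoOverlapError
from .sumstats_io import SumstatsTable

__all__ = ["HarmonizedSet", "harmonize"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "action",
]


def _is_snv(a: str) -> bool:
    return a in _COMPLEMENT


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele convention.

    ``pairs`` holds the retained variants (action ``none`` or
    ``flipped_outcome``); ``dropped`` holds the excluded ones with their
    reason in the ``action`` column.
    """

    pairs: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "action"])
    )
    exposure_label: str = ""
    outcome_label: str = ""

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        **labels,
    ) -> "HarmonizedSet":
        """Convenience constructor for already-aligned effect arrays."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp_{i}" for i in range(len(beta_exp))]
        pairs = pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "eaf_exp": np.nan,
                "eaf_out": np.nan,
                "action": "none",
            }
        )
        return cls(pairs=pairs, **labels)

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        return HarmonizedSet(
            pairs=self.pairs[self.pairs["snp_id"] != snp_id].reset_index(drop=True),
            dropped=self.dropped,
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )


def _orient_one(row, tol: float):
    """Return (beta_out, eaf_out, action) for one merged variant row."""
    e_ea, e_oa = row.effect_allele_exp, row.other_allele_exp
    o_ea, o_oa = row.effect_allele_out, row.other_allele_out
    beta_out, eaf_out = row.beta_out, row.eaf_out

    if not all(_is_snv(a) for a in (e_ea, e_oa, o_ea, o_oa)):
        return beta_out, eaf_out, "dropped_incompatible"

    if _is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return beta_out, eaf_out, "dropped_incompatible"
        eaf_exp = row.eaf_exp
        if pd.isna(eaf_exp) or pd.isna(eaf_out):
            return beta_out, eaf_out, "dropped_palindromic"
        if abs(eaf_exp - 0.5) <= tol or abs(eaf_out - 0.5) <= tol:
            return beta_out, eaf_out, "dropped_palindromic"
        action = "none"
        if o_ea != e_ea:  # nominal orientation swap
            beta_out, eaf_out, action = -beta_out, 1 - eaf_out, "flipped_outcome"
        if (eaf_exp < 0.5) != (eaf_out < 0.5):  # frequencies disagree: strand flip
            beta_out = -beta_out
            eaf_out = 1 - eaf_out
            action = "none" if action == "flipped_outcome" else "flipped_outcome"
        return beta_out, eaf_out, action

    pair_exp = {e_ea, e_oa}
    if {o_ea, o_oa} == pair_exp:
        pass  # same strand
    elif {_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]} == pair_exp:
        o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]  # strand flip, eaf unchanged
    else:
        return beta_out, eaf_out, "dropped_incompatible"

    if o_ea == e_ea:
        return beta_out, eaf_out, "none"
    return -beta_out, (1 - eaf_out if pd.notna(eaf_out) else eaf_out), "flipped_outcome"


def harmonize(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    palindromic_eaf_tol: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    Raises :class:`NoOverlapError` when the tables share no variant. The
    retained and dropped counts always sum to the intersection size.
    """
    if not (0 <= palindromic_eaf_tol < 0.5):
        raise ValueError("palindromic_eaf_tol must lie in [0, 0.5)")

    merged = exposure.data.merge(
        outcome.data, on="snp_id", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise NoOverlapError(
            f"no overlapping SNPs between {exposure.trait_label!r} "
            f"and {outcome.trait_label!r}"
        )

    rows = []
    dropped = []
    for row in merged.itertuples(index=False):
        beta_out, eaf_out, action = _orient_one(row, palindromic_eaf_tol)
        if action.startswith("dropped"):
            dropped.append((row.snp_id, action))
            continue
        rows.append(
            (
                row.snp_id, row.beta_exp, row.se_exp, beta_out, row.se_out,
                row.eaf_exp, eaf_out, action,
            )
        )
    return HarmonizedSet(
        pairs=pd.DataFrame(rows, columns=PAIR_COLUMNS),
        dropped=pd.DataFrame(dropped, columns=["snp_id", "action"]),
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
    )
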