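"""Heterogeneity, pleiotropy, and influence diagnostics.

Cochran's Q is computed on the Wald ratios with inverse first-order-variance
weights against the fixed-effect IVW center — algebraically the textbook
form. I² = max(0, (Q − df)/Q) summarizes the excess dispersion as a
fraction. The Egger intercept test re-exposes the intercept triple from the
Egger regression. Leave-one-out refits IVW dropping each variant in turn;
the single-variant display lists every Wald ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .estimators import MrEstimate, ivw, mr_egger, wald_ratio, _columns, _ratios
from .harmonize import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutRow",
    "SingleSnpRow",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "single_snp",
]


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    i2: float

    def to_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pval": self.pval, "i2": self.i2}


@dataclass
class LeaveOneOutRow:
    dropped_snp_id: str
    estimate: MrEstimate


@dataclass
class SingleSnpRow:
    snp_id: str
    estimate: MrEstimate | None
    note: str = ""


def cochran_q(h: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q over Wald ratios; df = n − 1; upper-tail chi-square p."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("cochran_q requires at least 2 variants")
    bx, _, by, sy = _columns(h)
    r, w = _ratios(bx, by, sy)
    center = float(np.sum(w * r) / np.sum(w))  # fixed-effect IVW estimate
    q = float(np.sum(w * (r - center) ** 2))
    df = h.n_snp - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2)


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, two-sided t p) from the Egger regression."""
    res = mr_egger(h)
    return res.intercept, res.intercept_se, res.intercept_pval


def leave_one_out(
    h: HarmonizedSet,
    re_mode: str = "multiplicative_random",
) -> list[LeaveOneOutRow]:
    """IVW re-estimated with each variant removed, in input order."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave_one_out requires at least 3 variants")
    rows = []
    for sid in h.pairs["snp_id"]:
        rows.append(LeaveOneOutRow(sid, ivw(h.drop_snp(sid), re_mode=re_mode)))
    return rows


def single_snp(h: HarmonizedSet) -> list[SingleSnpRow]:
    """Per-variant Wald ratios in input order; zero exposure effects are
    flagged instead of aborting the batch."""
    if h.n_snp < 1:
        raise InsufficientInstrumentsError("single_snp requires at least 1 variant")
    rows = []
    for row in h.pairs.itertuples(index=False):
        if row.beta_exp == 0:
            rows.append(SingleSnpRow(row.snp_id, None, "beta_exp = 0: ratio undefined"))
        else:
            rows.append(
                SingleSnpRow(row.snp_id, wald_ratio(row.beta_exp, row.beta_out, row.se_out))
            )
    return rows
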