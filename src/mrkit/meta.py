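"""Inverse-variance meta-analysis of MR estimates across datasets.

Pooling operates on the log-odds scale; printed confidence intervals are
converted back to standard errors with ``ci_to_se`` so published results can
be pooled directly. The fixed-effect model weights each study by 1/se²; the
random-effects companion uses the DerSimonian–Laird moment estimator of the
between-study variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diagnostics import HeterogeneityResult

__all__ = ["MetaInput", "MetaResult", "ci_to_se", "meta_fixed", "meta_random_dl"]


@dataclass
class MetaInput:
    """One study's estimate on the log-OR scale."""

    label: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.label!r}: se must be positive")

    @classmethod
    def from_or_ci(
        cls, label: str, odds_ratio: float, ci_low: float, ci_high: float,
        level: float = 0.95,
    ) -> "MetaInput":
        """Build from a printed OR with its confidence interval."""
        return cls(label, math.log(odds_ratio), ci_to_se(ci_low, ci_high, level))


@dataclass
class MetaResult:
    model: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    het: HeterogeneityResult
    k: int
    tau2: float = 0.0

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "model": self.model, "k": self.k, "beta": self.beta, "se": self.se,
            "or": self.odds_ratio, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "tau2": self.tau2, "het": self.het.to_dict(),
        }


def ci_to_se(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error of a log odds ratio from its printed OR interval.

    ``se = (ln ci_high − ln ci_low) / (2 z)`` with z the two-sided normal
    quantile for the interval's confidence level.
    """
    if not (0 < ci_low < ci_high):
        raise ValueError("require 0 < ci_low < ci_high")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return float((math.log(ci_high) - math.log(ci_low)) / (2 * z))


def _pool(betas, weights, model, k, tau2, level):
    pooled = float(np.sum(weights * betas) / np.sum(weights))
    se = float(1.0 / np.sqrt(np.sum(weights)))
    z = stats.norm.ppf(0.5 + level / 2)
    pval = float(2 * stats.norm.sf(abs(pooled) / se))
    return pooled, se, pooled - z * se, pooled + z * se, pval


def _across_study_q(betas, weights):
    center = np.sum(weights * betas) / np.sum(weights)
    q = float(np.sum(weights * (betas - center) ** 2))
    df = len(betas) - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2), q, df


def meta_fixed(studies: list[MetaInput], level: float = 0.95) -> MetaResult:
    """Fixed-effect inverse-variance pooling of k ≥ 2 studies."""
    if len(studies) < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    betas = np.array([s.beta for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    het, _, _ = _across_study_q(betas, w)
    pooled, se, lo, hi, pval = _pool(betas, w, "fixed", len(studies), 0.0, level)
    return MetaResult("fixed", pooled, se, lo, hi, pval, het, len(studies))


def meta_random_dl(studies: list[MetaInput], level: float = 0.95) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    ``tau2 = max(0, (Q − df) / (Σw − Σw²/Σw))`` with Q the fixed-effect
    across-study heterogeneity statistic; reduces to the fixed-effect result
    when Q ≤ df.
    """
    if len(studies) < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    betas = np.array([s.beta for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    het, q, df = _across_study_q(betas, w)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_re = np.array([1.0 / (s.se**2 + tau2) for s in studies])
    pooled, se, lo, hi, pval = _pool(betas, w_re, "random_dl", len(studies), tau2, level)
    return MetaResult("random_dl", pooled, se, lo, hi, pval, het, len(studies), tau2=tau2)
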