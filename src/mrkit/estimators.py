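"""Causal-effect estimators for harmonized two-sample MR data.

All estimators consume per-variant exposure effects ``beta_exp`` (with SE
``se_exp``) and outcome effects ``beta_out`` (with SE ``se_out``) and return
the causal effect of exposure on outcome. For binary traits the effects are
log odds ratios throughout; odds ratios appear only at the reporting
boundary via :meth:`MrEstimate.odds_ratio`.

Implemented methods and their conventions:

* **Wald ratio** — per-variant ``beta_out / beta_exp`` with the first-order
  delta-method SE ``se_out / |beta_exp|``.
* **IVW** — weighted least squares of ``beta_out`` on ``beta_exp`` through
  the origin with weights ``1/se_out**2``. The default variance model is
  multiplicative random effects: the fixed-effect SE is inflated by the
  weighted residual standard deviation, floored at 1 so overdispersion
  widens but underdispersion never narrows the interval. p-values are
  normal.
* **MR-Egger** — the same regression with a free intercept, variants first
  oriented so every ``beta_exp`` is non-negative. The intercept estimates
  directional pleiotropy. SEs carry the same multiplicative inflation
  (floored at 1); p-values use the t distribution with n − 2 df.
* **Weighted median** — the 50% point of the inverse-variance-weighted
  empirical quantile function of the Wald ratios, linearly interpolated
  between order statistics; SE by seeded parametric bootstrap.
* **Mode-based (simple / weighted)** — the mode of a normal-kernel density
  over the Wald ratios, bandwidth ``phi`` times a modified Silverman scale
  ``0.9 * min(sd, mad) * n**(-1/5)``; SE by the same bootstrap.

Weights for the ratio-based methods are the inverse first-order ratio
variance ``beta_exp**2 / se_out**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedSet

__all__ = [
    "MrEstimate",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_based",
]


@dataclass
class MrEstimate:
    """A causal-effect estimate on the log-odds (or outcome-unit) scale.

    ``se`` may be exactly zero for degenerate zero-residual inputs; the
    p-value is then defined by limit (1 for a zero estimate, 0 otherwise).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    level: float = 0.95

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "or": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "pval": self.pval,
            "level": self.level,
        }


@dataclass
class EggerResult:
    """MR-Egger slope (the causal estimate) plus the intercept triple."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2 * stats.norm.sf(abs(beta) / se))


def _t_p(beta: float, se: float, df: int) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2 * stats.t.sf(abs(beta) / se, df))


def _ci(beta: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    return beta - z * se, beta + z * se


def _estimate(method, beta, se, pval, n_snp, level) -> MrEstimate:
    lo, hi = _ci(beta, se, level)
    return MrEstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(lo), ci_high=float(hi), pval=float(pval),
        n_snp=int(n_snp), level=level,
    )


def _columns(h: HarmonizedSet):
    p = h.pairs
    return (
        p["beta_exp"].to_numpy(float),
        p["se_exp"].to_numpy(float),
        p["beta_out"].to_numpy(float),
        p["se_out"].to_numpy(float),
    )


def _ratios(beta_exp, beta_out, se_out):
    """Wald ratios and their inverse first-order-variance weights."""
    r = beta_out / beta_exp
    w = beta_exp**2 / se_out**2
    return r, w


def wald_ratio(
    beta_exp: float,
    beta_out: float,
    se_out: float,
    level: float = 0.95,
) -> MrEstimate:
    """Single-variant ratio estimate ``beta_out / beta_exp``."""
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _estimate("wald_ratio", beta, se, _normal_p(beta, se), 1, level)


def _ivw_fit(beta_exp, beta_out, se_out):
    """Origin-constrained WLS; returns (beta, fixed se, residual scale)."""
    w = 1.0 / se_out**2
    if len(beta_exp) == 1:  # degenerate single-variant fit: exact, no residual
        return float(beta_out[0] / beta_exp[0]), float(se_out[0] / abs(beta_exp[0])), 0.0
    res = sm.WLS(beta_out, beta_exp[:, None], weights=w).fit()
    beta = float(res.params[0])
    scale = float(res.scale) if len(beta_exp) > 1 else 0.0  # RSS_w / (n - 1)
    se_fixed = float(res.bse[0] / np.sqrt(res.scale)) if res.scale > 0 else (
        1.0 / np.sqrt(np.sum(w * beta_exp**2))
    )
    return beta, se_fixed, scale


def ivw(
    h: HarmonizedSet,
    re_mode: str = "multiplicative_random",
    level: float = 0.95,
) -> MrEstimate:
    """Inverse-variance-weighted estimate over all harmonized variants."""
    if re_mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown re_mode {re_mode!r}")
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("ivw requires at least 2 variants")
    bx, _, by, sy = _columns(h)
    beta, se, scale = _ivw_fit(bx, by, sy)
    if re_mode == "multiplicative_random":
        se *= max(1.0, np.sqrt(scale))
    return _estimate("ivw", beta, se, _normal_p(beta, se), h.n_snp, level)


def mr_egger(h: HarmonizedSet, level: float = 0.95) -> EggerResult:
    """Weighted regression with a free intercept (directional pleiotropy)."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("mr_egger requires at least 3 variants")
    bx, _, by, sy = _columns(h)
    sign = np.where(bx < 0, -1.0, 1.0)  # orient exposure effects non-negative
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    n = len(x)
    scale = float(res.scale)  # RSS_w / (n - 2)
    inflation = max(1.0, np.sqrt(scale))
    if scale > 0:
        se_unscaled = res.bse / np.sqrt(scale)
    else:  # exact fit: rebuild unscaled covariance from the design
        X = sm.add_constant(x)
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        se_unscaled = np.sqrt(np.diag(cov))
    intercept, slope = float(res.params[0]), float(res.params[1])
    se_int, se_slope = float(se_unscaled[0] * inflation), float(se_unscaled[1] * inflation)
    slope_est = _estimate(
        "egger", slope, se_slope, _t_p(slope, se_slope, n - 2), n, level
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_int,
        intercept_pval=_t_p(intercept, se_int, n - 2),
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Value of the weighted empirical quantile function at probability 0.5.

    Cumulative weight midpoints ``(cumsum(w) - w/2) / sum(w)`` anchor a
    piecewise-linear interpolant between the order statistics.
    """
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def _parametric_bootstrap(point_fn, bx, sx, by, sy, n_boot, seed):
    """SE of a ratio-based statistic by resampling effects from their
    sampling distributions. Identical seed gives identical output."""
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        reps[b] = point_fn(bx_b, by_b)
    return float(np.std(reps, ddof=1))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> MrEstimate:
    """Weighted-median estimate; consistent when valid instruments carry at
    least half the weight. SE by seeded parametric bootstrap."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("weighted_median requires at least 3 variants")
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    bx, sx, by, sy = _columns(h)
    r, w = _ratios(bx, by, sy)
    beta = _weighted_median_point(r, w)

    def point(bx_b, by_b):
        bx_safe = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b, w_b = _ratios(bx_safe, by_b, sy)
        return _weighted_median_point(r_b, w_b)

    se = _parametric_bootstrap(point, bx, sx, by, sy, n_boot, seed)
    return _estimate("weighted_median", beta, se, _normal_p(beta, se), h.n_snp, level)


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman scale: 0.9 * min(sd, normalized MAD) * n^(-1/5).

    When one of the two spread measures collapses to zero (e.g. a majority
    atom) the other is used; when both are zero the ratios are a single atom
    and the bandwidth is zero by convention.
    """
    sd = float(np.std(r, ddof=1))
    mad = float(stats.median_abs_deviation(r, scale="normal"))
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return 0.0
    return phi * 0.9 * min(scales) * len(r) ** (-1 / 5)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of the weighted normal-kernel density over a dense grid with
    parabolic refinement around the best grid point."""
    bw = _mode_bandwidth(r, phi)
    if bw == 0:
        # all mass at one point, or a dominant atom: return the heaviest value
        vals, idx = np.unique(r, return_inverse=True)
        mass = np.bincount(idx, weights=w)
        return float(vals[np.argmax(mass)])
    lo, hi = r.min() - 3 * bw, r.max() + 3 * bw
    grid = np.linspace(lo, hi, 2048)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / bw) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    if 0 < i < len(grid) - 1:
        y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return float(grid[i] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0]))
    return float(grid[i])


def mode_based(
    h: HarmonizedSet,
    variant: str = "weighted",
    bandwidth_phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> MrEstimate:
    """Mode-based estimate: the most common Wald ratio under kernel smoothing.

    ``variant="weighted"`` weights each ratio by its inverse first-order
    variance; ``"simple"`` weights equally.
    """
    if variant not in ("simple", "weighted"):
        raise ValueError(f"unknown mode variant {variant!r}")
    if bandwidth_phi <= 0:
        raise ValueError("bandwidth_phi must be positive")
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("mode_based requires at least 3 variants")
    if seed is None:
        raise ValueError("mode_based requires an explicit bootstrap seed")
    bx, sx, by, sy = _columns(h)
    r, w = _ratios(bx, by, sy)
    if variant == "simple":
        w = np.ones_like(r)
    beta = _mode_point(r, w / w.sum(), bandwidth_phi)

    def point(bx_b, by_b):
        bx_safe = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b, w_b = _ratios(bx_safe, by_b, sy)
        if variant == "simple":
            w_b = np.ones_like(r_b)
        return _mode_point(r_b, w_b / w_b.sum(), bandwidth_phi)

    se = _parametric_bootstrap(point, bx, sx, by, sy, n_boot, seed)
    method = "weighted_mode" if variant == "weighted" else "simple_mode"
    return _estimate(method, beta, se, _normal_p(beta, se), h.n_snp, level)


def all_methods(
    h: HarmonizedSet,
    methods: list[str] | None = None,
    ivw_mode: str = "multiplicative_random",
    n_boot: int = 1000,
    seed: int | None = None,
    phi: float = 1.0,
    level: float = 0.95,
) -> list[MrEstimate]:
    """Run the requested estimator battery (default: all five) in a fixed order."""
    methods = methods or ["ivw", "egger", "weighted_median", "weighted_mode", "simple_mode"]
    out = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(h, re_mode=ivw_mode, level=level))
        elif m == "egger":
            out.append(mr_egger(h, level=level).slope)
        elif m == "weighted_median":
            out.append(weighted_median(h, n_boot=n_boot, seed=seed, level=level))
        elif m == "weighted_mode":
            out.append(mode_based(h, "weighted", phi, n_boot, seed, level))
        elif m == "simple_mode":
            out.append(mode_based(h, "simple", phi, n_boot, seed, level))
        else:
            raise ValueError(f"unknown method {m!r}")
    return out
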