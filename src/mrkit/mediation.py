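"""Two-step mediation MR: decomposing a total causal effect into the
mediator pathway and the direct remainder.

Given three univariable MR estimates on the log-odds scale —

* ``alpha`` — total effect of exposure on outcome,
* ``beta1`` — effect of exposure on the mediator,
* ``beta2`` — effect of the mediator on the outcome (instrumented by the
  mediator's own variants),

the indirect (mediated) effect is ``beta1 * beta2``, the direct effect is
``alpha − beta1 * beta2``, and the proportion mediated is
``beta1 * beta2 / alpha``. Standard errors come from the delta method under
independence of the three estimates, which holds to first order when the
three GWAS samples do not overlap:

* ``var(indirect) = beta1² se2² + beta2² se1²`` (first order; the
  ``se1² se2²`` cross term can be added with ``second_order=True``),
* ``var(direct) = se_alpha² + var(indirect)``,
* ``var(proportion) = var(indirect)/alpha² + indirect² se_alpha²/alpha⁴``.

A proportion outside [0, 1] (inconsistent mediation: the direct and indirect
effects have opposite signs, or the indirect exceeds the total) is returned
with a warning flag, not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["Estimate", "MediationResult", "two_step_mediation"]


@dataclass
class Estimate:
    """A (beta, se) pair on the log-odds scale."""

    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")


@dataclass
class MediationResult:
    alpha: Estimate
    beta1: Estimate
    beta2: Estimate
    indirect: Estimate
    direct: Estimate
    proportion: float
    proportion_se: float
    ci_low: float
    ci_high: float
    pval: float
    level: float
    inconsistent: bool

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_dict(self) -> dict:
        return {
            "alpha": vars(self.alpha), "beta1": vars(self.beta1),
            "beta2": vars(self.beta2), "indirect": vars(self.indirect),
            "direct": vars(self.direct), "proportion": self.proportion,
            "proportion_se": self.proportion_se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pval": self.pval, "level": self.level,
            "inconsistent": self.inconsistent,
        }


def _as_estimate(x) -> Estimate:
    if isinstance(x, Estimate):
        return x
    beta, se = x
    return Estimate(float(beta), float(se))


def two_step_mediation(
    alpha,
    beta1,
    beta2,
    level: float = 0.95,
    second_order: bool = False,
) -> MediationResult:
    """Decompose ``alpha`` into ``beta1*beta2`` (indirect) plus a direct rest.

    Each argument is an :class:`Estimate` or a (beta, se) pair. The identity
    ``direct + indirect == alpha`` is exact by construction. Raises
    ``ValueError`` when ``alpha`` is zero (the proportion is undefined).
    """
    a = _as_estimate(alpha)
    b1 = _as_estimate(beta1)
    b2 = _as_estimate(beta2)
    if a.beta == 0:
        raise ValueError("proportion mediated undefined for a zero total effect")

    ind = b1.beta * b2.beta
    var_ind = b1.beta**2 * b2.se**2 + b2.beta**2 * b1.se**2
    if second_order:
        var_ind += b1.se**2 * b2.se**2
    se_ind = var_ind**0.5

    direct = a.beta - ind
    se_direct = (a.se**2 + var_ind) ** 0.5

    prop = ind / a.beta
    var_prop = var_ind / a.beta**2 + (ind**2 / a.beta**4) * a.se**2
    se_prop = var_prop**0.5

    z = stats.norm.ppf(0.5 + level / 2)
    pval = float(2 * stats.norm.sf(abs(prop) / se_prop)) if se_prop > 0 else (
        1.0 if prop == 0 else 0.0
    )
    return MediationResult(
        alpha=a, beta1=b1, beta2=b2,
        indirect=Estimate(ind, se_ind) if se_ind > 0 else _zero_se_estimate(ind),
        direct=Estimate(direct, se_direct),
        proportion=prop, proportion_se=se_prop,
        ci_low=prop - z * se_prop, ci_high=prop + z * se_prop,
        pval=pval, level=level,
        inconsistent=not (0.0 <= prop <= 1.0),
    )


def _zero_se_estimate(beta: float) -> Estimate:
    e = Estimate.__new__(Estimate)
    e.beta = beta
    e.se = 0.0
    return e
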