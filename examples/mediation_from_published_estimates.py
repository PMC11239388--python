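"""Decompose a published total effect into mediated and direct parts.

Takes three published IVW odds ratios — exposure->outcome (total),
exposure->mediator, and mediator->outcome — converts them to the log-odds
scale, and runs the two-step mediation decomposition.
"""

import math

from mrkit import ci_to_se, two_step_mediation

# OR (95% CI) as printed in a typical report
total = (math.log(1.13), ci_to_se(1.05, 1.21))            # exposure -> outcome
exposure_to_mediator = (math.log(1.12), ci_to_se(1.08, 1.17))
mediator_to_outcome = (math.log(1.49), ci_to_se(1.35, 1.64))

res = two_step_mediation(total, exposure_to_mediator, mediator_to_outcome)

print(f"indirect effect (log-OR): {res.indirect.beta:.4f} (se {res.indirect.se:.4f})")
print(f"direct effect   (log-OR): {res.direct.beta:.4f} (se {res.direct.se:.4f})")
print(
    f"proportion mediated: {res.proportion_pct:.1f}% "
    f"(95% CI {100 * res.ci_low:.1f}-{100 * res.ci_high:.1f}%, p = {res.pval:.3f})"
)
print(
    "Meaning: about this share of the exposure's effect on the outcome flows "
    "through the mediator; the rest is direct (or via unmodelled paths)."
)
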