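# Methods

This note records the statistical models mrkit implements, the conventions
and defaults it commits to where the literature leaves a choice open, and
what its synthetic-data tests do and do not demonstrate about real data.

## Data model

A summary-statistics table holds one GWAS trait's per-variant records:
identifier, chromosome/position (1-based, treated as opaque coordinates —
no genome-build awareness), effect and other allele, optional effect-allele
frequency, additive effect `beta` (log odds ratio for binary traits, trait
SD units for continuous), its standard error, p-value, and optional sample
size. Rows violating the validity rules (non-positive SE, p outside (0,1],
identical or non-ACGT alleles, frequency outside (0,1), duplicate ids) are
dropped with a logged reason rather than aborting: large public files
routinely contain a few malformed rows. The canonical on-disk dialect is a
tab-delimited file with one header line and empty fields (or `.`) for
missing values; a column map adapts foreign headers.

## Instrument selection

Three serial filters, each with a full exclusion trail:

1. **Association**: `pval < p_threshold`. Default 5e-6; genome-wide 5e-8
   is a config value away (both thresholds occur in practice, e.g. a more
   permissive one for exposures with few genome-wide-significant loci, the
   strict one for well-powered anthropometric traits).
2. **Independence**: greedy LD clumping at `r² < 0.001` within a 10,000 kb
   window — the de facto standard. Candidates are ranked by ascending
   p-value with a lexicographic id tie-break so output is deterministic.
   LD is an explicit input (a pairwise r² matrix); pairs it does not cover
   count as unlinked, which makes the step reproducible and
   reference-panel-agnostic. Distances are center-to-center on the same
   chromosome; cross-chromosome pairs never clump.
3. **Strength**: per-variant F = beta²/se², dropping F < 10, the
   conventional weak-instrument floor. Applied after clumping, so the
   reported instruments are exactly the set entering estimation.

Confounder screening is a local annotation table (variant → trait label)
standing in for a web lookup against a GWAS catalog; instruments annotated
to any listed confounder trait are removed in a *rerun* reported alongside
the primary analysis, not in place of it.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: matching
orientation is kept, swapped orientation negates the outcome beta and
complements its frequency, complementary-strand records are strand-flipped
first. Palindromic variants (A/T, C/G) carry no strand information in their
allele labels, so orientation is inferred from the allele frequencies; if
either frequency is missing or falls within 0.5 ± 0.08 (the community-
standard ambiguity band), the variant is dropped. Indels and irreconcilable
pairs are dropped as incompatible. The retained count is always reported —
downstream degrees of freedom depend on it.

## Estimators

All effects stay on the log-odds scale internally; odds ratios appear only
at the reporting boundary, so CI asymmetry in OR space falls out of the
exponential transform naturally.

- **IVW**: weighted least squares of outcome on exposure effects through
  the origin, weights 1/se_out². The default variance model is
  multiplicative random effects — the fixed-effect SE times
  max(1, weighted residual SD) — which widens intervals under
  heterogeneity but never narrows them below the fixed-effect SE. Fixed
  effects are available by argument. p-values are normal.
- **MR-Egger**: the same regression with a free intercept after orienting
  all exposure effects non-negative. The intercept estimates directional
  pleiotropy; slope and intercept SEs carry the same multiplicative
  inflation floored at 1, and p-values use t with n−2 df (the conventional
  pairing, stated explicitly because conventions differ).
- **Weighted median**: the 0.5 point of the weighted empirical quantile
  function of the Wald ratios (weights = inverse first-order ratio
  variance beta_exp²/se_out²), linearly interpolated between order
  statistics. Consistent when valid instruments carry ≥ 50% of the weight.
- **Mode-based (simple/weighted)**: the argmax of a normal-kernel density
  over the Wald ratios. Bandwidth is `phi` × 0.9·min(sd, MAD)·n^(−1/5)
  (modified Silverman; MAD normal-consistent). When one spread measure
  collapses to zero — e.g. a majority atom — the other is used; when both
  are zero the ratios are a single atom, returned exactly. The density is
  maximized on a 2048-point grid with parabolic refinement.
- Bootstrap SEs (median and mode) are parametric: effects resampled from
  normal(observed, se), 1000 replicates by default, seed mandatory — no
  silent nondeterminism. Degenerate exact-fit inputs can yield se = 0; the
  p-value is then defined by limit (1 for a zero estimate, 0 otherwise).

## Diagnostics

Cochran's Q is the weighted sum of squared deviations of Wald ratios from
the fixed-effect IVW center with the same first-order weights; df = n−1,
I² = max(0, (Q−df)/Q). The Egger intercept test re-exposes the regression
intercept. Leave-one-out refits IVW dropping each variant (same variance
mode as the headline analysis); the single-variant display lists every Wald
ratio, flagging zero exposure effects instead of failing.

## Meta-analysis and mediation

Published ORs with 95% CIs are converted to log-OR SEs via
(ln hi − ln lo)/(2z). Fixed-effect pooling is the default — it reproduces
the usual replication workflow — with DerSimonian–Laird random effects as a
sensitivity companion (tau² = max(0, (Q−df)/(Σw − Σw²/Σw))).

Two-step mediation takes three univariable MR estimates — total effect α,
exposure→mediator β₁, mediator→outcome β₂ (the mediator instrumented by its
own variants, no multivariable adjustment) — and reports indirect = β₁β₂,
direct = α − β₁β₂ (exact by construction), and proportion = β₁β₂/α. SEs use
the delta method under independence of the three estimates, justified to
first order by non-overlapping GWAS samples: var(ind) = β₁²se₂² + β₂²se₁²
(the second-order se₁²se₂² term is available behind a flag), var(direct) =
se_α² + var(ind), var(prop) = var(ind)/α² + ind²se_α²/α⁴. A proportion
outside [0,1] (inconsistent mediation) is flagged, not rejected. Published
mediation CIs computed by other means (e.g. bootstrap over the original
data) can be wider than this delta-method interval; mrkit reports its own
interval and does not attempt to match unspecified methods.

## Synthetic data

The generator works directly on the summary-statistic level — no
individual-level genotypes — which is sufficient for every estimator in
scope and orders of magnitude faster. The causal graph is
exposure → mediator → outcome with a direct exposure → outcome path:

- exposure instruments (default m = 100): γ_j ~ Normal(0, 0.05²) with
  |γ_j| floored at 0.03; mediator effect δγ_j; outcome effect
  θ_direct·γ_j + κδγ_j + sign(γ_j)·a_j;
- mediator instruments (default 100): exposure effect 0, mediator effect
  η_j drawn like γ, outcome effect κη_j. A separate mediator instrument
  set is what makes the univariable mediator→outcome step identifiable —
  with exposure instruments alone the ratio converges to κ + θ_direct/δ.
  It also gives reverse MR realistic behaviour: in the reverse direction
  selection picks predominantly mediator-driven outcome variants, whose
  exposure effects are null.

Observed effects add normal noise with the large-sample per-allele SE
1/sqrt(2·maf·(1−maf)·n), maf ~ Uniform(0.05, 0.5), each trait with its own
sample size (default 3×10⁵, non-overlapping by construction — matching the
independence assumption in the mediation SEs). p-values come from the
observed z-scores. Pleiotropic effects a_j ~ Normal(mean, sd²) are
expressed relative to the exposure-increasing allele — the frame in which
the Egger intercept is defined — so a nonzero mean is genuinely
directional; with signed allele-frame effects the orientation step would
symmetrize it away. Pleiotropic variants are listed in the generated
confounder-annotation table. LD blocks are materialized as a
block-diagonal r² matrix with members 1 kb apart and everything else
separated by ≥ 50 Mb.

Default effect sizes (θ_direct = 0.077, δ = 0.113, κ = 0.399) mirror the
scale of a sleep-apnea → BMI → osteoarthritis analysis, implying a total
effect of 0.1221 and a proportion mediated of 0.3693. The instrument-effect
floor of 0.03 is chosen so that even at the least-informative allele
frequency an instrument clears the 5e-6 selection threshold with margin
(z ≈ 5 at maf 0.05): the floor's purpose is that every generated
instrument is a genuine instrument, keeping selection deterministic and
winner's curse negligible.

**What the simulations do not emulate**: winner's curse from discovery
selection, sample overlap between GWAS, correlated pleiotropy (violations
of InSiDE), case-control SE refinements, real LD panels, and allele-
frequency mismatch between cohorts. Passing calibration and recovery tests
therefore demonstrates correctness of the estimators and plumbing under
the stated model, not robustness to those real-data complications.

## Problem sizes and numerical choices

Calibration runs use 500 replicates of the full select→harmonize→estimate
chain (null size of IVW; Egger intercept power under directional
pleiotropy with mean 0.02, sd 0.01); parameter recovery uses 200
replicates of the complete two-step pipeline. Both finish in well under a
minute on one core; the sizes were chosen to make 3-binomial-SE /
3-Monte-Carlo-SE assertions meaningful. All replicate seeds are spawned
deterministically from a single base seed. Ties in clumping are broken
lexicographically; weighted-median interpolation clamps outside the first
and last cumulative-weight midpoints; the mode grid spans the ratio range
± 3 bandwidths.

## Known limitations

- No multivariable MR, MR-PRESSO, Steiger filtering, or
  contamination-mixture estimators.
- Multiple outcomes are analysed independently at α = 0.05 with no
  multiplicity adjustment.
- The confounder screen is only as good as the supplied annotation table.
- Proxy-variant lookup and reference-panel strand inference are out of
  scope; palindromic variants without usable frequencies are simply lost.
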