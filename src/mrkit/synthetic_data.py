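"""Synthetic two-sample GWAS summary statistics with a known causal graph.

The generator emulates the data a two-step mediation MR consumes, directly
on the summary-statistic level (no individual-level genotypes). The causal
graph is exposure → mediator → outcome with an optional direct
exposure → outcome path and optional per-variant horizontal pleiotropy:

* exposure instruments (``m_snps``): true exposure effect γ_j drawn from a
  zero-mean normal with a minimum-|effect| floor so every instrument is
  genuinely strong; mediator effect δ·γ_j; outcome effect
  θ_direct·γ_j + κ·δ·γ_j + a_j where a_j is the pleiotropic term;
* mediator instruments (``m_mediator_snps``): no exposure effect, mediator
  effect η_j drawn the same way, outcome effect κ·η_j. A separate instrument
  set for the mediator is what makes the univariable mediator → outcome MR
  step identifiable — with exposure instruments alone the ratio estimate
  would converge to κ + θ_direct/δ, not κ.

Observed effects are the true effects plus normal noise with the standard
large-sample per-allele standard error ``1/sqrt(2·maf·(1−maf)·n)`` using
each trait's own sample size; p-values follow from the observed z scores.
The three samples are non-overlapping by construction, matching the
independence assumption used in the mediation standard errors.

LD structure is materialized as a block-diagonal r² matrix over the leading
exposure instruments (``ld_blocks``), with block members placed a kilobase
apart so clumping windows engage; everything else is unlinked. Variants
carrying pleiotropy are listed in a confounder-annotation table under the
trait label ``"pleiotropy"`` so the confounder-exclusion step can be
exercised against ground truth.

Defaults mirror the effect scale of a sleep-apnea → BMI → osteoarthritis
analysis: θ_direct = 0.077, δ = 0.113, κ = 0.399 on the log-odds scale
(implied total effect ≈ 0.122, proportion mediated ≈ 0.369), with
100 + 100 instruments and 3×10⁵ samples per GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import ivw
from .diagnostics import egger_intercept_test
from .harmonize import harmonize
from .instruments import ConfounderAnnotation, LdInfo, select_instruments
from .sumstats_io import SumstatsTable

__all__ = [
    "Pleiotropy",
    "SimulationConfig",
    "SimulatedStudy",
    "CalibrationReport",
    "simulate_study",
    "simulate_null_calibration",
]

# non-palindromic biallelic pairs used for generated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class Pleiotropy:
    """Per-variant pleiotropic outcome effects a_j ~ Normal(mean, sd²).

    ``mean = 0`` gives balanced pleiotropy (InSiDE-satisfying); a nonzero
    mean gives directional pleiotropy that biases IVW and shifts the Egger
    intercept.
    """

    mean: float = 0.0
    sd: float = 0.0

    @property
    def kind(self) -> str:
        if self.mean == 0 and self.sd == 0:
            return "none"
        return "balanced" if self.mean == 0 else "directional"


@dataclass
class SimulationConfig:
    m_snps: int = 100
    m_mediator_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05
    gamma_floor: float = 0.03
    n_exp: int = 300_000
    n_med: int = 300_000
    n_out: int = 300_000
    theta_direct: float = 0.077
    delta: float = 0.113
    kappa: float = 0.399
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 3:
            raise ValueError("m_snps must be at least 3")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
        if min(self.n_exp, self.n_med, self.n_out) <= 0:
            raise ValueError("sample sizes must be positive")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.delta * self.kappa

    @property
    def proportion_mediated(self) -> float:
        if self.theta_total == 0:
            return float("nan")  # undefined under the global null
        return self.delta * self.kappa / self.theta_total


@dataclass
class Truth:
    """Generating parameters plus the implied total effect and proportion."""

    theta_direct: float
    delta: float
    kappa: float
    theta_total: float
    proportion_mediated: float
    gamma: np.ndarray      # exposure-instrument effects on the exposure
    eta: np.ndarray        # mediator-instrument effects on the mediator
    pleiotropy: np.ndarray  # per-exposure-instrument outcome offsets a_j


@dataclass
class SimulatedStudy:
    exposure: SumstatsTable
    mediator: SumstatsTable
    outcome: SumstatsTable
    ld: LdInfo
    truth: Truth
    confounder_ann: ConfounderAnnotation
    config: SimulationConfig


def _floored_normal(rng, sd: float, floor: float, size: int) -> np.ndarray:
    x = rng.normal(0.0, sd, size)
    return np.sign(np.where(x == 0, 1.0, x)) * np.maximum(np.abs(x), floor)


def _positions(m_total: int, ld_blocks: list[tuple[int, float]]):
    """Chromosome/position layout: LD-block members 1 kb apart, everything
    else separated by 50 Mb gaps (outside any clumping window), cycling
    over 22 chromosomes."""
    chroms, positions = [], []
    block_sizes = [size for size, _ in ld_blocks]
    i = 0
    chrom, pos = 1, 1_000_000
    for size in block_sizes:
        size = min(size, m_total - i)
        if size <= 0:
            break
        for j in range(size):
            chroms.append(str(chrom))
            positions.append(pos + j * 1000)
        pos += size * 1000 + 50_000_000
        i += size
        if pos > 200_000_000:
            chrom = chrom % 22 + 1
            pos = 1_000_000
    while i < m_total:
        chroms.append(str(chrom))
        positions.append(pos)
        pos += 50_000_000
        i += 1
        if pos > 200_000_000:
            chrom = chrom % 22 + 1
            pos = 1_000_000
    return chroms, positions


def _ld_matrix(snp_ids, ld_blocks):
    m = np.eye(len(snp_ids))
    i = 0
    for size, r2 in ld_blocks:
        size = min(size, len(snp_ids) - i)
        if size <= 0:
            break
        m[i:i + size, i:i + size] = r2
        np.fill_diagonal(m[i:i + size, i:i + size], 1.0)
        i += size
    return LdInfo(snp_ids, m)


def _observed_table(rng, snp_ids, chroms, positions, alleles, maf, true_beta,
                    n, label, seed) -> SumstatsTable:
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    beta = rng.normal(true_beta, se)
    z = beta / se
    pval = np.maximum(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))
    df = pd.DataFrame(
        {
            "snp_id": pd.array(snp_ids, dtype="string"),
            "chrom": pd.array(chroms, dtype="string"),
            "pos": pd.array(positions, dtype="Int64"),
            "effect_allele": pd.array([a for a, _ in alleles], dtype="string"),
            "other_allele": pd.array([b for _, b in alleles], dtype="string"),
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": pd.array([n] * len(snp_ids), dtype="Int64"),
        }
    )
    return SumstatsTable(df, trait_label=label, trait_type="binary",
                         provenance=f"simulated(seed={seed})")


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one exposure/mediator/outcome study; same config (including
    seed) gives a bit-identical result."""
    rng = np.random.default_rng(config.seed)
    m_e, m_m = config.m_snps, config.m_mediator_snps
    m_total = m_e + m_m
    snp_ids = [f"rs{i + 1:06d}" for i in range(m_total)]
    chroms, positions = _positions(m_total, config.ld_blocks)
    alleles = [_ALLELE_PAIRS[int(k)] for k in rng.integers(0, len(_ALLELE_PAIRS), m_total)]
    maf = rng.uniform(*config.maf_range, m_total)

    gamma = _floored_normal(rng, config.gamma_sd, config.gamma_floor, m_e)
    eta = _floored_normal(rng, config.gamma_sd, config.gamma_floor, m_m)
    pl = config.pleiotropy
    a_j = (
        rng.normal(pl.mean, pl.sd, m_e)
        if pl.kind != "none"
        else np.zeros(m_e)
    )

    true_exp = np.concatenate([gamma, np.zeros(m_m)])
    true_med = np.concatenate([config.delta * gamma, eta])
    # Pleiotropic effects are expressed relative to the exposure-increasing
    # allele — the frame in which the Egger intercept is defined — so a
    # nonzero mean is directional pleiotropy there, not in the raw allele
    # frame where signed gamma_j would symmetrize it away.
    true_out = np.concatenate(
        [
            config.theta_direct * gamma + config.kappa * config.delta * gamma
            + np.sign(gamma) * a_j,
            config.kappa * eta,
        ]
    )

    make = lambda truth, n, label: _observed_table(
        rng, snp_ids, chroms, positions, alleles, maf, truth, n, label, config.seed
    )
    exposure = make(true_exp, config.n_exp, "exposure")
    mediator = make(true_med, config.n_med, "mediator")
    outcome = make(true_out, config.n_out, "outcome")

    flagged = [sid for sid, a in zip(snp_ids[:m_e], a_j) if a != 0]
    ann = ConfounderAnnotation.from_records(
        [(sid, "pleiotropy") for sid in flagged]
    )
    truth = Truth(
        theta_direct=config.theta_direct,
        delta=config.delta,
        kappa=config.kappa,
        theta_total=config.theta_total,
        proportion_mediated=config.proportion_mediated,
        gamma=gamma,
        eta=eta,
        pleiotropy=a_j,
    )
    return SimulatedStudy(
        exposure=exposure, mediator=mediator, outcome=outcome,
        ld=_ld_matrix(snp_ids, config.ld_blocks), truth=truth,
        confounder_ann=ann, config=config,
    )


@dataclass
class CalibrationReport:
    n_reps: int
    alpha: float
    ivw_rejection_rate: float
    egger_intercept_rejection_rate: float
    binomial_se: float
    ivw_mean_estimate: float

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_null_calibration(
    config: SimulationConfig,
    n_reps: int = 500,
    alpha: float = 0.05,
    p_threshold: float = 5e-6,
) -> CalibrationReport:
    """Type-I-error check of the full select → harmonize → estimate chain.

    Requires a causally null configuration (``theta_direct == 0`` and
    ``delta * kappa == 0``); pleiotropy may be present, which is how the
    Egger-intercept test's power under directional pleiotropy is measured.
    Per-replicate seeds are spawned deterministically from ``config.seed``.
    """
    if config.theta_direct != 0 or config.delta * config.kappa != 0:
        raise ValueError("calibration requires a causally null configuration")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_reps) % (2**31)
    ivw_rej = egger_rej = 0
    ivw_sum = 0.0
    for s in seeds:
        cfg = SimulationConfig(**{**asdict(config), "seed": int(s),
                                  "pleiotropy": config.pleiotropy,
                                  "ld_blocks": config.ld_blocks})
        study = simulate_study(cfg)
        inst = select_instruments(study.exposure, p_threshold=p_threshold, ld=study.ld)
        h = harmonize(inst.table, study.outcome)
        est = ivw(h)
        ivw_sum += est.beta
        if est.pval < alpha:
            ivw_rej += 1
        _, _, p_int = egger_intercept_test(h)
        if p_int < alpha:
            egger_rej += 1
    return CalibrationReport(
        n_reps=n_reps,
        alpha=alpha,
        ivw_rejection_rate=ivw_rej / n_reps,
        egger_intercept_rejection_rate=egger_rej / n_reps,
        binomial_se=float(np.sqrt(alpha * (1 - alpha) / n_reps)),
        ivw_mean_estimate=ivw_sum / n_reps,
    )
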