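"""End-to-end orchestration of a two-sample MR study.

``run_full`` composes, from a single config: forward MR of the exposure on
each outcome (with diagnostics and an optional confounder-filtered rerun),
reverse MR with the roles exchanged (instruments re-selected on the new
exposure — never reused), replication + inverse-variance meta-analysis when
a replication dataset is configured, and two-step mediation when a mediator
is configured. Every requested block appears in the report, either with
results or explicitly marked skipped/failed; identical config and seed give
an identical report apart from the timestamp.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import MrKitError
from .diagnostics import cochran_q, egger_intercept_test, leave_one_out, single_snp
from .estimators import all_methods, ivw
from .harmonize import harmonize
from .instruments import ConfounderAnnotation, LdInfo, filter_confounders, select_instruments
from .mediation import two_step_mediation
from .meta import MetaInput, meta_fixed, meta_random_dl
from .sumstats_io import SumstatsTable, read_sumstats

__all__ = ["AnalysisConfig", "run_forward", "run_reverse", "run_full", "mr_analysis"]

ALL_METHODS = ["ivw", "egger", "weighted_median", "weighted_mode", "simple_mode"]
_BOOTSTRAP_METHODS = {"weighted_median", "weighted_mode", "simple_mode"}


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run.

    Paths refer to canonical-dialect summary-statistics TSVs; ``ld_matrix``
    is a (snp_id, snp_id, r2) TSV; ``confounder_table`` a (snp_id,
    trait_label) TSV. ``seed`` is mandatory whenever a bootstrap-based
    method is requested.
    """

    exposure: str
    outcomes: dict[str, str]                     # label -> path
    out_dir: str
    mediator: str | None = None
    replication: str | None = None               # outcome table for replication MR
    ld_matrix: str | None = None
    confounder_table: str | None = None
    confounder_traits: list[str] = field(default_factory=list)
    p_threshold: float = 5e-6
    p_threshold_mediator: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    f_min: float = 10.0
    palindromic_tol: float = 0.08
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    phi: float = 1.0
    meta_model: str = "fixed"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.exposure, *self.outcomes.values()]
        for p in (self.mediator, self.replication, self.ld_matrix, self.confounder_table):
            if p is not None:
                paths.append(p)
        for p in paths:
            if not Path(p).exists():
                raise MrKitError(f"configured path does not exist: {p}")
        if self.seed is None and _BOOTSTRAP_METHODS & set(self.methods):
            raise MrKitError("seed is mandatory when bootstrap methods are requested")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_ld(config: AnalysisConfig) -> LdInfo | None:
    if config.ld_matrix is None:
        return None
    df = pd.read_csv(config.ld_matrix, sep="\t", header=None,
                     names=["a", "b", "r2"], dtype={"a": str, "b": str})
    ids = sorted(set(df["a"]) | set(df["b"]))
    return LdInfo.from_pairs(ids, df.itertuples(index=False, name=None))


def mr_analysis(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdInfo | None = None,
    p_threshold: float = 5e-6,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    f_min: float = 10.0,
    palindromic_tol: float = 0.08,
    methods: list[str] | None = None,
    ivw_mode: str = "multiplicative_random",
    n_boot: int = 1000,
    seed: int | None = None,
    phi: float = 1.0,
    instruments=None,
):
    """Select instruments (unless given), harmonize, and run the estimator
    battery. Returns (InstrumentSet, HarmonizedSet, [MrEstimate])."""
    if instruments is None:
        instruments = select_instruments(
            exposure, p_threshold=p_threshold, ld=ld,
            r2_threshold=r2_threshold, window_kb=window_kb, f_min=f_min,
        )
    h = harmonize(instruments.table, outcome, palindromic_eaf_tol=palindromic_tol)
    estimates = all_methods(
        h, methods=methods, ivw_mode=ivw_mode, n_boot=n_boot, seed=seed, phi=phi
    )
    return instruments, h, estimates


def _diagnostics_block(h, ivw_mode: str) -> dict:
    block: dict = {"n_snp": h.n_snp}
    block["cochran_q"] = cochran_q(h).to_dict()
    if h.n_snp >= 3:
        est, se, p = egger_intercept_test(h)
        block["egger_intercept"] = {"estimate": est, "se": se, "pval": p}
        block["leave_one_out"] = [
            {"dropped": row.dropped_snp_id, **row.estimate.to_dict()}
            for row in leave_one_out(h, re_mode=ivw_mode)
        ]
    block["single_snp"] = [
        {"snp_id": row.snp_id,
         **(row.estimate.to_dict() if row.estimate else {"note": row.note})}
        for row in single_snp(h)
    ]
    return block


def _one_direction(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    config: AnalysisConfig,
    ld: LdInfo | None,
    ann: ConfounderAnnotation | None,
    p_threshold: float,
    confounder_rerun: bool,
) -> dict:
    inst, h, estimates = mr_analysis(
        exposure, outcome, ld=ld, p_threshold=p_threshold,
        r2_threshold=config.r2_threshold, window_kb=config.window_kb,
        f_min=config.f_min, palindromic_tol=config.palindromic_tol,
        methods=config.methods, ivw_mode=config.ivw_mode,
        n_boot=config.n_boot, seed=config.seed, phi=config.phi,
    )
    block = {
        "status": "ok",
        "n_instruments": inst.n_instruments,
        "n_harmonized": h.n_snp,
        "n_dropped_harmonization": len(h.dropped),
        "estimates": [e.to_dict() for e in estimates],
        "diagnostics": _diagnostics_block(h, config.ivw_mode),
    }
    if confounder_rerun and ann is not None and config.confounder_traits:
        filtered = filter_confounders(inst, ann, config.confounder_traits)
        n_removed = inst.n_instruments - filtered.n_instruments
        if filtered.n_instruments >= 2:
            h2 = harmonize(filtered.table, outcome,
                           palindromic_eaf_tol=config.palindromic_tol)
            block["confounder_filtered"] = {
                "status": "ok",
                "n_removed": n_removed,
                "n_instruments": filtered.n_instruments,
                "estimates": [ivw(h2, re_mode=config.ivw_mode).to_dict()],
            }
        else:
            block["confounder_filtered"] = {
                "status": "skipped",
                "reason": "fewer than 2 instruments remain after the confounder filter",
                "n_removed": n_removed,
            }
    return block


def run_forward(config: AnalysisConfig) -> dict:
    """Forward MR of the exposure on every configured outcome."""
    config.validate()
    exposure = read_sumstats(config.exposure, trait_label="exposure")
    ld = _load_ld(config)
    ann = (ConfounderAnnotation.from_tsv(config.confounder_table)
           if config.confounder_table else None)
    block = {}
    for label, path in config.outcomes.items():
        outcome = read_sumstats(path, trait_label=label)
        try:
            block[label] = _one_direction(
                exposure, outcome, config, ld, ann,
                config.p_threshold, confounder_rerun=True,
            )
        except MrKitError as exc:  # record, keep sibling outcomes running
            block[label] = {"status": "failed", "error": str(exc)}
    return block


def run_reverse(config: AnalysisConfig) -> dict:
    """Reverse MR: each outcome becomes the exposure, with instruments
    re-selected on it; the original exposure becomes the outcome."""
    config.validate()
    target = read_sumstats(config.exposure, trait_label="exposure")
    ld = _load_ld(config)
    block = {}
    for label, path in config.outcomes.items():
        new_exposure = read_sumstats(path, trait_label=label)
        try:
            block[label] = _one_direction(
                new_exposure, target, config, ld, None,
                config.p_threshold, confounder_rerun=False,
            )
        except MrKitError as exc:
            block[label] = {"status": "failed", "error": str(exc)}
    return block


def _meta_block(config: AnalysisConfig, forward: dict) -> dict:
    if config.replication is None:
        return {"status": "skipped", "reason": "no replication dataset configured"}
    first_label = next(iter(config.outcomes))
    disc = forward.get(first_label, {})
    if disc.get("status") != "ok":
        return {"status": "failed",
                "error": f"discovery analysis for {first_label!r} unavailable"}
    disc_ivw = next(e for e in disc["estimates"] if e["method"] == "ivw")
    exposure = read_sumstats(config.exposure, trait_label="exposure")
    replication = read_sumstats(config.replication, trait_label="replication")
    ld = _load_ld(config)
    try:
        _, _, est = mr_analysis(
            exposure, replication, ld=ld, p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold, window_kb=config.window_kb,
            f_min=config.f_min, palindromic_tol=config.palindromic_tol,
            methods=["ivw"], ivw_mode=config.ivw_mode,
        )
    except MrKitError as exc:
        return {"status": "failed", "error": str(exc)}
    rep_ivw = est[0]
    studies = [
        MetaInput("discovery", disc_ivw["beta"], disc_ivw["se"]),
        MetaInput("replication", rep_ivw.beta, rep_ivw.se),
    ]
    pool = meta_fixed if config.meta_model == "fixed" else meta_random_dl
    return {
        "status": "ok",
        "replication_ivw": rep_ivw.to_dict(),
        "pooled": pool(studies).to_dict(),
    }


def _mediation_block(config: AnalysisConfig, forward: dict) -> dict:
    if config.mediator is None:
        return {"status": "skipped", "reason": "no mediator dataset configured"}
    first_label = next(iter(config.outcomes))
    disc = forward.get(first_label, {})
    if disc.get("status") != "ok":
        return {"status": "failed",
                "error": f"total-effect analysis for {first_label!r} unavailable"}
    alpha = next(e for e in disc["estimates"] if e["method"] == "ivw")
    exposure = read_sumstats(config.exposure, trait_label="exposure")
    mediator = read_sumstats(config.mediator, trait_label="mediator")
    outcome = read_sumstats(config.outcomes[first_label], trait_label=first_label)
    ld = _load_ld(config)
    try:
        # exposure -> mediator with the exposure's instruments
        _, _, est_b1 = mr_analysis(
            exposure, mediator, ld=ld, p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold, window_kb=config.window_kb,
            f_min=config.f_min, palindromic_tol=config.palindromic_tol,
            methods=["ivw"], ivw_mode=config.ivw_mode,
        )
        # mediator -> outcome with the mediator's own instruments
        _, _, est_b2 = mr_analysis(
            mediator, outcome, ld=ld, p_threshold=config.p_threshold_mediator,
            r2_threshold=config.r2_threshold, window_kb=config.window_kb,
            f_min=config.f_min, palindromic_tol=config.palindromic_tol,
            methods=["ivw"], ivw_mode=config.ivw_mode,
        )
        med = two_step_mediation(
            (alpha["beta"], alpha["se"]),
            (est_b1[0].beta, est_b1[0].se),
            (est_b2[0].beta, est_b2[0].se),
        )
    except (MrKitError, ValueError) as exc:
        return {"status": "failed", "error": str(exc)}
    return {"status": "ok", **med.to_dict()}


def run_full(config: AnalysisConfig) -> dict:
    """Compose forward, reverse, meta, and mediation blocks and write the
    report (JSON plus per-outcome estimate TSVs) to ``config.out_dir``."""
    config.validate()
    forward = run_forward(config)
    reverse = run_reverse(config)
    report = {
        "forward": forward,
        "reverse": reverse,
        "meta": _meta_block(config, forward),
        "mediation": _mediation_block(config, forward),
        "provenance": {
            "config_hash": config.digest(),
            "version": __version__,
            "seed": config.seed,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    }
    failed = any(
        isinstance(b, dict) and b.get("status") == "failed"
        for section in report.values() if isinstance(section, dict)
        for b in section.values() if isinstance(b, dict)
    ) or any(
        report[k].get("status") == "failed" for k in ("meta", "mediation")
    )
    report["any_failed"] = failed

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    for direction in ("forward", "reverse"):
        for label, block in report[direction].items():
            if block.get("status") == "ok":
                pd.DataFrame(block["estimates"]).to_csv(
                    out_dir / f"{direction}_{label}_estimates.tsv",
                    sep="\t", index=False,
                )
    return report
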