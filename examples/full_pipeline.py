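"""Run the complete analysis pipeline — forward MR, reverse MR, replication
meta-analysis, and mediation — from summary-statistics files on disk."""

import tempfile
from pathlib import Path

from mrkit import AnalysisConfig, SimulationConfig, run_full, simulate_study, write_sumstats

workdir = Path(tempfile.mkdtemp(prefix="mrkit_example_"))
study = simulate_study(SimulationConfig(seed=2))
write_sumstats(study.exposure, workdir / "exposure.tsv")
write_sumstats(study.mediator, workdir / "mediator.tsv")
write_sumstats(study.outcome, workdir / "outcome.tsv")

config = AnalysisConfig(
    exposure=str(workdir / "exposure.tsv"),
    outcomes={"outcome": str(workdir / "outcome.tsv")},
    mediator=str(workdir / "mediator.tsv"),
    out_dir=str(workdir / "results"),
    seed=2,
)
report = run_full(config)

fwd = report["forward"]["outcome"]
ivw_row = next(e for e in fwd["estimates"] if e["method"] == "ivw")
print(f"forward IVW: OR = {ivw_row['or']:.3f} "
      f"({ivw_row['or_ci_low']:.3f}-{ivw_row['or_ci_high']:.3f}) "
      f"over {ivw_row['n_snp']} variants")
rev = report["reverse"]["outcome"]
rev_ivw = next(e for e in rev["estimates"] if e["method"] == "ivw")
print(f"reverse IVW: beta = {rev_ivw['beta']:.4f} (se {rev_ivw['se']:.4f}) "
      f"-> no reverse causation signal expected")
med = report["mediation"]
print(f"mediation: proportion mediated = {100 * med['proportion']:.1f}% "
      f"(truth {100 * study.truth.proportion_mediated:.1f}%)")
print(f"report written to {workdir / 'results' / 'report.json'}")
print("Meaning: the forward arm recovers the simulated causal effect, the "
      "reverse arm is null by design, and mediation recovers the share of "
      "the effect routed through the mediator.")
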