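"""Generate a synthetic two-sample MR study with known causal structure,
select instruments, harmonize, and run the full estimator battery with
diagnostics."""

from mrkit import (
    SimulationConfig,
    cochran_q,
    egger_intercept_test,
    harmonize,
    ivw,
    mode_based,
    mr_egger,
    select_instruments,
    simulate_study,
    weighted_median,
)

study = simulate_study(SimulationConfig(seed=1))
print(f"true total effect (log-OR): {study.truth.theta_total:.4f}")

inst = select_instruments(study.exposure, p_threshold=5e-6, ld=study.ld)
print(f"instruments selected: {inst.n_instruments} "
      f"(min F = {inst.f_stats.min():.0f})")

h = harmonize(inst.table, study.outcome)
print(f"variants harmonized with the outcome: {h.n_snp}")

for est in [
    ivw(h),
    mr_egger(h).slope,
    weighted_median(h, seed=1),
    mode_based(h, "weighted", seed=1),
    mode_based(h, "simple", seed=1),
]:
    print(f"  {est.method:<15} beta = {est.beta:.4f} (se {est.se:.4f}), "
          f"OR = {est.odds_ratio:.3f}")

q = cochran_q(h)
icpt, icpt_se, icpt_p = egger_intercept_test(h)
print(f"heterogeneity: Q = {q.q:.1f} (df {q.df}, p = {q.pval:.2f})")
print(f"Egger intercept: {icpt:.5f} (p = {icpt_p:.2f})")
print("Meaning: all five estimators should bracket the true effect; a "
      "non-significant Q and intercept indicate no detectable heterogeneity "
      "or directional pleiotropy, as expected for this clean simulation.")
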