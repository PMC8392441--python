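"""Exhaustive Cox cutpoint scanning and the early/late hazard summary.

Every one of the n-1 rank stratification points of a gene's expression
enters a Cox model; the per-gene summary is the sum of log2 hazard ratios
over FDR-significant cut-offs, normalised to cohort size, computed
separately for recurrence before the 60-month landmark and after it.
"""

from qsig import simdata, survmodel

cohort, truth = simdata.simulate_cohort(
    n_patients=600, beta_early=0.0, beta_late=0.8, censor_rate=0.25, seed=31,
    genes=["gLATE", "gNULL"], prognostic_genes=["gLATE"], gene_loading=0.7)
print(f"{len(cohort)} patients, {cohort['event'].sum()} events; "
      "gLATE loads on the post-landmark hazard only, gNULL on nothing")

for gene in ["gLATE", "gNULL"]:
    s = survmodel.gene_hazard_summary(cohort, gene, landmark=60.0)
    print(f"{gene}: early summary {s.early_summary:+.3f} "
          f"({s.n_sig_early} significant cut-offs), "
          f"late summary {s.late_summary:+.3f} ({s.n_sig_late})")
print("(a positive late summary with a null early one is the signature of "
      "late-recurrence association)")

labels, km, (lr_stat, lr_p), scan = survmodel.dichotomize_optimal(
    cohort, "gLATE", min_group=20)
print(f"optimal stratification at rank {scan.best_index}/{len(cohort)}: "
      f"median DMFS low = {km['low'].median:.0f} months, "
      f"high = {km['high'].median:.0f} months, log-rank p = {lr_p:.2e}")
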