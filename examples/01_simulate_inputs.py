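"""Generate every pipeline input with planted ground truth.

The dye-retention design: four breast-cancer cell lines, each with
proliferative (DiD-) and quiescent dye-retaining (DiD+) fractions in
triplicate.  A known subset of genes carries a true log2 fold-change in the
DiD+ group; the survival cohort hides a score effect on the late (post
5-year) hazard only.
"""

from qsig import simdata

counts, truth = simdata.simulate_counts(
    n_genes=1000, de_fraction=0.05, lfc_magnitude=2.5, dispersion=0.1, seed=1)
print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"planted DE genes: {len(truth.de_genes)} "
      f"(true |log2FC| = 2.5, NB dispersion = 0.1)")

cohort, ctruth = simdata.simulate_cohort(
    n_patients=400, beta_early=0.0, beta_late=0.7, censor_rate=0.3, seed=2)
print(f"cohort: {len(cohort)} patients, "
      f"{cohort['event'].sum()} distant-recurrence events, "
      f"{(cohort['er_status'] == 'positive').mean():.0%} ER+")
print(f"planted hazard: none before 60 months, log-HR 0.7 per score SD after")

edges_a, edges_b, ntruth = simdata.simulate_network(
    n_nodes=60, communities=4, p_in=0.35, p_out=0.02, overlap_fraction=0.5,
    seed=3)
print(f"network: two pseudo-database edge lists "
      f"({len(edges_a)} + {len(edges_b)} edges, 4 planted communities)")

genesets = simdata.simulate_genesets(
    universe=list(counts.index), n_sets=20, set_size_range=(15, 50),
    planted_sets=5, signal_genes=list(truth.de_genes[:20]), seed=4)
print(f"gene sets: {len(genesets)} (5 planted around the first 20 DE genes)")
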