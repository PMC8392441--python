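# Methods

This note records the models, parameter choices, numerical details and
limitations behind `qsig`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

The synthetic-data module reproduces the structure of a dye-retention
quiescence experiment: four cell lines (one per breast-cancer sub-type),
each contributing a proliferative (DiD−) and a dye-retaining quiescent
(DiD+) fraction in three replicates — 24 samples. Downstream, patient
cohorts with distant-metastasis-free survival (DMFS) in months, an event
flag and ER status stand in for the composite microarray cohorts used to
assess prognostic value, with a 60-month landmark separating early from
late recurrence.

## Synthetic data generators

**Counts.** Gene baseline abundances are log-normal (σ = 1.5 on the log
scale), normalised to proportions; the expected count is library size ×
proportion × 2^(log₂FC·[DiD+]), with no compositional renormalisation so
planted ratios are exact against the true library sizes (TMM handles the
resulting composition shift downstream, as it would for real data). Counts
are NB with var = μ + φμ², φ either common (default 0.1, a typical bulk
RNA-seq value) or trended (φ = 0.05 + 2/μ_cpm). Defaults: 2000 genes,
de_fraction 0.0635 (≈ 127 DE genes), |log₂FC| = 2.5 (comfortably beyond
the θ = 1.5 threshold, as the reported DE genes were), 97% of DE genes up —
quiescence programmes are predominantly up-regulated (123/127 in the
reference signature). Library sizes uniform on [1, 3]·10⁶, scaled to the
2000-gene universe so per-gene depth is realistic.

**Cohorts.** Piecewise-exponential DMFS with one knot at the landmark
(60 months): hazard λ₀·exp(β_early·s) before, λ₀·exp(β_late·s) after, with
λ₀ = ln2/60 (median ≈ 5 years for an average patient) and s a standard
normal latent score, shifted +0.5 SD for ER+ patients before
re-standardisation (ER+ tumours score higher on quiescence signatures).
Censoring is independent exponential; its rate is calibrated by bisection
against the realised event-time distribution so the expected censored
fraction matches `censor_rate` (default 0.3), with administrative
truncation at 240 months. Per-gene expression columns are x_g = ρ·s +
√(1−ρ²)·ε with ρ = 0.7 for prognostic genes, 0 otherwise, so single-gene
cutpoint scans can recover the planted genes. Defaults β_early = 0,
β_late = 0.7–0.8: the planted association is with late recurrence only.

**Networks.** Planted-partition graphs (default 60 nodes, 4 communities,
p_in = 0.35, p_out = 0.02), Uniform(0.2, 1] weights, random
interaction-type labels. Each edge is assigned to both pseudo-database
lists with probability `overlap_fraction` and to one otherwise, so the
union always covers the planted graph.

**Gene sets.** Planted sets draw ~80% of members from a supplied signal
list, the rest uniformly; background sets are uniform. In the pipeline the
signal list is drawn from the *up-regulated* planted DE genes:
direction-coherent sets are what hallmark-style ontologies look like on a
signed ranking, and mixed-sign sets cancel in the running sum.

## Differential expression

TMM follows the original trimmed-mean-of-M-values recipe: reference =
sample whose upper-quartile CPM is closest to the mean upper-quartile;
per-sample weighted mean of M-values after trimming 30% (M) and 5% (A)
two-sided, precision weights from the delta-method binomial variances;
factors rescaled to geometric mean 1.

Dispersions are estimated on the cell-mean model (cell-line × group
cells). For a grid of 61 log-spaced φ values in [10⁻⁴, 10], the cell means
are profiled out by a per-cell Newton solve of the NB score equation and a
Cox–Reid term (−½ log Fisher information per cell) corrects the profile
likelihood. The common φ maximises the summed APL; the trend is the
per-gene grid MLE locally averaged over 20 abundance bins; tagwise values
maximise APL_g(φ) − (w/2)(log φ − log trend_g)², a normal prior on log φ
with precision `prior_weight` (default 10, shrinkage of roughly the
strength edgeR's default prior degrees of freedom provide). A parabolic
refinement through the grid argmax gives off-grid estimates; w → ∞
recovers the trend exactly. This is a deliberate simplification of the
weighted-likelihood empirical-Bayes machinery: accuracy is established by
simulation recovery (Poisson ⇒ φ̂ ≤ 0.05; φ = 0.4 ⇒ φ̂ within ±0.1 at 2000
genes), not by numeric identity with any reference implementation.

The threshold test fits per-gene NB GLMs (log link, offsets = log TMM
effective library sizes, tagwise φ) with intercept + DiD group + cell-line
blocking dummies, via IRLS batched across genes. The cell line enters as a
blocking factor (one average DiD+ effect across lines); this is one of the
two parameterisations compatible with the design, chosen for parsimony.
H₀: |log₂FC| ≤ θ is tested Wald-style against the nearer boundary with a
t reference on the residual df: p = P(T > (|b|−θ)/se) + P(T > (|b|+θ)/se).
This is the standard composite-null bound, conservative inside the null.
The original quasi-likelihood F-test is deliberately not reproduced; the
acceptance standard is simulation recovery (sensitivity ≥ 0.8, empirical
FDR ≤ 0.10 at planted |log₂FC| = 3, φ = 0.1). BH ties are broken by gene
id for deterministic output.

Default filter: CPM > 10/median-library-size-in-millions in at least the
smallest group size — the conventional reading of "k determined by library
sizes, n by the design".

## Enrichment

The running sum increments by |stat|^p/Σ|stat|^p at set members (p = 1)
and decrements by 1/(N−k) elsewhere; ES is the extremum, with the positive
extremum preferred when the two magnitudes tie exactly (ties occur for
small symmetric instances; the convention is asserted by the brute-force
oracle tests). The leading edge is the members at or before the maximum
(at or after the minimum for negative ES). The null permutes gene labels
(n_perm same-size random sets), evaluated in O(k) from hit positions only;
NES divides by the mean same-sign |ES_perm| and the p-value is the
same-sign tail with +1 continuity. Gene-label (not phenotype) permutation
is the only option meaningful for a preranked list. The ranking fed to
GSEA is signed −log₁₀(p) from the *unthresholded* (θ = 0) test: the
threshold test's p-values are ≈ 1 for every gene inside ±θ, which would
make the ranking effectively binary and destroy the permutation null's
resolution. min_size 5, max_size 500.

## Network analysis

Composite construction: union of edge lists; self-loops and
missing/zero/negative weights dropped; duplicate unordered pairs merged
with mean weight and the union of type/origin labels (idempotent by
construction). "Eigenvalue" centrality is read as eigenvector centrality
(dominant eigenvector of the weighted adjacency, non-negative
orientation); betweenness and closeness use unweighted shortest paths
(closeness with the component-size correction); degree is the incident
edge count. The combined score z-standardises the four metrics, embeds the
Euclidean distance matrix by classical MDS at k = 1 (leading eigenpair of
the doubly-centred squared-distance matrix), orients the axis to correlate
positively with degree, shifts the minimum to 1 and takes log₁₀ — classical
MDS is sign- and offset-indeterminate and raw log₁₀ would be undefined on
negative coordinates, so orientation and shift are part of the definition
here. Designation "high" at ≥ the 75th percentile.

The rewiring null restarts from the observed graph each round and applies
one double-edge swap per edge (≈ a full randomisation pass), rejecting
swaps that create self-loops or multi-edges, so every replicate has the
identical degree sequence (asserted). Z compares the observed average
local clustering coefficient to the replicate ensemble, two-tailed normal
p. Communities: greedy modularity (weight-aware, deterministic;
the seed argument exists for interface symmetry), min 3 members reported.

## Survival

The Cox fitter maximises the Efron-tie-corrected partial likelihood by
Newton–Raphson with step-halving; risk-set sums are cumulative sums over
descending time, tie groups expanded into their Efron terms, so one fit is
O(n·p²) and the exhaustive scans stay cheap. Convergence at relative
log-likelihood change < 10⁻⁹; monotone likelihood (separation) is flagged
(|β| > 15) rather than raised, since extreme scan cut-offs routinely
separate. The fitter agrees with an independent implementation to ~10⁻⁶
and with grid-search maximisation of the hand-written partial likelihood
to 10⁻³ (tests).

The cutpoint scan ranks subjects by score and enumerates all n−1 binary
splits (min_group = 1 by default, the literal rule; a guard option exists
because one-subject arms give unstable Wald SEs, and analyses here
typically pass min_group = 10–20). BH runs across the scan; the optimum is
the minimal adjusted p. The early window censors follow-up
administratively at the landmark; the late window conditions on being
event-free past the landmark on the original time scale — the standard
landmark construction for "< 5 vs ≥ 5 years". The per-gene summary sums
log₂ HR over cut-offs with adjusted p ≤ 0.05 and divides by the window
cohort size (exactly 0 when nothing is significant); a raw-p variant is
behind `use_fdr=False`. ER enters the Cox models when its own univariate
coefficient is significant at 0.05 in that window ("adjusted automatically
for significant covariates"); always-include is an option. Wilcoxon
rank-sum comparisons use exact enumeration when both sides ≤ 10 and are
untied, else the tie-corrected normal approximation.

## Scoring and selection

"Difference between geometric means of log-expression" is implemented as
the difference of arithmetic means in log₂ space (the log of the
geometric-mean ratio); a literal geometric mean of log values is
ill-defined for negative logs. Scores are z-standardised across the cohort
(mean 0, SD 1 to 10⁻⁸). Signature genes missing from a matrix are dropped
with a warning, erroring above 50% missing. Dataset merging standardises
per dataset and per gene before concatenation — deliberately simple
plumbing, not an empirical-Bayes batch correction.

Selection is (multiplicity ≥ 2 OR high centrality) AND late-significant in
≥ 1 cohort. The functional arm is a disjunction because the published
22-gene evidence table contains both high-centrality genes with zero
leading-edge memberships and multi-leading-edge genes with low centrality;
a conjunction would contradict it. The ≥ 2 multiplicity default follows the
"multiple (≥2) gene sets" convention. The packaged reference table encodes
that published evidence; reselecting all 22 genes from it is an acceptance
test.

## Pipeline and problem sizes

`run_pipeline` executes the stages in dependency order with per-stage
seeds derived from one config seed, and writes a manifest with SHA-256
hashes of every output; identical configs reproduce identical hashes. The
default synthetic study uses 2000 genes, two cohorts of 250/220 patients,
1000 permutations and 1000 rewiring rounds (10⁴ available via config);
tests and the acceptance script scale these to 600–2000 genes, 200–500
permutations and 40–500 rounds, sizes chosen to keep recovery properties
well-powered while the whole suite runs in minutes on one CPU.

## Known limitations

* The DE stage approximates the quasi-likelihood F-test with a Wald t
  test; p-values need not match edgeR numerically, only operationally
  (recovery properties above).
* The GSEA caption ambiguity in the source material (hypergeometric vs
  permutation) is resolved in favour of the permutation scheme; no
  over-representation test is provided.
* Synthetic cohorts have proportional hazards within each window by
  construction; violations (crossing hazards, cure fractions) are not
  emulated, so passing tests say nothing about robustness to them.
* Generated networks have independent edges given the partition; real
  interactomes have degree heterogeneity and motif structure beyond the
  planted-partition model, which the rewiring null only partially probes.
* No batch effects are simulated and no ComBat-style correction is
  implemented; `standardize_datasets` removes only per-dataset per-gene
  location/scale.
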