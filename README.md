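# qsig — quiescence-signature discovery for tumour dormancy

`qsig` reimplements, as a tested and reusable Python library, the analysis
strategy used to derive gene signatures of breast-cancer cell **quiescence**
(mitotic dormancy) from dye-retention experiments: non-dividing cells retain
a lipophilic pulse-chase label (DiD+) while dividing cells dilute it (DiD−),
and the two fractions are profiled by bulk mRNA-seq across cell lines. The
pipeline turns such a count matrix into a compact gene signature supported
by three independent evidence streams, and relates that signature to the
timing of distant metastatic recurrence in patient cohorts.

It is aimed at computational biologists who want each stage as a callable,
testable unit rather than a one-off script, with a synthetic-data module
that plants ground truth in every input so the whole chain is verifiable
without access rights to patient data.

## The method

1. **Differential expression** (`qsig.dge`) — CPM filtering, TMM
   library-size normalisation, NB dispersion estimation (common, trended,
   tagwise via empirical-Bayes shrinkage on an adjusted profile
   likelihood), then a fold-change-threshold Wald test (TREAT-style) of
   H₀: |log₂FC| ≤ θ with θ = 1.5 at 5% BH FDR. Genes are only called when
   their fold-change is significantly *beyond* the threshold.
2. **Enrichment** (`qsig.enrichment`) — preranked GSEA: the weighted
   Kolmogorov–Smirnov running sum over a signed −log₁₀(p) ranking,
   gene-label permutation null, NES = ES / mean same-sign |ES_perm|, and
   **leading-edge multiplicity**: the number of significantly enriched sets
   whose leading edge contains a gene (≥ 2 ⇒ functional evidence).
3. **Network** (`qsig.netfunc`) — a composite functional-association
   network merged from multiple edge-list databases; total degree,
   betweenness, eigenvector and closeness centralities fused into one
   score by classical MDS at k = 1 (log₁₀-transformed); nodes at or above
   the 75th percentile are "high centrality". Validation against a
   degree-preserving double-edge-swap null for the clustering coefficient
   (one-sample Z-test), modularity communities, Fisher overlap tests.
4. **Survival** (`qsig.survmodel`) — Kaplan–Meier, log-rank, an in-house
   Cox partial-likelihood fitter (Newton–Raphson, Efron ties), and the
   **exhaustive cutpoint scan**: all n−1 rank stratification points of a
   gene's expression enter Cox models; the per-gene summary is
   Σ log₂ HR over FDR-significant cut-offs / n, computed separately for
   recurrence **early** (< 5 years; follow-up administratively censored at
   the 60-month landmark) and **late** (≥ 5 years; landmark risk-set
   conditioning), with ER status as an automatically included covariate.
5. **Selection** (`qsig.select`) — a gene enters the final signature iff
   (leading-edge multiplicity ≥ 2 **or** high centrality) **and** a
   significant late-recurrence association in ≥ 1 cohort.
6. **Scoring** (`qsig.sigscore`) — the signature score of a sample is the
   standardised difference between mean log₂ expression of the up- and
   down-regulated signature genes.

`qsig.simdata` generates all inputs with planted truth: NB counts with
group-wise fold-changes per cell line, piecewise-exponential survival
cohorts whose score effect differs before/after the landmark, modular
weighted networks emitted as two overlapping pseudo-database edge lists,
and gene-set collections with planted enriched sets.

The package also ships the published 22-gene quiescence signature's
evidence table (`qsig.load_reference_evidence()`), against which the
selection predicate is validated.

## Worked example

```bash
python examples/05_survival_cutpoint_scan.py
```

```
600 patients, 437 events; gLATE loads on the post-landmark hazard only, gNULL on nothing
gLATE: early summary +0.000 (0 significant cut-offs), late summary +0.862 (198)
gNULL: early summary +0.000 (0 significant cut-offs), late summary +0.000 (0)
(a positive late summary with a null early one is the signature of late-recurrence association)
optimal stratification at rank 33/600: median DMFS low = 100 months, high = 56 months, log-rank p = 1.18e-02
```

The planted late-hazard gene yields a strongly positive late-window summary
(198 of 599 cut-offs significant after FDR adjustment, summed log₂ HR
normalised to cohort size = +0.86) and an exactly zero early-window
summary; the null gene is zero in both windows. Dichotomising the cohort at
the optimal stratification point splits median distant-metastasis-free
survival 100 vs 56 months.

The full chain (`examples/07_full_pipeline.py`, or `qsig run --outdir out/`)
prints, for a scaled synthetic study, the number of DE calls, enriched
sets, the network Z statistic and the selection table, and reports how many
planted signature genes were recovered end-to-end.

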