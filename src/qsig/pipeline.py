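"""End-to-end orchestration: simulate -> DE -> GSEA -> network -> survival
-> select -> score, with one config, per-stage outputs and a hash manifest.

Every stochastic stage derives its seed from the single config seed, so a
rerun with an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dge, enrichment, netfunc, select, sigscore, simdata, survmodel

__all__ = ["PipelineConfig", "CohortSpec", "run_pipeline"]

log = logging.getLogger("qsig")


@dataclass
class CohortSpec:
    name: str = "CB_A"
    n_patients: int = 250
    er_fraction: float = 0.65
    beta_early: float = 0.0
    beta_late: float = 0.8
    censor_rate: float = 0.25
    landmark: float = 60.0


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the analysis defaults.

    theta/alpha are the DE fold-change threshold (log2) and FDR cut-off;
    landmark is the early/late boundary in months; percentile the
    high-centrality designation cut-off; min_leading_edges the multiplicity
    needed for the functional arm of selection.
    """

    seed: int = 1
    # stage toggles
    run_network: bool = True
    run_survival: bool = True
    run_score: bool = True
    # simulate
    n_genes: int = 2000
    de_fraction: float = 0.0635
    lfc_magnitude: float = 2.5
    dispersion: float = 0.1
    n_celllines: int = 4
    n_reps: int = 3
    n_signature_genes: int = 20
    n_gene_sets: int = 30
    planted_sets: int = 8
    set_size_range: tuple[int, int] = (15, 80)
    network_nodes: int = 60
    network_communities: int = 4
    p_in: float = 0.35
    p_out: float = 0.02
    overlap_fraction: float = 0.5
    cohorts: list[CohortSpec] = field(default_factory=lambda: [
        CohortSpec(name="CB_A"), CohortSpec(name="CB_B", n_patients=220)])
    gene_loading: float = 0.7
    # dge
    theta: float = 1.5
    alpha: float = 0.05
    k_cpm: float | None = None
    min_samples: int | None = None
    # gsea
    n_perm: int = 1000
    min_set_size: int = 5
    max_set_size: int = 500
    # network analysis
    n_rounds: int = 10000
    swaps_per_round: int | None = None
    min_community_size: int = 3
    centrality_percentile: float = 75.0
    # survival
    landmark: float = 60.0
    min_group: int = 1
    covariate: str | None = "er_status"
    # select
    min_leading_edges: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohorts = [CohortSpec(**c) for c in raw.pop("cohorts", [])] or None
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cohorts:
            cfg.cohorts = cohorts
        if isinstance(cfg.set_size_range, list):
            cfg.set_size_range = tuple(cfg.set_size_range)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["set_size_range"] = list(self.set_size_range)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all enabled stages in dependency order.

    Writes per-stage TSV/CSV/JSON outputs plus ``manifest.json`` (config,
    seeds, sha256 of every output) under ``outdir`` and returns the
    in-memory results dict (counts, de, gsea, evidence, selection, ...).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    results: dict = {}
    files: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t" if name.endswith(".tsv") else ",", **kw)
        files.append(path)
        return path

    def save_json(obj, name: str):
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        files.append(path)
        return path

    # ---- simulate ---------------------------------------------------------
    log.info("stage simulate: %d genes, %d cohorts", cfg.n_genes, len(cfg.cohorts))
    counts, count_truth = simdata.simulate_counts(
        n_genes=cfg.n_genes, de_fraction=cfg.de_fraction,
        lfc_magnitude=cfg.lfc_magnitude, dispersion=cfg.dispersion,
        n_celllines=cfg.n_celllines, n_reps=cfg.n_reps, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    de_true = list(count_truth.de_genes)
    # the planted signature is drawn from the up-regulated genes so planted
    # gene sets are directionally coherent (mixed-sign sets cancel in the
    # signed running sum, as they would in a real preranked analysis)
    de_up = [g for g in de_true if count_truth.log2_fc[g] > 0]
    n_sig = min(cfg.n_signature_genes, len(de_up))
    signature_truth = sorted(rng.choice(de_up, size=n_sig, replace=False).tolist())

    collection = simdata.simulate_genesets(
        universe=list(counts.index), n_sets=cfg.n_gene_sets,
        set_size_range=cfg.set_size_range, planted_sets=cfg.planted_sets,
        seed=cfg.seed + 1, signal_genes=signature_truth)

    other_de = [g for g in de_true if g not in set(signature_truth)]
    fill = [g for g in counts.index if g not in set(de_true)]
    net_nodes = (signature_truth + other_de + fill)[: cfg.network_nodes]
    edges_a, edges_b, net_truth = simdata.simulate_network(
        n_nodes=len(net_nodes), communities=cfg.network_communities,
        p_in=cfg.p_in, p_out=cfg.p_out, overlap_fraction=cfg.overlap_fraction,
        seed=cfg.seed + 2, node_ids=net_nodes)

    cohorts: dict[str, pd.DataFrame] = {}
    for i, spec in enumerate(cfg.cohorts):
        cohort, _ = simdata.simulate_cohort(
            n_patients=spec.n_patients, er_fraction=spec.er_fraction,
            beta_early=spec.beta_early, beta_late=spec.beta_late,
            landmark=spec.landmark, censor_rate=spec.censor_rate,
            seed=cfg.seed + 10 + i, genes=de_true,
            prognostic_genes=signature_truth, gene_loading=cfg.gene_loading)
        cohorts[spec.name] = cohort
        save_df(cohort, f"cohort_{spec.name}.csv", index=False)

    save_df(counts, "counts.tsv")
    save_df(count_truth.sample_meta, "sample_meta.tsv")
    enrichment.write_gmt(collection, out / "genesets.gmt")
    files.append(out / "genesets.gmt")
    netfunc.write_edge_list(edges_a, out / "edges_a.tsv")
    netfunc.write_edge_list(edges_b, out / "edges_b.tsv")
    files += [out / "edges_a.tsv", out / "edges_b.tsv"]
    save_json({"signature_truth": signature_truth, "de_truth": de_true},
              "truth.json")
    results.update(counts=counts, count_truth=count_truth,
                   signature_truth=signature_truth, collection=collection,
                   cohorts=cohorts, network_truth=net_truth)

    # ---- differential expression -----------------------------------------
    log.info("stage dge")
    min_samples = cfg.min_samples if cfg.min_samples is not None else cfg.n_reps
    filtered = dge.filter_low_expression(counts, k_cpm=cfg.k_cpm,
                                         n_samples=min_samples)
    factors = dge.tmm_norm_factors(filtered)
    meta = count_truth.sample_meta
    cells = meta["cell_line"].astype(str) + ":" + meta["group"].astype(str)
    disp = dge.estimate_dispersions(filtered, cells, factors)
    de_res = dge.test_de_threshold(filtered, meta, dispersions=disp,
                                   theta=cfg.theta, alpha=cfg.alpha,
                                   norm_factors=factors)
    # unthresholded test: continuous evidence ranking for enrichment
    de_rank = dge.test_de_threshold(filtered, meta, dispersions=disp,
                                    theta=0.0, alpha=cfg.alpha,
                                    norm_factors=factors)
    save_df(de_res, "de.tsv")
    save_df(de_rank, "de_unthresholded.tsv")
    called = de_res.index[de_res["direction"] != "ns"]
    results.update(de=de_res, de_rank=de_rank, de_called=list(called),
                   norm_factors=factors, dispersions=disp)
    log.info("  %d/%d genes called DE", len(called), len(de_res))

    # ---- enrichment -------------------------------------------------------
    log.info("stage gsea: %d sets, %d permutations", len(collection), cfg.n_perm)
    ranked = enrichment.rank_genes(de_rank, mode="signed_logp")
    gsea_res = enrichment.gsea(ranked, collection, n_perm=cfg.n_perm,
                               min_size=cfg.min_set_size,
                               max_size=cfg.max_set_size, seed=cfg.seed + 20,
                               alpha=cfg.alpha)
    leading = enrichment.leading_edge_multiplicity(
        gsea_res, min_sets=1, alpha=cfg.alpha)  # keep all counts; arm applies >= min later
    gsea_out = gsea_res.copy()
    gsea_out["leading_edge"] = gsea_out["leading_edge"].map(",".join)
    save_df(gsea_out, "gsea.tsv")
    save_df(leading.to_frame(), "leading_edges.tsv")
    results.update(ranked=ranked, gsea=gsea_res, leading_counts=leading)

    # ---- network ----------------------------------------------------------
    if cfg.run_network:
        log.info("stage network: %d rewiring rounds", cfg.n_rounds)
        graph = netfunc.build_composite([edges_a, edges_b])
        cent = netfunc.centralities(graph)
        cent = netfunc.combined_centrality(cent,
                                           percentile=cfg.centrality_percentile)
        null = netfunc.rewire_null(graph, n_rounds=cfg.n_rounds,
                                   swaps_per_round=cfg.swaps_per_round,
                                   seed=cfg.seed + 30)
        comms = netfunc.detect_communities(graph,
                                           min_size=cfg.min_community_size,
                                           seed=cfg.seed + 31)
        high = set(cent.index[cent["designation"] == "high"])
        uni = set(called) | set(graph.nodes())
        le_genes = set(leading[leading >= cfg.min_leading_edges].index) & uni
        ov_k, ov_p = netfunc.overlap_test(le_genes, high, uni)
        save_df(cent, "centrality.tsv")
        save_json({"clustering_observed": null.observed_clustering,
                   "null_mean": null.null_mean, "null_sd": null.null_sd,
                   "z": null.z, "p": null.p,
                   "n_communities": len(comms),
                   "overlap_leading_vs_central": ov_k,
                   "overlap_fisher_p": ov_p}, "network_stats.json")
        save_json([sorted(c) for c in comms], "communities.json")
        results.update(graph=graph, centrality=cent, rewire=null,
                       communities=comms, overlap=(ov_k, ov_p))
    else:
        cent = pd.DataFrame(columns=["combined_score", "designation"])
        results.update(centrality=cent)

    # ---- survival ---------------------------------------------------------
    hazard_summaries: dict[str, pd.DataFrame] = {}
    if cfg.run_survival:
        scan_genes = [g for g in called if g in next(iter(cohorts.values())).columns]
        log.info("stage survival: %d genes x %d cohorts", len(scan_genes),
                 len(cohorts))
        for name, cohort in cohorts.items():
            rows = []
            for g in scan_genes:
                summ = survmodel.gene_hazard_summary(
                    cohort, g, landmark=cfg.landmark, alpha=cfg.alpha,
                    covariate=cfg.covariate, min_group=cfg.min_group)
                rows.append((g, summ.early_summary, summ.late_summary,
                             summ.n_sig_early, summ.n_sig_late))
            df = pd.DataFrame(rows, columns=["gene", "early_summary",
                                             "late_summary", "n_sig_early",
                                             "n_sig_late"]).set_index("gene")
            hazard_summaries[name] = df
            save_df(df, f"hazard_{name}.tsv")
        stats = {}
        first = next(iter(hazard_summaries.values()))
        if len(first) >= 2:
            w, p = survmodel.compare_early_late(first["late_summary"],
                                                first["early_summary"])
            stats["late_vs_early_wilcoxon_p"] = p
            stats["late_vs_early_statistic"] = w
        save_json(stats, "survival_stats.json")
        results.update(hazard_summaries=hazard_summaries)

    # ---- select -----------------------------------------------------------
    if hazard_summaries:
        log.info("stage select")
        evidence = select.build_evidence(de_res, leading, cent,
                                         hazard_summaries, alpha=cfg.alpha)
        selection = select.select_signature(
            evidence, min_leading_edges=cfg.min_leading_edges)
        save_df(select.report_table(evidence), "evidence.tsv")
        save_df(select.report_table(selection), "selection.tsv")
    else:
        # no prognostic evidence: selection is undefined, not empty-by-merit
        log.info("stage select skipped (survival stage disabled)")
        evidence = pd.DataFrame()
        selection = pd.DataFrame()
    signature = (select.selection_to_signature(selection)
                 if len(selection) else None)
    if signature is not None:
        signature.to_json(out / "signature.json")
        files.append(out / "signature.json")
    results.update(evidence=evidence, selection=selection, signature=signature)
    log.info("  %d genes selected", len(selection))

    # ---- score ------------------------------------------------------------
    if cfg.run_score and signature is not None and cfg.run_survival:
        name, cohort = next(iter(cohorts.items()))
        expr = cohort.set_index("id")[
            [g for g in de_true if g in cohort.columns]].T
        try:
            scores = sigscore.signature_score(expr, signature)
            cohort_scored = cohort.set_index("id").assign(
                signature_score=scores["score"])
            w, p = sigscore.score_vs_group(
                cohort_scored["signature_score"],
                cohort_scored["er_status"].to_numpy())
            labels, km, lr, _ = survmodel.dichotomize_optimal(
                cohort_scored.reset_index(), "signature_score",
                min_group=max(cfg.min_group, 10))
            save_df(scores, "signature_scores.csv")
            save_json({"cohort": name, "er_rank_sum_p": p,
                       "km_median_low": km["low"].median,
                       "km_median_high": km["high"].median,
                       "logrank_p": lr[1]}, "score_stats.json")
            results.update(scores=scores, score_er_p=p, score_km=km,
                           score_logrank=lr)
        except ValueError as err:
            log.warning("score stage skipped: %s", err)

    manifest = {
        "config": cfg.to_dict(),
        "outputs": {f.name: _sha256(f) for f in sorted(set(files))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    results["manifest"] = manifest
    return results
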