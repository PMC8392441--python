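"""Preranked gene-set enrichment with permutation-normalised scores.

Implements the weighted Kolmogorov-Smirnov running-sum statistic on a signed
ranked gene list, gene-label permutation null, NES normalisation by the mean
same-sign permutation score, BH adjustment across sets, and leading-edge
multiplicity counting (how many significantly enriched sets share a gene in
their leading edge), which is one of the three evidence arms of the final
signature selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dge import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "leading_edge_multiplicity",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name <tab> description <tab> members...)."""
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {i}: need name, description, members")
            collection[parts[0]] = [g for g in parts[2:] if g]
    return collection


def write_gmt(collection: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def rank_genes(de_result: pd.DataFrame, mode: str = "signed_logp") -> pd.Series:
    """Signed per-gene ranking statistic from a DE table, sorted descending.

    mode "signed_logp": sign(log2FC) * -log10(p) (direction from the
    fold-change, evidence from the p-value); mode "lfc": the log2
    fold-change itself.  Ties are broken by gene id for determinism.
    """
    if de_result.index.has_duplicates:
        dup = de_result.index[de_result.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    if mode == "signed_logp":
        p = np.clip(de_result["PValue"].to_numpy(float), 1e-300, 1.0)
        stat = np.sign(de_result["log2FC"].to_numpy(float)) * (-np.log10(p))
    elif mode == "lfc":
        stat = de_result["log2FC"].to_numpy(float)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite ranking statistics")
    s = pd.Series(stat, index=de_result.index, name="stat")
    order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
    return s.iloc[order]


def _es_at_hits(hit_pos: np.ndarray, hit_w: np.ndarray, n_total: int):
    """Running-sum extremum evaluated only where it can occur (O(k)).

    ``hit_pos`` are sorted 0-based ranks of the set members, ``hit_w`` their
    |stat|**p weights.  The running sum increases by w/A at a hit and
    decreases by 1/(N-k) per miss; its maximum is attained immediately after
    a hit and its minimum immediately before one (or at the end).
    Returns (ES, extremum_rank, at_max) where extremum_rank is the 0-based
    rank position of the extremum.
    """
    k = len(hit_pos)
    n_miss = n_total - k
    if n_miss == 0:
        raise ValueError("gene set equals the full universe; miss penalty undefined")
    A = hit_w.sum()
    if A <= 0:
        # all weights zero (e.g. weight_p applied to zero stats): equal steps
        hit_w = np.ones(k)
        A = float(k)
    cum = np.cumsum(hit_w) / A
    j = np.arange(1, k + 1)
    dec = 1.0 / n_miss
    after_hit = cum - (hit_pos + 1 - j) * dec          # value just after hit j
    before_hit = cum - hit_w / A - (hit_pos - (j - 1)) * dec  # just before hit j
    i_max = int(np.argmax(after_hit))
    i_min = int(np.argmin(before_hit))
    top, bottom = after_hit[i_max], min(before_hit[i_min], 0.0)
    if top >= -bottom:
        return float(top), int(hit_pos[i_max]), True
    if bottom == 0.0:
        return 0.0, int(hit_pos[i_max]), True
    return float(bottom), int(hit_pos[i_min]), False


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0):
    """Weighted KS enrichment score of one gene set on a ranked list.

    Returns (ES, running_sum, leading_edge): the signed extremum of the
    running sum, the full running-sum trajectory (value after each rank),
    and the leading-edge genes — hit genes at or before the maximum for a
    positive ES, at or after the minimum for a negative ES.
    """
    genes = ranked.index
    in_set = genes.isin(set(gene_set))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    n = len(genes)
    stats = ranked.to_numpy(float)
    w = np.abs(stats) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    A = hit_w.sum()
    if A <= 0:
        hit_w = in_set.astype(float)
        A = float(k)
    if n == k:
        raise ValueError("gene set equals the full universe; miss penalty undefined")
    steps = np.where(in_set, hit_w / A, -1.0 / (n - k))
    running = np.cumsum(steps)

    es, pos, at_max = _es_at_hits(np.flatnonzero(in_set),
                                  np.where(in_set, w, 0.0)[in_set], n)
    if at_max:
        leading = genes[(np.arange(n) <= pos) & in_set].tolist()
    else:
        leading = genes[(np.arange(n) >= pos) & in_set].tolist()
    return es, running, leading


def gsea(ranked: pd.Series, collection: dict[str, list[str]],
         n_perm: int = 1000, min_size: int = 5, max_size: int = 500,
         seed: int = 0, weight_p: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Preranked GSEA over a collection with a gene-label permutation null.

    For each set (after intersecting with the ranked universe and size
    filtering), ``n_perm`` random same-size gene sets give the null ES
    distribution; NES = ES / mean(|ES_perm| of the same sign) and the
    p-value is the one-sided same-sign permutation tail with +1 continuity.
    BH adjustment across sets.  Deterministic given ``seed``.

    Returns a frame indexed by set name: ES, NES, pval, padj, size,
    leading_edge (list), significant (padj <= alpha).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = set(ranked.index)
    n = len(ranked)
    stats = ranked.to_numpy(float)
    w_all = np.abs(stats) ** weight_p

    sets = {}
    for name, members in collection.items():
        inter = [g for g in members if g in universe]
        if min_size <= len(inter) <= min(max_size, n - 1):
            sets[name] = inter
    if not sets:
        raise ValueError("no gene sets left after size filtering")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for name, members in sets.items():
        es, _, leading = enrichment_score(ranked, members, weight_p)
        k = len(members)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pos = np.sort(rng.choice(n, size=k, replace=False))
            perm_es[b], _, _ = _es_at_hits(pos, w_all[pos], n)
        same = perm_es > 0 if es >= 0 else perm_es < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes, p = np.nan, 1.0
        else:
            nes = es / np.abs(perm_es[same]).mean()
            p = (1.0 + np.sum(np.abs(perm_es[same]) >= abs(es))) / (1.0 + n_same)
        rows.append((name, es, nes, p, k, leading))

    res = pd.DataFrame(rows, columns=["set", "ES", "NES", "pval", "size",
                                      "leading_edge"]).set_index("set")
    res["padj"] = bh_adjust(res["pval"].to_numpy())
    res["significant"] = res["padj"] <= alpha
    return res


def leading_edge_multiplicity(results: pd.DataFrame, min_sets: int = 2,
                              alpha: float = 0.05) -> pd.Series:
    """Per-gene count of significantly enriched sets sharing it in their
    leading edge; genes with count >= ``min_sets`` are returned.

    ``results`` is a :func:`gsea` output frame (needs padj and leading_edge).
    """
    counts: dict[str, int] = {}
    sig = results[results["padj"] <= alpha]
    for edge in sig["leading_edge"]:
        for g in edge:
            counts[g] = counts.get(g, 0) + 1
    out = pd.Series(counts, dtype=int, name="leading_edges").sort_index()
    return out[out >= min_sets]
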