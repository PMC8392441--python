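"""Intersection of the three evidence streams into the final gene signature.

A gene enters the signature when it has *functional* evidence — membership
in the leading edge of at least ``min_leading_edges`` significantly enriched
gene sets OR a high combined-centrality designation in the interaction
network — AND *prognostic* evidence: a significant association with late
metastatic recurrence (at least one significant late-window cutpoint) in at
least one survival cohort.  The functional arm is a disjunction: published
quiescence-signature genes include both high-centrality genes with no
leading-edge membership and multi-leading-edge genes with low centrality, so
a conjunction would be inconsistent with the evidence the selection must
reproduce.

The package ships the published 22-gene breast-cancer quiescence signature's
evidence table (:func:`load_reference_evidence`) for validation and reuse.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .sigscore import SignatureDefinition

__all__ = [
    "build_evidence",
    "select_signature",
    "report_table",
    "selection_to_signature",
    "load_reference_evidence",
]

EVIDENCE_COLUMNS = ["log2FC", "q_value", "leading_edges", "centrality_score",
                    "designation"]


def load_reference_evidence() -> pd.DataFrame:
    """Evidence table of the published 22-gene quiescence signature.

    Columns mirror a selection report: per-gene DE log2 fold-change and
    q-value, leading-edge multiplicity over the MSigDB hallmark collection,
    combined centrality score and high/low designation, and the survival
    cohorts (CB572/CB482 composites) in which the gene was significantly
    associated with late metastatic recurrence.
    """
    ref = resources.files("qsig").joinpath("data/quiescence22_evidence.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="gene")
    for cohort in ("CB572", "CB482"):
        df[f"sig_{cohort}"] = df["cohorts"].str.contains(cohort)
    return df.drop(columns=["cohorts"])


def build_evidence(de_result: pd.DataFrame, leading_counts: pd.Series,
                   centrality_table: pd.DataFrame,
                   hazard_summaries: dict[str, pd.DataFrame],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Outer-join the per-gene outputs of the upstream stages.

    ``de_result`` is a DE table (log2FC, FDR) indexed by gene;
    ``leading_counts`` maps gene -> leading-edge multiplicity;
    ``centrality_table`` has combined_score and designation per network
    node; ``hazard_summaries`` maps cohort name -> frame indexed by gene
    with late-window columns (late_summary, n_sig_late).

    Genes absent from the network get designation "absent" (which never
    satisfies the centrality arm); missing multiplicities are 0; the
    per-cohort significance flag is n_sig_late >= 1.
    """
    genes = de_result.index
    genes = genes.union(leading_counts.index).union(centrality_table.index)
    for df in hazard_summaries.values():
        genes = genes.union(df.index)
    if len(genes) == 0:
        raise ValueError("no genes in any evidence input")
    genes = genes.sort_values()

    ev = pd.DataFrame(index=pd.Index(genes, name="gene"))
    ev["log2FC"] = de_result["log2FC"].reindex(genes)
    ev["q_value"] = de_result["FDR"].reindex(genes)
    ev["leading_edges"] = leading_counts.reindex(genes).fillna(0).astype(int)
    if "combined_score" in centrality_table.columns:
        ev["centrality_score"] = centrality_table["combined_score"].reindex(genes)
    else:
        ev["centrality_score"] = np.nan
    desig = centrality_table.get("designation")
    if desig is not None:
        ev["designation"] = desig.reindex(genes).fillna("absent")
    else:
        ev["designation"] = "absent"
    for cohort, df in hazard_summaries.items():
        n_sig = df["n_sig_late"].reindex(genes).fillna(0)
        ev[f"sig_{cohort}"] = n_sig >= 1
        ev[f"late_summary_{cohort}"] = df["late_summary"].reindex(genes)
    return ev


def _predicate(ev: pd.DataFrame, min_leading_edges: int) -> pd.Series:
    flag_cols = [c for c in ev.columns if c.startswith("sig_")]
    if not flag_cols:
        raise ValueError("evidence table has no per-cohort sig_* flag columns")
    functional = (ev["leading_edges"] >= min_leading_edges) | \
        (ev["designation"].astype(str).str.lower() == "high")
    prognostic = ev[flag_cols].any(axis=1)
    return functional & prognostic


def select_signature(evidence: pd.DataFrame,
                     min_leading_edges: int = 2) -> pd.DataFrame:
    """Apply the selection predicate; return selected rows ordered by symbol.

    selected <=> (leading-edge multiplicity >= min_leading_edges OR
    centrality designation == high) AND significant late-recurrence
    association in >= 1 cohort.
    """
    if evidence.index.has_duplicates:
        dup = evidence.index[evidence.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids: {dup[:5]}")
    keep = _predicate(evidence, min_leading_edges)
    return evidence.loc[keep].sort_index()


def report_table(selection: pd.DataFrame) -> pd.DataFrame:
    """Selection report with canonical column order (TSV-ready).

    Columns: gene symbol index, log2FC, q_value, leading_edges,
    centrality_score, designation, then the per-cohort significance flags.
    An empty selection yields the header-only frame.
    """
    flag_cols = sorted(c for c in selection.columns if c.startswith("sig_"))
    cols = [c for c in EVIDENCE_COLUMNS if c in selection.columns] + flag_cols
    return selection[cols].copy()


def selection_to_signature(selection: pd.DataFrame,
                           provenance: str = "qsig selection") -> SignatureDefinition:
    """Convert a selection table into up/down lists by DE direction."""
    lfc = selection["log2FC"].fillna(0.0)
    up = sorted(selection.index[lfc >= 0])
    down = sorted(selection.index[lfc < 0])
    return SignatureDefinition(up=up, down=down, provenance=provenance)
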