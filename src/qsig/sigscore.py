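"""Integrated signature scoring over expression cohorts.

The signature score of a sample is the difference between the mean
log2-normalised expression of the up-regulated genes and that of the
down-regulated genes (the log-domain equivalent of a ratio of geometric
means), z-standardised across the cohort.  Also provides per-dataset
standardisation plumbing for merging cohorts and small rank-statistics
utilities (Spearman correlation, rank-sum group comparison).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .survmodel import compare_early_late

__all__ = [
    "SignatureDefinition",
    "signature_score",
    "standardize_datasets",
    "spearman_corr",
    "score_vs_group",
]


@dataclass
class SignatureDefinition:
    """Up/down gene lists defining a signature."""

    up: list[str]
    down: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene lists must be disjoint")
        if not self.up and not self.down:
            raise ValueError("signature must contain at least one gene")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"up": list(self.up), "down": list(self.down),
                       "provenance": self.provenance}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignatureDefinition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(up=d["up"], down=d.get("down", []),
                   provenance=d.get("provenance", ""))


def signature_score(expression: pd.DataFrame, signature: SignatureDefinition,
                    max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Integrated signature score per sample.

    ``expression`` is genes x samples, already normalised and
    log2-transformed.  raw = mean over up genes - mean over down genes (an
    empty down list gives raw = up-mean); the standardized column is the
    z-score of raw across samples.  Signature genes absent from the matrix
    are dropped with a warning; more than ``max_missing_fraction`` missing
    is an error.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sig_genes = list(signature.up) + list(signature.down)
    present = [g for g in sig_genes if g in expression.index]
    missing = sorted(set(sig_genes) - set(present))
    if not present:
        raise ValueError(f"no signature genes present; missing: {missing}")
    if len(missing) / len(sig_genes) > max_missing_fraction:
        raise ValueError(
            f"{len(missing)}/{len(sig_genes)} signature genes missing: {missing}")
    if missing:
        warnings.warn(f"dropping {len(missing)} signature gene(s) absent "
                      f"from the matrix: {missing}", stacklevel=2)

    up = [g for g in signature.up if g in expression.index]
    down = [g for g in signature.down if g in expression.index]
    raw = np.zeros(expression.shape[1])
    if up:
        raw = raw + expression.loc[up].mean(axis=0).to_numpy(float)
    if down:
        raw = raw - expression.loc[down].mean(axis=0).to_numpy(float)
    sd = raw.std(ddof=0)
    if sd <= 0:
        raise ValueError("signature score has zero variance across samples")
    return pd.DataFrame({"raw": raw, "score": (raw - raw.mean()) / sd},
                        index=expression.columns)


def standardize_datasets(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-dataset gene standardisation, then concatenation on shared genes.

    Each matrix (genes x samples) is restricted to the gene intersection,
    mean-centred and unit-scaled per gene within its dataset, and the
    columns concatenated.  Genes constant within a dataset get scale 1 to
    avoid division by zero.  This is deliberately simple plumbing for
    removing dataset-level location/scale shifts before merged analyses.
    """
    if not matrices:
        raise ValueError("no datasets supplied")
    genes: pd.Index | None = None
    for df in matrices.values():
        genes = df.index if genes is None else genes.intersection(df.index)
    if genes is None or len(genes) == 0:
        raise ValueError("empty gene intersection across datasets")
    genes = genes.sort_values()
    parts = []
    for name, df in matrices.items():
        sub = df.loc[genes].astype(float)
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
        z = sub.sub(mu, axis=0).div(sd, axis=0)
        z.columns = [f"{name}:{c}" if len(matrices) > 1 else c for c in z.columns]
        parts.append(z)
    return pd.concat(parts, axis=1)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; t-approx p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def score_vs_group(scores, grouping) -> tuple[float, float]:
    """Rank-sum comparison of scores between two groups.

    ``grouping`` is a binary labelling; returns the two-sided Wilcoxon
    rank-sum (statistic, p) for group-1 vs group-0 scores.
    """
    s = np.asarray(scores, float)
    g = np.asarray(grouping)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a = s[g == levels[1]]
    b = s[g == levels[0]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return compare_early_late(a, b)
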