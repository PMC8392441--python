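"""Differential expression between quiescent (DiD+) and proliferative (DiD-) cells.

The stage mirrors a standard bulk RNA-seq workflow: CPM filtering of lowly
expressed genes, trimmed-mean-of-M-values (TMM) library-size normalisation,
negative-binomial dispersion estimation (common, trended and tagwise with
empirical-Bayes shrinkage), and a per-gene NB GLM with a fold-change-threshold
Wald test (TREAT-style): a gene is called up-regulated only when its log2
fold-change is significantly *above* +theta (down: below -theta) at a BH FDR
cut-off, not merely significantly non-zero.

The NB model uses the var = mu + phi*mu^2 parameterisation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.special import gammaln
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DispersionEstimates",
    "ClusterResult",
    "read_counts",
    "compute_cpm",
    "filter_low_expression",
    "tmm_norm_factors",
    "estimate_dispersions",
    "test_de_threshold",
    "cluster_samples",
    "bh_adjust",
]


def read_counts(path) -> pd.DataFrame:
    """Read a genes-x-samples count TSV (first column = gene ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# CPM and filtering


def compute_cpm(counts: pd.DataFrame, norm_factors: pd.Series | None = None,
                log2: bool = False, prior_count: float = 0.5) -> pd.DataFrame:
    """Counts per million over effective library sizes.

    cpm[g, s] = counts[g, s] / (libsize_s * factor_s) * 1e6.  With
    ``log2=True`` returns log2(cpm + prior-count-adjusted offset) in the
    conventional way: log2((count + prior) / (efflib + 2*prior) * 1e6).
    """
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if norm_factors is None:
        eff = lib
    else:
        eff = lib * norm_factors.reindex(counts.columns).astype(float)
    if log2:
        return np.log2((counts + prior_count).div(eff + 2 * prior_count, axis=1) * 1e6)
    return counts.div(eff, axis=1) * 1e6


def filter_low_expression(counts: pd.DataFrame, k_cpm: float | None = None,
                          n_samples: int | None = None,
                          norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Keep genes with CPM > ``k_cpm`` in at least ``n_samples`` samples.

    Defaults follow common practice: k_cpm = 10 / median library size in
    millions (roughly 10 raw counts in a typical sample) and n_samples = the
    smallest plausible group size (here: total samples // 2, capped at the
    sample count), which callers with a real design should override with the
    smallest group size.  Row order is preserved.
    """
    if k_cpm is None:
        med_lib_millions = counts.sum(axis=0).median() / 1e6
        k_cpm = 10.0 / max(med_lib_millions, 1e-9)
    if k_cpm < 0:
        raise ValueError("k_cpm must be >= 0")
    total = counts.shape[1]
    if n_samples is None:
        n_samples = max(1, total // 2)
    if not 1 <= n_samples <= total:
        raise ValueError(f"n_samples must lie in [1, {total}], got {n_samples}")
    cpm = compute_cpm(counts, norm_factors)
    keep = (cpm > k_cpm).sum(axis=1) >= n_samples
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TMM normalisation


def tmm_norm_factors(counts: pd.DataFrame, trim_M: float = 0.30,
                     trim_A: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values normalisation factors.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper-quartile.  For each sample, genes expressed in both sample and
    reference contribute a log-ratio M and log-abundance A; after trimming
    ``trim_M`` of the M distribution and ``trim_A`` of the A distribution
    (both tails each), the factor is 2**(precision-weighted mean M), with
    weights from the asymptotic (delta-method) binomial variances.  Factors
    are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")

    y = counts.to_numpy(dtype=float)
    lib_v = lib.to_numpy()
    cpm = y / lib_v[None, :] * 1e6
    uq = np.array([np.quantile(cpm[cpm[:, j] > 0, j] if (cpm[:, j] > 0).any()
                               else cpm[:, j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            factors[j] = 1.0
            continue
        factors[j] = 2.0 ** _tmm_pair(y[:, j], lib_v[j], y[:, ref], lib_v[ref],
                                      trim_M, trim_A)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _tmm_pair(obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
              trim_M: float, trim_A: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 0.0
    po, pr = obs[ok] / n_obs, ref[ok] / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])

    if np.allclose(M, M[0], atol=1e-10):
        return float(M[0])

    n = len(M)
    lo_M, hi_M = np.floor(n * trim_M) + 1, n - np.floor(n * trim_M)
    lo_A, hi_A = np.floor(n * trim_A) + 1, n - np.floor(n * trim_A)
    rank_M = pd.Series(M).rank().to_numpy()
    rank_A = pd.Series(A).rank().to_numpy()
    keep = (rank_M >= lo_M) & (rank_M <= hi_M) & (rank_A >= lo_A) & (rank_A <= hi_A)
    if not keep.any():
        keep = np.ones(n, dtype=bool)
    inv_w = 1.0 / w[keep]
    return float(np.sum(M[keep] * inv_w) / np.sum(inv_w))


# ---------------------------------------------------------------------------
# Dispersion estimation

_LOG_PHI_GRID = np.linspace(np.log(1e-4), np.log(10.0), 61)


@dataclass
class DispersionEstimates:
    common: float
    trended: pd.Series   # per gene
    tagwise: pd.Series   # per gene
    prior_weight: float


def _cell_offsets(counts: pd.DataFrame, groups: pd.Series,
                  norm_factors: pd.Series | None):
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns).astype(float)
    offsets = np.log(lib.to_numpy())
    labels = groups.reindex(counts.columns)
    cells = [np.flatnonzero((labels == lv).to_numpy()) for lv in labels.unique()]
    return offsets, cells


def _cell_profile(y: np.ndarray, off: np.ndarray, phi: float):
    """Profile out the cell mean at fixed dispersion; return (ll, fisher_info).

    One log-link Newton solve of the score equation sum (y-mu)/(1+phi*mu)=0
    per gene, vectorised across genes.  Returns per-gene NB log-likelihood at
    the profiled mean and the Fisher information of the mean parameter (used
    for the Cox-Reid adjustment).
    """
    tot = y.sum(axis=1)
    denom = np.exp(off).sum()
    beta = np.log(np.maximum(tot, 0.5) / denom)
    for _ in range(12):
        mu = np.exp(beta[:, None] + off[None, :])
        score = ((y - mu) / (1.0 + phi * mu)).sum(axis=1)
        hess = (mu * (1.0 + phi * y) / (1.0 + phi * mu) ** 2).sum(axis=1)
        step = score / np.maximum(hess, 1e-12)
        beta = beta + np.clip(step, -5.0, 5.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(beta[:, None] + off[None, :])
    r = 1.0 / phi
    ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
          + y * np.log(phi * mu) - (y + r) * np.log1p(phi * mu)).sum(axis=1)
    info = (mu / (1.0 + phi * mu)).sum(axis=1)
    return ll, info


def _apl_matrix(y: np.ndarray, offsets: np.ndarray, cells: list[np.ndarray],
                log_grid: np.ndarray) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood, genes x grid points."""
    apl = np.zeros((y.shape[0], len(log_grid)))
    for k, lphi in enumerate(log_grid):
        phi = float(np.exp(lphi))
        for idx in cells:
            ll, info = _cell_profile(y[:, idx], offsets[idx], phi)
            apl[:, k] += ll - 0.5 * np.log(np.maximum(info, 1e-12))
    return apl


def _parabolic_argmax(xs: np.ndarray, fs: np.ndarray) -> float:
    """Vertex of the parabola through the argmax and its grid neighbours."""
    k = int(np.argmax(fs))
    if k == 0 or k == len(xs) - 1:
        return float(xs[k])
    x0, x1, x2 = xs[k - 1], xs[k], xs[k + 1]
    f0, f1, f2 = fs[k - 1], fs[k], fs[k + 1]
    denom = (f0 - 2 * f1 + f2)
    if denom >= 0 or abs(denom) < 1e-300:
        return float(x1)
    return float(x1 - 0.5 * (x2 - x1) * (f2 - f0) / denom)


def estimate_dispersions(counts: pd.DataFrame, groups: pd.Series,
                         norm_factors: pd.Series | None = None,
                         prior_weight: float = 10.0,
                         n_bins: int = 20) -> DispersionEstimates:
    """Common, trended and tagwise NB dispersions.

    ``groups`` assigns each sample to an experimental cell (e.g. the
    cell-line x DiD-group combination); means are profiled out per cell with
    a Cox-Reid adjustment, following the adjusted-profile-likelihood approach
    of weighted-likelihood empirical Bayes estimators:

    * common: maximises the summed adjusted profile likelihood (APL),
    * trended: per-gene grid MLEs locally averaged over ``n_bins`` abundance
      bins (log mean CPM),
    * tagwise: per-gene maximiser of APL_g(phi) - prior_weight/2 *
      (log phi - log trend_g)^2, i.e. shrinkage toward the trend with a
      normal prior on log phi of precision ``prior_weight``.  prior_weight ->
      infinity recovers the trend exactly.
    """
    labels = groups.reindex(counts.columns)
    sizes = labels.value_counts()
    if (sizes < 2).all():
        raise ValueError("no residual degrees of freedom: every group has < 2 samples")
    y = counts.to_numpy(dtype=float)
    offsets, cells = _cell_offsets(counts, labels, norm_factors)

    apl = _apl_matrix(y, offsets, cells, _LOG_PHI_GRID)
    common = float(np.exp(_parabolic_argmax(_LOG_PHI_GRID, apl.sum(axis=0))))

    # per-gene grid MLE then local averaging over abundance bins
    tag_mle_log = _LOG_PHI_GRID[np.argmax(apl, axis=1)]
    abundance = np.log2(compute_cpm(counts).mean(axis=1).to_numpy() + 0.5)
    order = np.argsort(abundance, kind="stable")
    n_genes = y.shape[0]
    bins = max(1, min(n_bins, n_genes))
    trend_log = np.empty(n_genes)
    for b, chunk in enumerate(np.array_split(order, bins)):
        trend_log[chunk] = tag_mle_log[chunk].mean()
    trended = np.exp(trend_log)

    penalty = -0.5 * prior_weight * (_LOG_PHI_GRID[None, :] - trend_log[:, None]) ** 2
    obj = apl + penalty
    tag_log = np.array([_parabolic_argmax(_LOG_PHI_GRID, obj[g]) for g in range(n_genes)])
    tagwise = np.exp(tag_log)

    return DispersionEstimates(
        common=common,
        trended=pd.Series(trended, index=counts.index, name="trended"),
        tagwise=pd.Series(tagwise, index=counts.index, name="tagwise"),
        prior_weight=prior_weight,
    )


# ---------------------------------------------------------------------------
# NB GLM and threshold test


def _design_matrix(meta: pd.DataFrame) -> tuple[np.ndarray, list[str], int]:
    """Intercept + DiD group indicator + cell-line blocking dummies."""
    groups = meta["group"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    # treatment level: the dye-retaining group when present, else the
    # lexicographically later level
    treat = next((lv for lv in levels if lv.endswith("+")), levels[-1])
    pos = groups == treat
    cols = [np.ones(len(meta)), pos.to_numpy(float)]
    names = ["intercept", f"group[{treat}]"]
    if "cell_line" in meta.columns:
        cl = meta["cell_line"].astype(str)
        for lv in sorted(cl.unique())[1:]:
            cols.append((cl == lv).to_numpy(float))
            names.append(f"cell_line[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design matrix; columns: {names}")
    return X, names, 1  # index of the group coefficient


def _nb_glm_batch(y: np.ndarray, X: np.ndarray, offsets: np.ndarray,
                  phi: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Batched NB GLM (log link) IRLS across genes sharing one design.

    Returns (beta (G,p), cov (G,p,p)) with Fisher-information covariance
    using weights mu/(1+phi*mu).
    """
    n_genes, n = y.shape
    p = X.shape[1]
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros((n_genes, p))
    for _ in range(max_iter):
        w = mu / (1.0 + phi[:, None] * mu)
        z = eta - offsets[None, :] + (y - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", X, w, X)
        xtwz = np.einsum("ni,gn,gn->gi", X, w, z)
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        eta = np.clip(beta @ X.T + offsets[None, :], -50.0, 50.0)
        mu = np.exp(eta)
        if delta.max() < tol:
            break
    w = mu / (1.0 + phi[:, None] * mu)
    xtwx = np.einsum("ni,gn,nj->gij", X, w, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(xtwx)
    return beta, cov


def test_de_threshold(counts: pd.DataFrame, meta: pd.DataFrame,
                      dispersions: DispersionEstimates | None = None,
                      theta: float = 1.5, alpha: float = 0.05,
                      norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Fold-change-threshold DE test (TREAT-style Wald test).

    Fits a per-gene NB GLM with intercept, DiD-group term and cell-line
    blocking factors (offsets = log effective library sizes, tagwise
    dispersions).  H0: |log2FC| <= theta is tested against the nearer
    threshold boundary with a Wald t statistic on the residual degrees of
    freedom; p = P(T > (|b|-theta)/se) + P(T > (|b|+theta)/se), which is the
    usual composite-null bound.  BH adjustment across genes; direction 'up'
    iff significantly above +theta, 'down' iff below -theta, else 'ns'.

    Returns a frame indexed by gene: log2FC, lfcSE, PValue, FDR, direction,
    dispersion.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    meta = meta.loc[counts.columns]
    if norm_factors is None:
        norm_factors = tmm_norm_factors(counts)
    if dispersions is None:
        cell = meta["group"].astype(str)
        if "cell_line" in meta.columns:
            cell = meta["cell_line"].astype(str) + ":" + cell
        dispersions = estimate_dispersions(counts, cell, norm_factors)

    X, names, group_idx = _design_matrix(meta)
    lib = counts.sum(axis=0).astype(float) * norm_factors.reindex(counts.columns)
    offsets = np.log(lib.to_numpy())
    y = counts.to_numpy(dtype=float)
    phi = dispersions.tagwise.reindex(counts.index).to_numpy()

    beta, cov = _nb_glm_batch(y, X, offsets, phi)
    b_ln = beta[:, group_idx]
    se_ln = np.sqrt(np.maximum(cov[:, group_idx, group_idx], 1e-300))
    lfc = b_ln / np.log(2.0)
    se = se_ln / np.log(2.0)

    df = counts.shape[1] - X.shape[1]
    if df < 1:
        raise ValueError("no residual degrees of freedom for the Wald test")
    t_near = (np.abs(lfc) - theta) / se
    t_far = (np.abs(lfc) + theta) / se
    pvals = t_dist.sf(t_near, df) + t_dist.sf(t_far, df)
    pvals = np.clip(pvals, 0.0, 1.0)

    res = pd.DataFrame(
        {"log2FC": lfc, "lfcSE": se, "PValue": pvals,
         "dispersion": phi}, index=counts.index)
    res = res.sort_index(kind="stable")  # deterministic BH tie handling
    res["FDR"] = bh_adjust(res["PValue"].to_numpy())
    sig = res["FDR"] <= alpha
    res["direction"] = np.where(sig & (res["log2FC"] > 0), "up",
                                np.where(sig & (res["log2FC"] < 0), "down", "ns"))
    res.attrs["theta"] = theta
    res.attrs["alpha"] = alpha
    res.attrs["design_columns"] = names
    res.attrs["common_dispersion"] = dispersions.common
    return res.loc[counts.index.sort_values()]


# ---------------------------------------------------------------------------
# Unsupervised structure


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray     # scipy hierarchical linkage (average, Euclidean)
    sample_ids: list[str]
    pca_scores: pd.DataFrame       # samples x components
    explained_variance_ratio: np.ndarray


def cluster_samples(log_cpm: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering + PCA of samples.

    Distances are Euclidean between sample columns of the (typically TMM
    normalised log2 CPM) expression matrix; PCA is on per-gene mean-centred
    values, scores returned for all components.
    """
    if log_cpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = log_cpm.to_numpy(dtype=float).T          # samples x genes
    Z = linkage(pdist(mat, metric="euclidean"), method="average")
    centred = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u * s[None, :]
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    k = scores.shape[1]
    return ClusterResult(
        linkage_matrix=Z,
        sample_ids=list(log_cpm.columns),
        pca_scores=pd.DataFrame(scores, index=log_cpm.columns,
                                columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=evr,
    )
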