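"""Survival machinery for recurrence analysis.

Kaplan-Meier estimation and log-rank testing (via lifelines), an in-house Cox
proportional-hazards fitter (Newton-Raphson on the Efron-tie-corrected
partial likelihood, vectorised so that thousands of fits are cheap),
exhaustive cutpoint scanning — every one of the n-1 rank stratification
points of a score enters a Cox model and the best FDR-adjusted p wins — and
the per-gene early/late hazard summary: the summed log2 hazard ratio of all
significant cutpoints, normalised to cohort size, computed separately for
recurrence before the landmark (follow-up administratively censored at the
landmark) and after it (landmark risk-set conditioning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import mannwhitneyu, norm

from .dge import bh_adjust

__all__ = [
    "CoxResult",
    "KMResult",
    "CutpointScan",
    "GeneHazardSummary",
    "km_fit",
    "logrank",
    "cox_fit",
    "cutpoint_scan",
    "dichotomize_optimal",
    "gene_hazard_summary",
    "compare_early_late",
]

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMResult:
    times: np.ndarray        # event/censoring grid of the step function
    survival: np.ndarray     # S(t) at each grid time
    median: float            # earliest t with S(t) <= 0.5; inf if never reached
    n: int
    n_events: int


def km_fit(time, event, groups=None) -> dict[str, KMResult]:
    """Product-limit survival estimate per group.

    Returns a mapping group label -> :class:`KMResult` (a single key "all"
    when ``groups`` is None).  The median is the earliest time at which the
    survival function drops to 0.5 or below, ``inf`` if never reached.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if np.any(t <= 0):
        raise ValueError("all survival times must be positive")
    if groups is None:
        groups = np.zeros(len(t), dtype=int)
        labels = {0: "all"}
    else:
        groups = np.asarray(groups)
        labels = {g: str(g) for g in pd.unique(groups)}
    out: dict[str, KMResult] = {}
    for g, name in labels.items():
        m = groups == g
        if m.sum() < 1:
            raise ValueError(f"group {name} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        sf = kmf.survival_function_
        out[name] = KMResult(
            times=sf.index.to_numpy(float),
            survival=sf.iloc[:, 0].to_numpy(float),
            median=float(kmf.median_survival_time_),
            n=int(m.sum()),
            n_events=int(e[m].sum()),
        )
    return out


def logrank(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    for lv in levels:
        if (g == lv).sum() == 0:
            raise ValueError(f"group {lv} has no subjects")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


@dataclass
class CoxResult:
    coef: np.ndarray          # natural-log hazard ratios
    se: np.ndarray
    hr: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    separation: bool          # monotone likelihood flagged
    n: int
    n_events: int

    @property
    def log2_hr(self) -> np.ndarray:
        return self.coef / LN2


def _efron_ll_grad_hess(beta, t, e, X, group_ends, d_per_group, reps, lfrac):
    """Partial log-likelihood, gradient and Hessian with Efron ties.

    Arrays are pre-sorted by descending time so risk-set sums are cumulative
    sums; ``group_ends`` indexes the last member of each tie group,
    ``reps``/``lfrac`` expand tie groups into their Efron terms l/d.
    """
    n, p = X.shape
    eta = np.clip(X @ beta, -200, 200)
    w = np.exp(eta)
    wx = X * w[:, None]
    wxx = np.einsum("ni,nj->nij", X, wx)

    r0 = np.cumsum(w)[group_ends]                         # (G,)
    r1 = np.cumsum(wx, axis=0)[group_ends]                # (G, p)
    r2 = np.cumsum(wxx, axis=0)[group_ends]               # (G, p, p)

    ev = e.astype(bool)
    we, wxe, wxxe = np.where(ev, w, 0.0), np.where(ev[:, None], wx, 0.0), \
        np.where(ev[:, None, None], wxx, 0.0)
    starts = np.concatenate([[0], group_ends[:-1] + 1])
    d0 = np.add.reduceat(we, starts)
    d1 = np.add.reduceat(wxe, starts, axis=0)
    d2 = np.add.reduceat(wxxe, starts, axis=0)

    gidx = reps                                           # (m,) group index per Efron term
    phi0 = r0[gidx] - lfrac * d0[gidx]
    phi1 = r1[gidx] - lfrac[:, None] * d1[gidx]
    phi2 = r2[gidx] - lfrac[:, None, None] * d2[gidx]
    phi0 = np.maximum(phi0, 1e-300)

    ll = float(eta[ev].sum() - np.log(phi0).sum())
    u = phi1 / phi0[:, None]
    grad = X[ev].sum(axis=0) - u.sum(axis=0)
    h1 = (phi2 / phi0[:, None, None]).sum(axis=0)
    h2 = np.einsum("mi,mj->ij", u, u)
    hess = -(h1 - h2)
    return ll, grad, hess


def _prepare_cox(time, event, X):
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(t):
        X = X.T
    order = np.argsort(-t, kind="stable")   # descending time; ties share one risk set
    t, e, X = t[order], e[order], X[order]
    # tie groups over identical times
    change = np.flatnonzero(np.diff(t) != 0)
    group_ends = np.concatenate([change, [len(t) - 1]])
    starts = np.concatenate([[0], group_ends[:-1] + 1])
    d_per_group = np.add.reduceat(e, starts)
    # Efron expansion: for group g with d events, terms l = 0..d-1, weight l/d
    reps = np.repeat(np.arange(len(group_ends)), d_per_group)
    l_within = np.concatenate([np.arange(d) for d in d_per_group if d > 0]) \
        if d_per_group.sum() > 0 else np.array([], dtype=int)
    d_rep = np.repeat(d_per_group, d_per_group)
    lfrac = l_within / np.maximum(d_rep, 1)
    return t, e, X, group_ends, d_per_group, reps, lfrac


def cox_fit(time, event, covariates, max_iter: int = 60,
            tol: float = 1e-9) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson with Efron ties.

    ``covariates`` is (n,) or (n, p).  Convergence when the relative change
    in partial log-likelihood falls below ``tol``; monotone likelihood
    (perfect separation) is flagged and iteration capped rather than raised.
    """
    e_arr = np.asarray(event, int)
    if e_arr.sum() < 1:
        raise ValueError("need at least one event")
    X_in = np.asarray(covariates, float)
    if X_in.ndim == 1:
        X_in = X_in[:, None]
    if np.any(np.std(X_in, axis=0) <= 0):
        bad = [j for j in range(X_in.shape[1]) if np.std(X_in[:, j]) <= 0]
        raise ValueError(f"constant covariate column(s): {bad}")

    t, e, X, group_ends, d_per_group, reps, lfrac = _prepare_cox(time, event, X_in)
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, hess = _efron_ll_grad_hess(beta, t, e, X, group_ends,
                                         d_per_group, reps, lfrac)
    converged = False
    separation = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess - 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = grad / (np.abs(np.diag(hess)).max() + 1e-12)
        new_beta = beta - step
        new_ll, new_grad, new_hess = _efron_ll_grad_hess(
            new_beta, t, e, X, group_ends, d_per_group, reps, lfrac)
        halvings = 0
        while new_ll < ll and halvings < 12:
            step *= 0.5
            new_beta = beta - step
            new_ll, new_grad, new_hess = _efron_ll_grad_hess(
                new_beta, t, e, X, group_ends, d_per_group, reps, lfrac)
            halvings += 1
        rel = abs(new_ll - ll) / (abs(ll) + 0.1)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > 25):
            separation = True
            break
        if rel < tol:
            converged = True
            break
    # monotone likelihood: the optimum drifts to huge |beta| with a flat
    # profile; Newton may stall "converged" there, so flag by magnitude
    if np.any(np.abs(beta) > 15):
        separation = True

    cov = np.linalg.inv(-(hess) + 1e-300 * np.eye(p))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * norm.sf(np.abs(z))
    return CoxResult(coef=beta, se=se, hr=np.exp(beta), z=z, p=pvals,
                     loglik=ll, converged=converged, separation=separation,
                     n=n, n_events=int(e.sum()))


# ---------------------------------------------------------------------------
# Exhaustive cutpoint scanning


@dataclass
class CutpointScan:
    table: pd.DataFrame      # cut_index, threshold, n_low, n_high, log2_hr, p, padj
    best_index: int          # cut_index of the minimal adjusted p (NaN-safe)
    order: np.ndarray = field(repr=False, default=None)  # ascending-score order

    @property
    def best_row(self) -> pd.Series:
        return self.table.loc[self.table["cut_index"] == self.best_index].iloc[0]


def cutpoint_scan(score, time, event, covariate=None, min_group: int = 1,
                  use_fdr: bool = True) -> CutpointScan:
    """Cox scan over every rank stratification point of a score.

    Samples are ranked in increasing score order; for each of the n-1
    possible cut-offs a binary high/low indicator (high = above the cut)
    enters a Cox model, together with ``covariate`` when supplied.  BH
    adjustment is applied across the scan and the best cut-off is the one
    with the most significant adjusted p-value.  Cut-offs leaving fewer than
    ``min_group`` subjects on either side are excluded from adjustment and
    from the optimum (rows retained with NaN p).
    """
    s = np.asarray(score, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(s)):
        raise ValueError("missing scores are not allowed")
    if e.sum() < 1:
        raise ValueError("no events in the cohort")
    cov = None
    if covariate is not None:
        cov = np.asarray(covariate, float)
        if np.std(cov) <= 0:
            cov = None  # constant covariate carries no information

    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    rows = []
    for i in range(1, n):
        z = np.zeros(n)
        z[order[i:]] = 1.0
        n_low, n_high = i, n - i
        thr = s_sorted[i - 1]
        if min(n_low, n_high) < min_group:
            rows.append((i, thr, n_low, n_high, np.nan, np.nan))
            continue
        X = z if cov is None else np.column_stack([z, cov])
        try:
            fit = cox_fit(t, e, X)
            rows.append((i, thr, n_low, n_high, fit.log2_hr[0], fit.p[0]))
        except (ValueError, np.linalg.LinAlgError):
            rows.append((i, thr, n_low, n_high, np.nan, np.nan))

    tab = pd.DataFrame(rows, columns=["cut_index", "threshold", "n_low",
                                      "n_high", "log2_hr", "p"])
    tab["padj"] = bh_adjust(tab["p"].to_numpy())
    crit = tab["padj"] if use_fdr else tab["p"]
    if crit.notna().any():
        best = int(tab.loc[crit.idxmin(), "cut_index"])
    else:
        best = -1
    return CutpointScan(table=tab, best_index=best, order=order)


def dichotomize_optimal(cohort: pd.DataFrame, score_column: str,
                        covariate=None, min_group: int = 1):
    """High/low labels from the optimal stratification point, plus KM/log-rank.

    Returns (labels Series with values 'high'/'low', km dict, (logrank
    statistic, p), CutpointScan).
    """
    s = cohort[score_column].to_numpy(float)
    if np.unique(s).size < 2:
        raise ValueError("all scores equal: no valid stratification point")
    scan = cutpoint_scan(s, cohort["time_months"], cohort["event"],
                         covariate=covariate, min_group=min_group)
    if scan.best_index < 0:
        raise ValueError("no valid cut-off under the group-size constraint")
    labels = np.full(len(s), "low", dtype=object)
    labels[scan.order[scan.best_index:]] = "high"
    labels = pd.Series(labels, index=cohort.index, name="group")
    km = km_fit(cohort["time_months"], cohort["event"], labels.to_numpy())
    lr = logrank(cohort["time_months"], cohort["event"], labels.to_numpy())
    return labels, km, lr, scan


# ---------------------------------------------------------------------------
# Early vs late hazard summaries


@dataclass
class GeneHazardSummary:
    gene: str
    early_summary: float     # sum of significant log2 HRs / window cohort size
    late_summary: float
    n_sig_early: int
    n_sig_late: int
    n_early: int
    n_late: int
    covariate_used: bool


def _er_numeric(series: pd.Series) -> np.ndarray:
    m = series.astype(str).str.lower().map(
        {"positive": 1.0, "pos": 1.0, "1": 1.0, "negative": 0.0, "neg": 0.0, "0": 0.0})
    return m.to_numpy(float)


def _window_summary(s, t, e, cov, alpha, min_group, use_fdr):
    scan = cutpoint_scan(s, t, e, covariate=cov, min_group=min_group,
                         use_fdr=use_fdr)
    crit = scan.table["padj"] if use_fdr else scan.table["p"]
    sig = crit <= alpha
    total = float(scan.table.loc[sig, "log2_hr"].sum())
    return total / len(s), int(sig.sum())


def gene_hazard_summary(cohort: pd.DataFrame, gene_column: str,
                        landmark: float = 60.0, alpha: float = 0.05,
                        covariate: str | None = "er_status",
                        min_group: int = 1, use_fdr: bool = True,
                        covariate_rule: str = "significant") -> GeneHazardSummary:
    """Early- and late-window cutpoint-scan summaries for one gene.

    Early window: follow-up administratively censored at the landmark
    (events after it become censored at the landmark).  Late window:
    subjects still event-free and under follow-up at the landmark, analysed
    on the original time scale.  In each window every rank cut-off of the
    gene's expression enters a Cox model; the summary is the sum of log2
    hazard ratios over cut-offs with FDR-adjusted p <= alpha, normalised to
    the window cohort size (exactly 0 when nothing is significant).

    The ER covariate enters the Cox models only when its own univariate Cox
    coefficient is significant at 0.05 in that window
    (``covariate_rule="always"`` forces inclusion).
    """
    t = cohort["time_months"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    s = cohort[gene_column].to_numpy(float)
    if landmark <= 0 or landmark >= t.max():
        raise ValueError("landmark must lie within the follow-up range")

    cov_all = None
    if covariate is not None and covariate in cohort.columns:
        cov_all = _er_numeric(cohort[covariate])
        if np.any(~np.isfinite(cov_all)):
            cov_all = np.where(np.isfinite(cov_all), cov_all, np.nanmean(cov_all))

    # early: administrative censoring at the landmark
    e_early = np.where(t <= landmark, e, 0)
    t_early = np.minimum(t, landmark)
    # late: conditional on being event-free at the landmark
    late_mask = t > landmark
    if late_mask.sum() < 3 or len(t) < 3:
        raise ValueError("landmark leaves fewer than 3 subjects in a window")

    def pick_cov(mask, tt, ee):
        if cov_all is None:
            return None
        c = cov_all[mask]
        if np.std(c) <= 0:
            return None
        if covariate_rule == "always":
            return c
        if ee.sum() < 1:
            return None
        uni = cox_fit(tt, ee, c)
        return c if uni.p[0] <= 0.05 else None

    full = np.ones(len(t), dtype=bool)
    cov_e = pick_cov(full, t_early, e_early) if e_early.sum() >= 1 else None
    early, n_sig_e = (_window_summary(s, t_early, e_early, cov_e, alpha,
                                      min_group, use_fdr)
                      if e_early.sum() >= 1 else (0.0, 0))
    t_l, e_l, s_l = t[late_mask], e[late_mask], s[late_mask]
    cov_l = pick_cov(late_mask, t_l, e_l) if e_l.sum() >= 1 else None
    late, n_sig_l = (_window_summary(s_l, t_l, e_l, cov_l, alpha,
                                     min_group, use_fdr)
                     if e_l.sum() >= 1 else (0.0, 0))

    return GeneHazardSummary(
        gene=gene_column, early_summary=early, late_summary=late,
        n_sig_early=n_sig_e, n_sig_late=n_sig_l,
        n_early=len(t), n_late=int(late_mask.sum()),
        covariate_used=cov_e is not None or cov_l is not None,
    )


def compare_early_late(late_values, early_values) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of late vs early summaries.

    Exact enumeration when both sides have <= 10 untied values, otherwise
    the normal approximation with tie correction and continuity correction.
    Returns (U statistic, p).
    """
    x = np.asarray(late_values, float)
    y = np.asarray(early_values, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per side")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
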