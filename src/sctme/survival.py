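"""Module scores, correlation/group tests and the signature survival pipeline.

The survival pathway mirrors the standard bulk-validation recipe for a
single-cell signature: per gene log2(x+1) then z-score across samples, the
signature score is the mean z over the signature genes, samples are split at
the median score (ties go low), and the high/low groups are compared by
Kaplan–Meier curves, the log-rank test and a univariate Cox proportional
hazards model (Breslow tie handling, Newton–Raphson on the partial
likelihood, Wald confidence intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import t as _t

from .core_io import ValidationError
from .markers import _auc_block, _dense

__all__ = [
    "CoxResult",
    "module_score",
    "spearman_corr",
    "signature_score_bulk",
    "median_split",
    "km_curve",
    "logrank_test",
    "cox_univariate",
    "wilcoxon_group_test",
    "significance_stars",
]


def module_score(
    norm,
    gene_set,
    gene_ids,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score: mean set expression minus matched controls.

    Genes are binned into ``n_bins`` equal-frequency bins by their average
    expression over all cells; for each set gene, ``n_ctrl`` control genes
    are sampled from its bin (with replacement when the bin is smaller), and
    the score is mean(set genes) − mean(pooled control genes) per cell.
    """
    gene_ids = list(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    set_idx = [pos[g] for g in gene_set if g in pos]
    if not set_idx:
        raise ValidationError("no gene of the set is present in the matrix")
    X = _dense(norm)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    n_bins_eff = min(n_bins, len(gene_ids))
    bins = np.empty(len(gene_ids), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins_eff)):
        bins[chunk] = b
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        replace = pool.size < n_ctrl
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=replace))
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, name="module_score")


def spearman_corr(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    p uses the t approximation, or exact enumeration over permutations of the
    second variable when n ≤ ``exact_max_n``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValidationError("need two equal-length vectors of length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValidationError("zero variance: Spearman correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        hits = 0
        total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
            total += 1
        return rho, hits / total
    if abs(rho) >= 1:
        return rho, 0.0
    t_stat = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return rho, float(2 * _t.sf(abs(t_stat), df=n - 2))


def signature_score_bulk(bulk_expr: pd.DataFrame, signature_genes) -> pd.Series:
    """Per-sample signature score: mean of per-gene z-scored log2(x+1).

    ``bulk_expr`` is samples × genes on linear scale.  Genes absent from the
    matrix or with zero variance are dropped with a warning.
    """
    present = [g for g in signature_genes if g in bulk_expr.columns]
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    dropped = [g for g in signature_genes if g not in bulk_expr.columns]
    if dropped:
        warnings.warn(f"signature gene(s) absent, dropped: {dropped}")
    logged = np.log2(bulk_expr[present].astype(float) + 1.0)
    sd = logged.std(axis=0, ddof=1)
    flat = list(sd.index[sd == 0])
    if flat:
        warnings.warn(f"zero-variance gene(s) dropped: {flat}")
        logged = logged.drop(columns=flat)
        if logged.shape[1] == 0:
            raise ValidationError("all signature genes have zero variance")
        sd = sd.drop(flat)
    z = (logged - logged.mean(axis=0)) / sd
    return z.mean(axis=1).rename("signature_score")


def median_split(scores: pd.Series) -> pd.Series:
    """'high' iff score > median; ties (score == median) go 'low'."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 samples")
    med = float(np.median(scores.values))
    return pd.Series(
        np.where(scores.values > med, "high", "low"), index=scores.index, name="group"
    )


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate as a step table (time, survival)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def logrank_test(group_labels, times, events) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (df 1) and p-value."""
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValidationError("log-rank test needs exactly 2 groups")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() < 1:
        raise ValidationError("log-rank test needs at least one event")
    m = labels == uniq[0]
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    se: float

    def __post_init__(self) -> None:
        assert self.ci_low <= self.hr <= self.ci_high


def cox_univariate(
    covariate, times, events, tol: float = 1e-8, max_iter: int = 100
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow ties, Newton–Raphson).

    Returns the hazard ratio with a 95% Wald confidence interval and p-value.
    Raises on non-convergence or monotone likelihood (complete separation).
    """
    x = np.asarray(covariate, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() < 2:
        raise ValidationError("need at least 2 events")
    if np.std(x) == 0:
        raise ValidationError("covariate is constant")
    order = np.argsort(-times, kind="stable")  # descending: cumulative risk sets
    x_s = x[order]
    t_s = times[order]
    e_s = events[order]

    event_times, inv = np.unique(t_s[e_s == 1], return_inverse=True)
    sum_x_events = float(x_s[e_s == 1].sum())

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x_s)
        cs0 = np.cumsum(w)
        cs1 = np.cumsum(w * x_s)
        cs2 = np.cumsum(w * x_s * x_s)
        # risk set of time t = subjects with time >= t = prefix of descending order
        grad = sum_x_events
        hess = 0.0
        for t in event_times:
            k = int(np.searchsorted(-t_s, -t, side="right")) - 1
            d = int(((t_s == t) & (e_s == 1)).sum())
            s0, s1, s2 = cs0[k], cs1[k], cs2[k]
            grad -= d * s1 / s0
            hess -= d * (s2 / s0 - (s1 / s0) ** 2)
        if hess >= -1e-14:
            raise ValidationError("monotone partial likelihood (complete separation?)")
        step = grad / hess
        beta_new = beta - step
        if abs(beta_new) > 50:
            raise ValidationError("monotone partial likelihood (complete separation?)")
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise ValidationError(f"Cox fit did not converge in {max_iter} iterations")

    # observed information at the optimum
    w = np.exp(beta * x_s)
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(w * x_s)
    cs2 = np.cumsum(w * x_s * x_s)
    info = 0.0
    for t in event_times:
        k = int(np.searchsorted(-t_s, -t, side="right")) - 1
        d = int(((t_s == t) & (e_s == 1)).sum())
        s0, s1, s2 = cs0[k], cs1[k], cs2[k]
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2 * _norm.sf(abs(z)))
    return CoxResult(
        log_hr=float(beta),
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=p,
        se=se,
    )


def significance_stars(p: float) -> str:
    """Star annotation: * p<.05, ** p<.01, *** p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def wilcoxon_group_test(values_a, values_b) -> tuple[float, float, str]:
    """Wilcoxon rank-sum comparison of two samples: (AUC, p, stars).

    Uses the same engine as the marker module (exact for total n ≤ 12).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    X = np.concatenate([a, b])[:, None]
    mask = np.zeros(X.shape[0], dtype=bool)
    mask[: a.size] = True
    auc, _, p = _auc_block(X, mask)
    return float(auc[0]), float(p[0]), significance_stars(float(p[0]))
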