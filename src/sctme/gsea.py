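"""Preranked gene-set enrichment analysis.

Genes are ranked by a signed AUC metric (AUC − 0.5 from the marker engine, or
any caller-supplied score).  The enrichment score of a gene set is the
extremum of the classic weighted Kolmogorov–Smirnov running sum: walking down
the ranking, hits add ``|metric|**p`` (normalized over hit genes) and misses
subtract ``1/(N − N_hits)``.  Significance uses gene-set permutation: null
scores come from random sets of identical size drawn from the ranked
universe, the normalized enrichment score divides by the mean |null ES| of
matching sign, and the FDR is the standard per-sign ratio-of-tails estimator
on pooled null NES versus observed NES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ValidationError

__all__ = ["RankedList", "GseaResult", "rank_by_auc", "enrichment_score", "nes_fdr"]


@dataclass
class RankedList:
    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValidationError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        self.metric = np.asarray(self.metric, dtype=float)
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValidationError("metric must be sorted descending")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str]


def rank_by_auc(marker_stats: pd.DataFrame) -> RankedList:
    """Rank genes by signed AUC (auc − 0.5), descending.

    Ties broken by descending log2FC then ascending gene id.  Expects one row
    per gene with columns ``auc`` and ``log2fc`` and the gene id in the index
    or a ``gene`` column.
    """
    df = marker_stats.copy()
    if "gene" not in df.columns:
        df = df.reset_index().rename(columns={df.index.name or "index": "gene"})
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate genes in marker stats")
    df["metric"] = df["auc"] - 0.5
    df = df.sort_values(["metric", "log2fc", "gene"], ascending=[False, False, True])
    return RankedList(genes=list(df["gene"]), metric=df["metric"].to_numpy())


def _running_sum(metric: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> np.ndarray:
    n = metric.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the whole ranked list")
    w = np.abs(metric) ** weight_p
    hit_total = w[hit_mask].sum()
    steps = np.where(
        hit_mask,
        (w / hit_total) if hit_total > 0 else (1.0 / n_hits),
        -1.0 / (n - n_hits),
    )
    if hit_total == 0:
        # all hit metrics are zero: fall back to unweighted hit increments
        steps = np.where(hit_mask, 1.0 / n_hits, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score, running sum and leading edge.

    The ES is the running-sum value of maximal absolute deviation; the
    leading edge contains the hit genes up to (positive ES) or from
    (negative ES) that position.
    """
    genes = ranked.genes
    gs = set(gene_set)
    hit_mask = np.array([g in gs for g in genes])
    rs = _running_sum(ranked.metric, hit_mask, weight_p)
    imax = int(np.argmax(rs))
    imin = int(np.argmin(rs))
    # magnitude ties between the two extremes resolve to the positive one
    if rs[imax] >= -rs[imin] - 1e-12:
        pos, es = imax, float(rs[imax])
    else:
        pos, es = imin, float(rs[imin])
    if es >= 0:
        leading = [g for g, h in zip(genes[: pos + 1], hit_mask[: pos + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[pos:], hit_mask[pos:]) if h]
    return es, rs, leading


def _null_es(
    ranked: RankedList, size: int, n_perm: int, weight_p: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(ranked.genes)
    out = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.choice(n, size=size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        rs = _running_sum(ranked.metric, mask, weight_p)
        hi, lo = rs.max(), rs.min()
        out[k] = hi if hi >= -lo - 1e-12 else lo
    return out


def nes_fdr(
    ranked: RankedList,
    gene_sets,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[GseaResult]:
    """Permutation NES, p and FDR for every gene set.

    ``gene_sets`` is a mapping name → gene list (or an iterable of such
    pairs).  Null distributions are size-matched random gene sets; p is the
    fraction of same-sign null ES at least as extreme; FDR is the per-sign
    ratio of (pooled null NES tail fraction) to (observed NES tail
    fraction), capped at 1.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    items = list(gene_sets.items() if hasattr(gene_sets, "items") else gene_sets)
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)

    observed = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, genes in items:
        size = len(set(genes) & universe)
        es, _, leading = enrichment_score(ranked, genes, weight_p)
        if size not in null_by_size:
            null_by_size[size] = _null_es(ranked, size, n_perm, weight_p, rng)
        observed.append((name, es, leading, size))

    # normalize: divide by mean |null| of matching sign (per set size)
    results: list[GseaResult] = []
    nes_obs = []
    null_nes_pool: list[np.ndarray] = []
    norms: dict[int, tuple[float, float]] = {}
    for size, null in null_by_size.items():
        pos = null[null > 0]
        neg = null[null < 0]
        if pos.size == 0 and neg.size == 0:
            raise ValidationError("degenerate permutation null (all zero)")
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        norms[size] = (mean_pos, mean_neg)
        normed = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_pool.append(normed[np.isfinite(normed)])
    pooled_null = np.concatenate(null_nes_pool)

    for name, es, leading, size in observed:
        null = null_by_size[size]
        mean_pos, mean_neg = norms[size]
        if es >= 0:
            same = null[null > 0]
            p = float((same >= es).mean()) if same.size else 1.0
            nes = es / mean_pos if np.isfinite(mean_pos) else 0.0
        else:
            same = null[null < 0]
            p = float((same <= es).mean()) if same.size else 1.0
            nes = es / mean_neg if np.isfinite(mean_neg) else 0.0
        nes_obs.append(nes)
        results.append(GseaResult(name, es, float(nes), p, fdr=np.nan, leading_edge=leading))

    nes_obs_arr = np.array(nes_obs)
    for r, nes in zip(results, nes_obs_arr):
        if nes >= 0:
            null_tail = (pooled_null >= nes).mean()
            pos_null = (pooled_null >= 0).mean()
            obs_tail = (nes_obs_arr >= nes).mean()
            pos_obs = (nes_obs_arr >= 0).mean()
        else:
            null_tail = (pooled_null <= nes).mean()
            pos_null = (pooled_null < 0).mean()
            obs_tail = (nes_obs_arr <= nes).mean()
            pos_obs = (nes_obs_arr < 0).mean()
        num = null_tail / pos_null if pos_null > 0 else 1.0
        den = obs_tail / pos_obs if pos_obs > 0 else 1.0
        r.fdr = float(min(1.0, num / den if den > 0 else 1.0))
    return results
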