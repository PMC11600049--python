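"""Marker detection and cluster annotation.

The DE engine is a one-vs-rest Wilcoxon rank-sum test reported together with
the AUC of each gene as a classifier for the in-group (the two are the same
statistic: AUC = U / (n_in * n_out), ties counted half).  p-values use the
tie-corrected normal approximation, switching to exact enumeration over label
assignments when the total group size is at most 12.  log2 fold changes are
computed on back-transformed normalized means with a +1 stabilizer:
``log2((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1))``.

Marker retention follows the standard single-cell criteria: detected in at
least 25% of the in-cluster cells, Bonferroni-adjusted p < 0.05 (family =
genes tested per cluster) and log2FC > 0.25.

Cluster annotation scores each reference cell type by the mean normalized
expression of its marker genes over the cluster's cells and assigns the
argmax, flagging calls where the top two scores are within 10% of each other.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .core_io import ValidationError

__all__ = [
    "REFERENCE_MARKERS",
    "wilcoxon_auc",
    "find_all_markers",
    "annotate_clusters",
    "composition_table",
    "composition_percentages",
    "top_n_signature",
    "classify_quadrants",
]

#: Canonical lineage markers used for annotation.
REFERENCE_MARKERS: dict[str, tuple[str, ...]] = {
    "T/NK": ("CD3D", "CD3E", "CD3G", "NKG7"),
    "Plasma": ("JCHAIN", "IGKC", "IGHG1"),
    "B": ("CD79A", "MS4A1", "CD19"),
    "Myeloid": ("LYZ", "CD14", "SPP1"),
    "CAF": ("DCN", "LUM", "COL1A1"),
    "Epithelial": ("EPCAM", "KRT8", "CAPS"),
    "Mast": ("KIT", "CPA3", "MS4A2"),
    "Endothelial": ("VWF", "PECAM1", "CALCRL"),
}

EXACT_MAX_N = 12


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def _tie_term(col: np.ndarray) -> float:
    _, counts = np.unique(col, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def _exact_p(col: np.ndarray, n_in: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all in/out label assignments."""
    n = col.size
    ranks = rankdata(col)
    mu = n_in * (n - n_in) / 2.0
    dev = abs(u_obs - mu)
    offset = n_in * (n_in + 1) / 2.0
    hits = 0
    for combo in itertools.combinations(range(n), n_in):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n_in)


def _auc_block(X: np.ndarray, in_mask: np.ndarray, exact: bool | None = None):
    """AUC, U and two-sided p for every gene column of X."""
    n = X.shape[0]
    n_in = int(in_mask.sum())
    n_out = n - n_in
    if n_in == 0 or n_out == 0:
        raise ValidationError("both groups must be non-empty")
    ranks = rankdata(X, axis=0)
    u = ranks[in_mask].sum(axis=0) - n_in * (n_in + 1) / 2.0
    auc = u / (n_in * n_out)
    if exact is None:
        exact = n <= EXACT_MAX_N
    if exact:
        p = np.array([_exact_p(X[:, j], n_in, u[j]) for j in range(X.shape[1])])
    else:
        mu = n_in * n_out / 2.0
        tie = np.array([_tie_term(X[:, j]) for j in range(X.shape[1])])
        sigma2 = n_in * n_out / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sigma2 > 0, (u - mu) / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
        p = np.where(sigma2 > 0, 2 * _norm.sf(np.abs(z)), 1.0)
        p = np.minimum(p, 1.0)
    return auc, u, p


def wilcoxon_auc(norm, in_cells, out_cells, gene_ids=None) -> pd.DataFrame:
    """Per-gene Wilcoxon/AUC statistics for in-group vs out-group cells.

    Parameters
    ----------
    norm
        Cells × genes normalized matrix (dense or sparse).
    in_cells, out_cells
        Disjoint row-index arrays.
    gene_ids
        Optional gene names for the result index.

    Returns a DataFrame with columns ``auc, log2fc, p, pct_in, pct_out``.
    """
    in_cells = np.asarray(in_cells, dtype=int)
    out_cells = np.asarray(out_cells, dtype=int)
    if in_cells.size == 0 or out_cells.size == 0:
        raise ValidationError("both cell groups must be non-empty")
    if np.intersect1d(in_cells, out_cells).size:
        raise ValidationError("in_cells and out_cells must be disjoint")
    X = _dense(norm)
    sub = X[np.concatenate([in_cells, out_cells])]
    in_mask = np.zeros(sub.shape[0], dtype=bool)
    in_mask[: in_cells.size] = True
    auc, _, p = _auc_block(sub, in_mask)
    expr_in = np.expm1(sub[in_mask])
    expr_out = np.expm1(sub[~in_mask])
    log2fc = np.log2((expr_in.mean(axis=0) + 1) / (expr_out.mean(axis=0) + 1))
    pct_in = (sub[in_mask] > 0).mean(axis=0)
    pct_out = (sub[~in_mask] > 0).mean(axis=0)
    idx = gene_ids if gene_ids is not None else np.arange(X.shape[1])
    return pd.DataFrame(
        {"auc": auc, "log2fc": log2fc, "p": p, "pct_in": pct_in, "pct_out": pct_out},
        index=pd.Index(idx, name="gene"),
    )


def find_all_markers(
    norm,
    clusters,
    gene_ids=None,
    min_pct: float = 0.25,
    max_p_adj: float = 0.05,
    min_log2fc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest marker detection over every cluster with standard filters.

    Bonferroni adjustment is applied per cluster over the genes tested.
    Clusters with fewer than 3 cells are skipped with a warning.  Returns the
    retained rows (``gene, cluster, auc, log2fc, p, p_adj, pct_in, pct_out``)
    sorted by cluster then descending log2FC.
    """
    clusters = np.asarray(clusters)
    names = pd.unique(clusters)
    if len(names) < 2:
        raise ValidationError("need at least 2 clusters")
    X = _dense(norm)
    m = X.shape[1]
    out_frames = []
    all_idx = np.arange(X.shape[0])
    for name in names:
        in_cells = all_idx[clusters == name]
        if in_cells.size < 3:
            warnings.warn(f"cluster {name!r} has < 3 cells; skipped")
            continue
        out_cells = all_idx[clusters != name]
        stats = wilcoxon_auc(X, in_cells, out_cells, gene_ids=gene_ids)
        stats["p_adj"] = np.minimum(1.0, stats["p"] * m)
        stats["cluster"] = name
        keep = (
            (stats["pct_in"] >= min_pct)
            & (stats["p_adj"] < max_p_adj)
            & (stats["log2fc"] > min_log2fc)
        )
        out_frames.append(stats[keep].reset_index())
    if not out_frames:
        return pd.DataFrame(
            columns=["gene", "cluster", "auc", "log2fc", "p", "p_adj", "pct_in", "pct_out"]
        )
    res = pd.concat(out_frames, ignore_index=True)
    res = res.sort_values(["cluster", "log2fc"], ascending=[True, False])
    cols = ["gene", "cluster", "auc", "log2fc", "p", "p_adj", "pct_in", "pct_out"]
    return res[cols].reset_index(drop=True)


def annotate_clusters(
    norm,
    clusters,
    gene_ids,
    reference: dict[str, tuple[str, ...]] | None = None,
    ambiguity_margin: float = 0.10,
) -> pd.DataFrame:
    """Assign a reference cell type to each cluster by mean marker expression.

    The score of a type is the mean normalized expression of its marker genes
    over the cluster's cells.  The call is the argmax; ``ambiguous`` is set
    when the runner-up score is within ``ambiguity_margin`` (relative) of the
    top score.
    """
    reference = reference or REFERENCE_MARKERS
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    usable: dict[str, list[int]] = {}
    any_present = False
    for ct, genes in reference.items():
        present = [gene_pos[g] for g in genes if g in gene_pos]
        missing = [g for g in genes if g not in gene_pos]
        if missing:
            warnings.warn(f"{ct}: marker gene(s) absent, dropped: {missing}")
        if present:
            any_present = True
            usable[ct] = present
    if not any_present:
        raise ValidationError("no reference marker gene present in the dataset")
    X = _dense(norm)
    clusters = np.asarray(clusters)
    rows = []
    for name in pd.unique(clusters):
        mask = clusters == name
        scores = {
            ct: float(X[np.ix_(mask, idx)].mean()) for ct, idx in usable.items()
        }
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        top_ct, top = ordered[0]
        second = ordered[1][1] if len(ordered) > 1 else -np.inf
        margin = top - second
        denom = abs(top) if abs(top) > 1e-12 else 1e-12
        ambiguous = len(ordered) > 1 and (margin <= 0 or margin / denom < ambiguity_margin)
        rows.append(
            {
                "cluster": name,
                "cell_type": top_ct,
                "score": top,
                "margin": margin,
                "ambiguous": bool(ambiguous),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def composition_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentages (2 decimals) of each type from raw per-type cell counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no cells")
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def composition_table(meta: pd.DataFrame, by: str = "group", type_col: str = "cell_type") -> pd.DataFrame:
    """Per-stratum cell-type composition in percent (2 decimals).

    Rows are strata (values of ``by``), columns cell types; each row sums to
    100 up to rounding.  Empty strata are omitted with a warning.
    """
    if type_col not in meta.columns or by not in meta.columns:
        raise ValidationError(f"meta must carry columns {by!r} and {type_col!r}")
    tab = pd.crosstab(meta[by], meta[type_col])
    empty = tab.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"empty strata omitted: {list(tab.index[empty])}")
        tab = tab[~empty]
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    return pct.round(2)


def top_n_signature(markers: pd.DataFrame, n: int = 10) -> list[str]:
    """Top ``n`` marker genes of one cluster by descending log2FC.

    Ties broken by smaller p then lexicographic gene id.  If fewer than ``n``
    markers exist, all are returned with a warning.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if markers["cluster"].nunique() > 1:
        raise ValidationError("top_n_signature expects markers of a single cluster")
    ordered = markers.sort_values(
        ["log2fc", "p", "gene"], ascending=[False, True, True]
    )
    genes = list(ordered["gene"])
    if len(genes) < n:
        warnings.warn(f"only {len(genes)} markers available (requested {n})")
        return genes
    return genes[:n]


def classify_quadrants(
    counts,
    gene_ids,
    clusters=None,
    gene_x: str = "CXCL9",
    gene_y: str = "SPP1",
):
    """Per-cell quadrant labels from the positivity (raw count > 0) of two genes.

    Returns ``(labels, fractions)``: per-cell labels like ``"CXCL9-SPP1+"``
    and a quadrant-fraction table — one row per cluster when ``clusters`` is
    given, a single ``all`` row otherwise; each row sums to 1.
    """
    gene_ids = list(gene_ids)
    for g in (gene_x, gene_y):
        if g not in gene_ids:
            raise ValidationError(f"gene {g!r} absent from the matrix")
    X = counts
    xi = gene_ids.index(gene_x)
    yi = gene_ids.index(gene_y)
    col = lambda j: (
        np.asarray(X[:, [j]].todense()).ravel() if sp.issparse(X) else np.asarray(X)[:, j]
    )
    pos_x = col(xi) > 0
    pos_y = col(yi) > 0
    quads = [
        f"{gene_x}{'+' if px else '-'}{gene_y}{'+' if py else '-'}"
        for px, py in zip(pos_x, pos_y)
    ]
    labels = pd.Series(quads, name="quadrant")
    order = [
        f"{gene_x}-{gene_y}-",
        f"{gene_x}-{gene_y}+",
        f"{gene_x}+{gene_y}-",
        f"{gene_x}+{gene_y}+",
    ]
    strata = pd.Series(np.asarray(clusters) if clusters is not None else "all")
    tab = pd.crosstab(strata, labels).reindex(columns=order, fill_value=0)
    fractions = tab.div(tab.sum(axis=1), axis=0)
    return labels, fractions
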