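"""Cell-level quality control, library-size normalization and covariate regression.

QC keeps a cell iff ``min_genes <= n_genes <= max_genes``, ``n_umi <=
max_umi`` and ``pct_mito <= max_pct_mito`` — the bounds themselves are kept
(a cell at exactly 200 detected genes, 30 000 UMIs or 30.0% mitochondrial
content survives); the removal phrases are read strictly.  Cell-cycle (or any
other nuisance) covariates are handled by per-gene least-squares regression
of the normalized matrix, with gene means restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ExpressionDataset, ValidationError

__all__ = [
    "QCThresholds",
    "compute_cell_qc",
    "apply_qc_filters",
    "normalize_log1p",
    "regress_out",
]


@dataclass
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 5000
    max_umi: int = 30_000
    max_pct_mito: float = 30.0

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if min(self.min_genes, self.max_genes, self.max_umi, self.max_pct_mito) <= 0:
            raise ValidationError("all thresholds must be positive")


def compute_cell_qc(dataset: ExpressionDataset, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: n_genes, n_umi, pct_mito.

    ``pct_mito`` is 100 × (counts on genes with ``mito_prefix``) / n_umi, and
    0 for an all-zero cell.
    """
    if not mito_prefix:
        raise ValidationError("mito_prefix must be non-empty")
    X = dataset.counts.tocsr()
    n_genes = X.getnnz(axis=1)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in dataset.gene_ids])
    mito_counts = (
        np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        if mito_mask.any()
        else np.zeros(X.shape[0])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_counts / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_umi": n_umi.astype(int),
            "pct_mito": pct,
        },
        index=dataset.cell_ids,
    )


def apply_qc_filters(qc: pd.DataFrame, thresholds: QCThresholds | None = None):
    """Return ``(kept_cell_ids, removed_per_rule)``.

    A cell is counted against every rule it violates, so the per-rule tallies
    may sum to more than the number of removed cells.
    """
    th = thresholds or QCThresholds()
    low = qc["n_genes"] < th.min_genes
    high = qc["n_genes"] > th.max_genes
    umi = qc["n_umi"] > th.max_umi
    mito = qc["pct_mito"] > th.max_pct_mito
    keep = ~(low | high | umi | mito)
    removed = {
        "min_genes": int(low.sum()),
        "max_genes": int(high.sum()),
        "max_umi": int(umi.sum()),
        "max_pct_mito": int(mito.sum()),
    }
    return list(qc.index[keep]), removed


def normalize_log1p(dataset: ExpressionDataset, scale_factor: float = 10_000.0):
    """Library-size normalize then natural-log: ln(1 + sf * x / n_umi).

    All-zero cells map to zero rows.  Returns a CSR matrix and also stores it
    on ``dataset.norm``.
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    X = dataset.counts.tocsr().astype(float)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    inv = np.where(n_umi > 0, scale_factor / np.maximum(n_umi, 1e-300), 0.0)
    norm = sp.diags(inv) @ X
    norm.data = np.log1p(norm.data)
    norm = sp.csr_matrix(norm)
    dataset.norm = norm
    return norm


def regress_out(norm, covariates) -> np.ndarray:
    """Residualize each gene on the covariates (plus intercept), restoring means.

    Parameters
    ----------
    norm
        Cells × genes matrix (dense or sparse).
    covariates
        Cells × k array or DataFrame; an intercept is added internally.

    Raises a :class:`ValidationError` naming collinear columns when the
    design is rank-deficient.
    """
    X = np.asarray(norm.todense()) if sp.issparse(norm) else np.asarray(norm, float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.values.astype(float)
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != X.shape[0]:
            C = C.T
        names = [f"cov{i}" for i in range(C.shape[1])]
    if C.shape[0] != X.shape[0]:
        raise ValidationError("covariate matrix must have one row per cell")
    design = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank beyond the preceding ones
        bad = []
        r = 1
        for j in range(C.shape[1]):
            r_new = np.linalg.matrix_rank(design[:, : j + 2])
            if r_new == r:
                bad.append(names[j])
            r = r_new
        raise ValidationError(f"collinear covariate column(s): {bad}")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    return resid + X.mean(axis=0, keepdims=True)
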