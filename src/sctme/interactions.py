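"""Ligand–receptor interaction scoring with permutation significance.

The communication probability of a pair between a sender and a receiver
cluster is a Hill-saturated product of trimmed means:

    L = trimmed mean (25% each tail) of ligand expression over senders
    R = geometric mean over receptor subunits of their trimmed means
    probability = L*R / (K_h + L*R),  K_h = 0.5

Significance comes from shuffling cluster labels among the sender+receiver
cells.  An interaction is *retained* only when all four criteria hold: the
ligand is expressed (count > 0) in more than 10% of sender cells, the
receptor (every subunit) in more than 10% of receiver cells, the ligand's
log2 fold change in the sender versus all other cells exceeds 0.1, and the
BH-adjusted permutation p is below 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import trim_mean

from .core_io import LRDatabase, LRPair, ValidationError
from .enrichment import bh_adjust

__all__ = [
    "K_H",
    "expression_fraction",
    "communication_probability",
    "interaction_test",
]

K_H = 0.5
TRIM = 0.25

MIN_FRACTION = 0.10
MIN_LIGAND_LOG2FC = 0.1
MAX_P_ADJ = 0.05


def _dense_col(X, j) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X[:, [j]].todense()).ravel()
    return np.asarray(X)[:, j]


def expression_fraction(counts, cells, gene_idx: int) -> float:
    """Fraction of the given cells with raw count > 0 for the gene."""
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise ValidationError("empty cell set")
    col = _dense_col(counts, gene_idx)
    return float((col[cells] > 0).mean())


def _trimmed(x: np.ndarray) -> float:
    return float(trim_mean(x, TRIM)) if x.size else 0.0


def communication_probability(
    norm, sender_cells, receiver_cells, ligand_idx: int, receptor_idx
) -> float:
    """Hill-saturated ligand × receptor score in [0, 1]."""
    sender_cells = np.asarray(sender_cells, int)
    receiver_cells = np.asarray(receiver_cells, int)
    ligand = _dense_col(norm, ligand_idx)[sender_cells]
    L = _trimmed(ligand)
    sub_means = []
    for ri in receptor_idx:
        sub_means.append(_trimmed(_dense_col(norm, ri)[receiver_cells]))
    sub_means = np.asarray(sub_means)
    R = 0.0 if np.any(sub_means <= 0) else float(np.exp(np.mean(np.log(sub_means))))
    lr = L * R
    return lr / (K_H + lr)


def _ligand_log2fc(norm, ligand_idx: int, sender_cells: np.ndarray) -> float:
    col = _dense_col(norm, ligand_idx)
    mask = np.zeros(col.size, dtype=bool)
    mask[sender_cells] = True
    mean_in = np.expm1(col[mask]).mean()
    mean_out = np.expm1(col[~mask]).mean()
    return float(np.log2((mean_in + 1) / (mean_out + 1)))


def interaction_test(
    counts,
    norm,
    meta: pd.DataFrame,
    gene_ids,
    lr_db: LRDatabase,
    sender: str,
    receiver: str,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score and test every LR pair between a sender and a receiver cluster.

    Returns one row per pair with columns ``pair_name, probability, p, p_adj,
    ligand_log2fc, sender_fraction, receiver_fraction, retained``.  The null
    shuffles cluster labels among the union of sender and receiver cells;
    p = (1 + #null ≥ observed) / (1 + n_perm).  Deterministic for a fixed
    seed.  Pairs whose genes are absent are skipped with a warning.
    """
    if n_perm < 50:
        raise ValidationError("n_perm must be >= 50")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    clusters = meta["cluster"].to_numpy()
    for name in (sender, receiver):
        if name not in set(clusters):
            raise ValidationError(f"unknown cluster {name!r}")
    sender_cells = np.flatnonzero(clusters == sender)
    receiver_cells = np.flatnonzero(clusters == receiver)
    if sender_cells.size < 3 or receiver_cells.size < 3:
        warnings.warn("cluster smaller than 3 cells; no pairs tested")
        return pd.DataFrame(
            columns=[
                "pair_name", "sender", "receiver", "probability", "p", "p_adj",
                "ligand_log2fc", "sender_fraction", "receiver_fraction", "retained",
            ]
        )
    rng = np.random.default_rng(seed)
    union = np.concatenate([sender_cells, receiver_cells])
    n_s = sender_cells.size

    rows = []
    null_obs: list[np.ndarray] = []
    pairs_used: list[LRPair] = []
    # pre-draw the permutations once so every pair sees the same label shuffles
    perms = [rng.permutation(union.size) for _ in range(n_perm)]
    for pair in lr_db:
        missing = [
            g for g in (pair.ligand, *pair.receptor_subunits) if g not in gene_pos
        ]
        if missing:
            warnings.warn(f"pair {pair.pair_name!r}: missing gene(s) {missing}; skipped")
            continue
        li = gene_pos[pair.ligand]
        ri = [gene_pos[g] for g in pair.receptor_subunits]
        prob = communication_probability(norm, sender_cells, receiver_cells, li, ri)
        null = np.empty(n_perm)
        for k, perm in enumerate(perms):
            shuffled = union[perm]
            null[k] = communication_probability(
                norm, shuffled[:n_s], shuffled[n_s:], li, ri
            )
        p = (1.0 + float((null >= prob - 1e-12).sum())) / (1.0 + n_perm)
        s_frac = expression_fraction(counts, sender_cells, li)
        r_frac = min(
            expression_fraction(counts, receiver_cells, j) for j in ri
        )
        lfc = _ligand_log2fc(norm, li, sender_cells)
        rows.append(
            {
                "pair_name": pair.pair_name,
                "sender": sender,
                "receiver": receiver,
                "probability": prob,
                "p": p,
                "ligand_log2fc": lfc,
                "sender_fraction": s_frac,
                "receiver_fraction": r_frac,
            }
        )
        pairs_used.append(pair)
    res = pd.DataFrame(rows)
    if res.empty:
        res["p_adj"] = []
        res["retained"] = []
        return res
    res["p_adj"] = bh_adjust(res["p"].values)
    res["retained"] = (
        (res["sender_fraction"] > MIN_FRACTION)
        & (res["receiver_fraction"] > MIN_FRACTION)
        & (res["ligand_log2fc"] > MIN_LIGAND_LOG2FC)
        & (res["p_adj"] < MAX_P_ADJ)
    )
    return res
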