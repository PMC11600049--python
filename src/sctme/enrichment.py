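"""Cluster × group odds-ratio preference testing.

For every (cluster i, group j) combination a 2×2 contingency table is built
(cells in i∩j, in i only, in j only, neither), Fisher's exact test yields the
odds ratio and two-sided p-value, p-values are Benjamini–Hochberg adjusted
over all combinations jointly, and each combination is labelled:

* ``enriched``  — adjusted p < 0.01 and OR > 1.5
* ``depleted``  — adjusted p < 0.01 and OR < 0.5
* ``ns``        — otherwise

The OR point estimate is the cross-product ratio a*d/(b*c); when any cell is
zero, 0.5 is added to every cell (Haldane–Anscombe) before forming the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "fisher_or",
    "bh_adjust",
    "or_preference_matrix",
    "OR_ENRICHED",
    "OR_DEPLETED",
    "OR_ALPHA",
]

OR_ENRICHED = 1.5
OR_DEPLETED = 0.5
OR_ALPHA = 0.01


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a..d for one cluster × group combination."""

    a: int  # in cluster and in group
    b: int  # in cluster, not in group
    c: int  # in group, not in cluster
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_contingency(meta: pd.DataFrame, cluster_i: str, group_j: str) -> ContingencyTable:
    """Tabulate cells by membership in ``cluster_i`` × ``group_j``."""
    if cluster_i not in set(meta["cluster"]):
        raise ValidationError(f"unknown cluster {cluster_i!r}")
    if group_j not in set(meta["group"]):
        raise ValidationError(f"unknown group {group_j!r}")
    in_c = meta["cluster"] == cluster_i
    in_g = meta["group"] == group_j
    return ContingencyTable(
        a=int((in_c & in_g).sum()),
        b=int((in_c & ~in_g).sum()),
        c=int((~in_c & in_g).sum()),
        d=int((~in_c & ~in_g).sum()),
    )


def fisher_or(table: ContingencyTable) -> tuple[float, float]:
    """Odds ratio (cross-product, Haldane-corrected on zeros) and exact p.

    p is the two-sided Fisher exact probability: the sum of hypergeometric
    probabilities of tables at most as probable as the observed one.
    """
    if table.total == 0:
        raise ValidationError("all-zero contingency table")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    _, p = fisher_exact(table.as_array(), alternative="two-sided")
    return odds_ratio, float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def _label(odds_ratio: float, p_adj: float) -> str:
    if p_adj < OR_ALPHA and odds_ratio > OR_ENRICHED:
        return "enriched"
    if p_adj < OR_ALPHA and odds_ratio < OR_DEPLETED:
        return "depleted"
    return "ns"


def or_preference_matrix(meta: pd.DataFrame, by: str = "cells") -> pd.DataFrame:
    """Odds-ratio preference of every cluster for every group.

    ``by="cells"`` counts cells (default); ``by="samples"`` counts samples
    containing at least one cell of the cluster, a pseudo-replication-aware
    alternative.  BH adjustment pools all cluster × group combinations.
    Returns rows ``cluster, group, odds_ratio, p, p_adj, label``.
    """
    if by not in ("cells", "samples"):
        raise ValidationError("by must be 'cells' or 'samples'")
    work = meta
    if by == "samples":
        work = meta.drop_duplicates(["sample_id", "cluster"])[
            ["sample_id", "cluster", "group"]
        ]
    clusters = list(pd.unique(work["cluster"]))
    groups = list(pd.unique(work["group"]))
    if len(clusters) < 2 or len(groups) < 2:
        raise ValidationError("need at least 2 clusters and 2 groups")
    rows = []
    for ci in clusters:
        for gj in groups:
            tab = build_contingency(work, ci, gj)
            odds_ratio, p = fisher_or(tab)
            rows.append({"cluster": ci, "group": gj, "odds_ratio": odds_ratio, "p": p})
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p"].values)
    res["label"] = [
        _label(o, q) for o, q in zip(res["odds_ratio"], res["p_adj"])
    ]
    return res


def or_heatmap_matrix(result: pd.DataFrame) -> pd.DataFrame:
    """Pivot an :func:`or_preference_matrix` result to a cluster × group OR grid."""
    return result.pivot(index="cluster", columns="group", values="odds_ratio")
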