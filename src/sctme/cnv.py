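"""Copy-number scoring, malignancy calling, arm events and clonal trees.

The copy-number signal is represented as copy-neutral-centered residuals per
cell and genomic window, so departures from diploidy accumulate as energy:
the per-cell CNV score is the quadratic sum of residuals across the genome,
and a cell is called malignant when its score exceeds the reference mean by
more than two reference standard deviations.

Residuals are reduced to whole-arm events (gain/loss per p/q arm by mean
residual against symmetric cutoffs), cells with identical event sets are
collapsed into subclones, and subclones are arranged into a clonal tree whose
edges follow strict event-set inclusion (each node's parent is its largest
proper subset).  Trees serialize to Newick with cell fractions as branch
lengths.

:func:`estimate_cnv_residuals` provides a smoothing-based residual estimate
from normalized expression (reference-centered, clipped, moving-averaged in
genomic order); it is deliberately simple plumbing, not an HMM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import CytobandTable, ValidationError

__all__ = [
    "CNVProfile",
    "ArmEvent",
    "Subclone",
    "ClonalTree",
    "estimate_cnv_residuals",
    "cnv_score",
    "call_malignant",
    "map_events_to_arms",
    "collapse_subclones",
    "build_clonal_tree",
    "serialize_newick",
]

GAIN_CUT = 0.3
LOSS_CUT = -0.3


class ArmEvent(NamedTuple):
    chrom: str
    arm: str  # 'p' or 'q'
    direction: str  # 'gain' or 'loss'


@dataclass
class CNVProfile:
    """Cells × windows copy-number residuals, 0 = copy-neutral."""

    residuals: np.ndarray
    windows: list[tuple[str, int, int]]
    cell_ids: list[str]
    reference_cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.shape != (len(self.cell_ids), len(self.windows)):
            raise ValidationError("residual matrix shape mismatch")
        missing = set(self.reference_cell_ids) - set(self.cell_ids)
        if missing:
            raise ValidationError(f"reference cells not in profile: {sorted(missing)[:3]}")
        order = sorted(range(len(self.windows)), key=lambda i: (self.windows[i][0], self.windows[i][1]))
        if order != list(range(len(self.windows))):
            self.windows = [self.windows[i] for i in order]
            self.residuals = self.residuals[:, order]

    def reference_mask(self) -> np.ndarray:
        ref = set(self.reference_cell_ids)
        return np.array([c in ref for c in self.cell_ids])


def estimate_cnv_residuals(
    norm,
    gene_positions: pd.DataFrame,
    reference_cells: Sequence[str],
    cell_ids: Sequence[str],
    window_size_genes: int = 10,
) -> CNVProfile:
    """Smoothing-based residual estimate from normalized expression.

    ``gene_positions`` has one row per gene with columns ``gene, chrom,
    start, end``; genes absent from it are dropped with a warning.  Each
    placed gene is centered by the reference-cell mean, clipped to ±3 SDs
    (computed over all cells), then moving-averaged over ``window_size_genes``
    consecutive genes in genomic order (windows are non-overlapping blocks);
    finally each cell is re-centered by its median.
    """
    import scipy.sparse as sp

    X = np.asarray(norm.todense()) if sp.issparse(norm) else np.asarray(norm, float)
    cell_ids = list(cell_ids)
    ref_set = set(reference_cells)
    ref_mask = np.array([c in ref_set for c in cell_ids])
    if ref_mask.sum() < 10:
        raise ValidationError("need at least 10 reference cells")
    n_genes_total = X.shape[1]
    if len(gene_positions) < n_genes_total:
        warnings.warn(f"{n_genes_total - len(gene_positions)} gene(s) unplaced; dropped")
    gp = gene_positions.sort_values(["chrom", "start"]).reset_index(drop=True)
    if "col" not in gp.columns:
        raise ValidationError("gene_positions must carry a 'col' column of matrix indices")
    cols = gp["col"].to_numpy(int)
    sub = X[:, cols]
    ref_mean = sub[ref_mask].mean(axis=0)
    # clip by the all-cell SD: the reference SD would flatten real aberrations
    sd = sub.std(axis=0, ddof=1)
    centered = sub - ref_mean
    lim = 3.0 * sd
    centered = np.clip(centered, -lim, lim)
    # non-overlapping windows of window_size_genes genes, per chromosome
    windows: list[tuple[str, int, int]] = []
    window_cols: list[np.ndarray] = []
    chroms = gp["chrom"].to_numpy()
    starts = gp["start"].to_numpy()
    ends = gp["end"].to_numpy()
    i = 0
    n = len(gp)
    while i < n:
        chrom = chroms[i]
        j = i
        while j < n and chroms[j] == chrom and j - i < window_size_genes:
            j += 1
        windows.append((chrom, int(starts[i]), int(ends[j - 1])))
        window_cols.append(np.arange(i, j))
        i = j
    res = np.column_stack([centered[:, c].mean(axis=1) for c in window_cols])
    res = res - np.median(res, axis=1, keepdims=True)
    return CNVProfile(
        residuals=res,
        windows=windows,
        cell_ids=cell_ids,
        reference_cell_ids=list(reference_cells),
    )


def cnv_score(profile: CNVProfile) -> pd.Series:
    """Per-cell CNV score: the quadratic sum of residuals over all windows."""
    scores = (profile.residuals ** 2).sum(axis=1)
    return pd.Series(scores, index=profile.cell_ids, name="cnv_score")


def call_malignant(scores: pd.Series, reference_cell_ids: Sequence[str]) -> pd.Series:
    """Malignant iff score > reference mean + 2 × reference sample SD."""
    ref = scores.loc[list(reference_cell_ids)]
    if len(ref) < 2:
        raise ValidationError("need at least 2 reference cells")
    sd = float(ref.std(ddof=1))
    if sd == 0:
        warnings.warn("reference scores have zero variance; threshold = mean")
    threshold = float(ref.mean()) + 2.0 * sd
    return pd.Series(scores.values > threshold, index=scores.index, name="is_malignant")


def _assign_windows_to_arms(
    windows: Sequence[tuple[str, int, int]], cytoband: CytobandTable
) -> list[tuple[str, str] | None]:
    """Arm of each window by majority overlap; None when off the cytoband map."""
    extents = cytoband.arm_extents()
    spans: dict[tuple[str, str], tuple[int, int]] = {
        (r.chrom, r.arm): (r.start, r.end) for r in extents.itertuples()
    }
    out = []
    for chrom, start, end in windows:
        best, best_ov = None, 0
        for arm in ("p", "q"):
            span = spans.get((chrom, arm))
            if span is None:
                continue
            ov = max(0, min(end, span[1]) - max(start, span[0]))
            # p wins exact ties via strict inequality order (p checked first)
            if ov > best_ov:
                best, best_ov = (chrom, arm), ov
        out.append(best)
    return out


def map_events_to_arms(
    profile: CNVProfile,
    cytoband: CytobandTable,
    gain_cut: float = GAIN_CUT,
    loss_cut: float = LOSS_CUT,
) -> list[frozenset]:
    """Per-cell arm-level event sets from mean residual per chromosome arm.

    An arm is gained when its mean residual exceeds ``gain_cut`` and lost
    below ``loss_cut``; arms with no assigned windows are skipped.
    """
    if gain_cut <= 0 or loss_cut >= 0:
        raise ValidationError("gain_cut must be > 0 and loss_cut < 0")
    arm_of = _assign_windows_to_arms(profile.windows, cytoband)
    arm_windows: dict[tuple[str, str], list[int]] = {}
    for wi, arm in enumerate(arm_of):
        if arm is not None:
            arm_windows.setdefault(arm, []).append(wi)
    events: list[frozenset] = []
    R = profile.residuals
    arm_means = {
        arm: R[:, idx].mean(axis=1) for arm, idx in arm_windows.items()
    }
    for ci in range(R.shape[0]):
        ev = set()
        for (chrom, arm), means in arm_means.items():
            m = means[ci]
            if m > gain_cut:
                ev.add(ArmEvent(chrom, arm, "gain"))
            elif m < loss_cut:
                ev.add(ArmEvent(chrom, arm, "loss"))
        events.append(frozenset(ev))
    return events


@dataclass(frozen=True)
class Subclone:
    events: frozenset
    n_cells: int
    fraction: float

    def label(self) -> str:
        return _event_set_label(self.events)


def _event_label(ev: ArmEvent) -> str:
    sign = "+" if ev.direction == "gain" else "-"
    chrom = ev.chrom[3:] if ev.chrom.startswith("chr") else ev.chrom
    return f"{chrom}{ev.arm}{sign}"


def _event_set_label(events: frozenset) -> str:
    """'|'-joined labels like ``5q+|7+``; whole-chromosome events collapse p|q."""
    if not events:
        return "root"
    by_chrom_dir: dict[tuple[str, str], set[str]] = {}
    for ev in events:
        by_chrom_dir.setdefault((ev.chrom, ev.direction), set()).add(ev.arm)
    parts = []
    for (chrom, direction), arms in by_chrom_dir.items():
        sign = "+" if direction == "gain" else "-"
        name = chrom[3:] if chrom.startswith("chr") else chrom
        if arms == {"p", "q"}:
            parts.append(f"{name}{sign}")
        else:
            parts.extend(f"{name}{a}{sign}" for a in sorted(arms))
    return "|".join(sorted(parts))


def collapse_subclones(event_sets: Sequence[frozenset]) -> list[Subclone]:
    """Group cells by exact event-set equality into subclones.

    Fractions are over all input cells and sum to 1.  Subclones are returned
    sorted by descending cell count, then label.
    """
    if not event_sets:
        raise ValidationError("no cells")
    counts: dict[frozenset, int] = {}
    for ev in event_sets:
        counts[frozenset(ev)] = counts.get(frozenset(ev), 0) + 1
    total = len(event_sets)
    subs = [
        Subclone(events=ev, n_cells=n, fraction=n / total) for ev, n in counts.items()
    ]
    subs.sort(key=lambda s: (-s.n_cells, s.label()))
    return subs


@dataclass
class ClonalTree:
    """Subclone nodes with strict event-set inclusion edges."""

    nodes: list[Subclone]
    parent: dict[int, int | None]  # node index -> parent index (None for root)

    def children(self, idx: int) -> list[int]:
        return [i for i, p in self.parent.items() if p == idx]

    @property
    def root_index(self) -> int:
        for i, p in self.parent.items():
            if p is None:
                return i
        raise ValidationError("tree has no root")


def build_clonal_tree(subclones: Sequence[Subclone]) -> ClonalTree:
    """Arrange subclones into a tree by strict event-set inclusion.

    Each node's parent is the subclone whose event set is the largest proper
    subset of its own (ties broken by larger fraction, then lexicographically
    smallest event-set label); subclones with no proper subset among the
    nodes attach to the root (the empty event set, added with fraction 0 when
    absent).
    """
    nodes = list(subclones)
    if not any(len(s.events) == 0 for s in nodes):
        nodes.append(Subclone(events=frozenset(), n_cells=0, fraction=0.0))
    root_idx = next(i for i, s in enumerate(nodes) if len(s.events) == 0)
    parent: dict[int, int | None] = {root_idx: None}
    for i, s in enumerate(nodes):
        if i == root_idx:
            continue
        candidates = [
            (j, t)
            for j, t in enumerate(nodes)
            if j != i and t.events < s.events
        ]
        if not candidates:
            parent[i] = root_idx
            continue
        candidates.sort(key=lambda jt: (-len(jt[1].events), -jt[1].fraction, jt[1].label()))
        parent[i] = candidates[0][0]
    return ClonalTree(nodes=nodes, parent=parent)


def serialize_newick(tree: ClonalTree) -> str:
    """Newick string: node label = event-set label, branch length = fraction."""

    def render(idx: int) -> str:
        kids = sorted(tree.children(idx), key=lambda j: tree.nodes[j].label())
        node = tree.nodes[idx]
        length = 0.0 if tree.parent[idx] is None else node.fraction
        body = (
            "(" + ",".join(render(k) for k in kids) + ")" if kids else ""
        )
        if tree.parent[idx] is None:
            return f"{body}{node.label()}:0"
        return f"{body}{node.label()}:{length:.4f}"

    return render(tree.root_index) + ";"
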