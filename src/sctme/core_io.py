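"""Data model and readers/writers for every external format the pipeline touches.

The central container is :class:`ExpressionDataset`: a sparse cells × genes UMI
count matrix with per-cell metadata (sample, group, cluster) and an optional
log-normalized layer.  On-disk representation follows the 10x triplet dialect
(MatrixMarket matrix + features.tsv + barcodes.tsv) plus a tab-separated
metadata table.  Gene sets travel as GMT, genomic arms as UCSC cytoBand TSV,
ligand–receptor pairs as a three-column CSV with '+'-joined receptor subunits.

Coordinates are 0-based half-open throughout; matrices are cells-as-rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "VALID_GROUPS",
    "ValidationError",
    "FormatError",
    "ExpressionDataset",
    "GeneSetCollection",
    "CytobandTable",
    "LRPair",
    "LRDatabase",
    "read_dataset",
    "write_dataset",
    "read_gmt",
    "read_cytoband",
    "read_lr_pairs",
]

#: Closed vocabulary for the per-cell ``group`` label.
VALID_GROUPS = ("MPLC_Tumour", "MPLC_Normal", "SPLC_Tumour", "SPLC_Normal")

META_REQUIRED = ("cell_id", "sample_id", "group", "cluster")


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _check_unique(values: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class ExpressionDataset:
    """Sparse UMI counts with aligned per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells × genes (any scipy sparse or dense
        array; stored as CSR).
    gene_ids, cell_ids
        Ordered, unique identifier lists matching the matrix axes.
    meta
        One row per cell, indexed by cell id, with at least ``sample_id``,
        ``group`` (one of :data:`VALID_GROUPS`) and ``cluster`` columns.
    norm
        Optional natural-log normalized layer of the same shape.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    meta: pd.DataFrame
    norm: Optional[sp.csr_matrix] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {n_genes} genes but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cells} cells but {len(self.cell_ids)} barcodes"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "barcode")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ValidationError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts contain non-integral entries")
        if list(self.meta.index) != self.cell_ids:
            # allow unordered meta keyed by cell id
            missing = set(self.cell_ids) - set(self.meta.index)
            if missing:
                raise ValidationError(
                    f"meta missing {len(missing)} cells, e.g. {sorted(missing)[:3]}"
                )
            if len(self.meta) != len(self.cell_ids):
                raise ValidationError("meta must have exactly one record per cell")
            self.meta = self.meta.loc[self.cell_ids]
        for col in ("sample_id", "group", "cluster"):
            if col not in self.meta.columns:
                raise ValidationError(f"meta lacks required column {col!r}")
        bad = set(self.meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(
                f"unknown group label(s) {sorted(bad)}; expected one of {VALID_GROUPS}"
            )
        if self.norm is not None:
            if self.norm.shape != self.counts.shape:
                raise ValidationError("norm layer shape differs from counts")

    # convenience -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def subset_cells(self, keep: Sequence[str]) -> "ExpressionDataset":
        """Return a new dataset restricted to ``keep`` (order preserved)."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([pos[c] for c in keep], dtype=int)
        return ExpressionDataset(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            meta=self.meta.iloc[idx].copy(),
            norm=None if self.norm is None else self.norm[idx],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene in set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class CytobandTable:
    """UCSC-style cytoband records; 0-based half-open coordinates."""

    records: pd.DataFrame  # columns chrom, start, end, band

    def __post_init__(self) -> None:
        df = self.records
        for col in ("chrom", "start", "end", "band"):
            if col not in df.columns:
                raise ValidationError(f"cytoband table lacks column {col!r}")
        if not df["band"].str.match(r"^[pq]").all():
            bad = df.loc[~df["band"].str.match(r"^[pq]"), "band"].iloc[0]
            raise ValidationError(f"cytoband band {bad!r} does not start with p or q")
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if (sub["end"].values[:-1] > sub["start"].values[1:]).any():
                raise ValidationError(f"overlapping bands on {chrom}")
        self.records = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    def arm_extents(self) -> pd.DataFrame:
        """Per (chrom, arm) genomic span: columns chrom, arm, start, end."""
        df = self.records.copy()
        df["arm"] = df["band"].str[0]
        g = df.groupby(["chrom", "arm"], sort=True).agg(
            start=("start", "min"), end=("end", "max")
        )
        return g.reset_index()


@dataclass(frozen=True)
class LRPair:
    pair_name: str
    ligand: str
    receptor_subunits: tuple[str, ...]


@dataclass
class LRDatabase:
    """Curated ligand–receptor pairs; multi-subunit receptors supported."""

    pairs: list[LRPair]

    def __post_init__(self) -> None:
        _check_unique([p.pair_name for p in self.pairs], "pair name")
        for p in self.pairs:
            if not p.receptor_subunits:
                raise ValidationError(f"pair {p.pair_name!r} has no receptor subunits")

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_id_column(path: str) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_dataset(
    matrix_path: str,
    features_path: str,
    barcodes_path: str,
    meta_path: str,
) -> ExpressionDataset:
    """Load a dataset from MatrixMarket + features + barcodes + metadata files.

    The matrix is stored cells-as-rows; cell order follows the barcodes file.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed MatrixMarket
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_id_column(features_path)
    cells = _read_id_column(barcodes_path)
    if mat.shape != (len(cells), len(genes)):
        raise FormatError(
            f"matrix is {mat.shape} but barcodes/features give "
            f"({len(cells)}, {len(genes)})"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    for col in META_REQUIRED:
        if col not in meta.columns:
            raise FormatError(f"meta table lacks required column {col!r}")
    meta = meta.set_index("cell_id")
    return ExpressionDataset(
        counts=sp.csr_matrix(mat), gene_ids=genes, cell_ids=cells, meta=meta
    )


def write_dataset(dataset: ExpressionDataset, out_dir: str) -> dict[str, str]:
    """Write matrix.mtx / features.tsv / barcodes.tsv / meta.tsv into ``out_dir``.

    Returns the mapping of role → path; output is readable by
    :func:`read_dataset`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "features": os.path.join(out_dir, "features.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "meta": os.path.join(out_dir, "meta.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(dataset.counts), field="integer")
    with open(paths["features"], "w") as fh:
        fh.writelines(g + "\n" for g in dataset.gene_ids)
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(c + "\n" for c in dataset.cell_ids)
    meta = dataset.meta.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "cell_id"})
    meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: gene set has no genes")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{ln}: duplicate set name {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def read_cytoband(path: str) -> CytobandTable:
    """Parse a UCSC cytoBand TSV (chrom, start, end, band, stain)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "start": int, "end": int, "band": str, "stain": str},
    )
    return CytobandTable(df[["chrom", "start", "end", "band"]])


def read_lr_pairs(path: str) -> LRDatabase:
    """Parse a ligand–receptor CSV: pair_name, ligand, receptor.

    Receptor complexes are '+'-joined, e.g. ``CD74+CD44``.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("pair_name", "ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"LR table lacks column {col!r}")
    pairs = [
        LRPair(
            pair_name=row.pair_name,
            ligand=row.ligand,
            receptor_subunits=tuple(s for s in row.receptor.split("+") if s),
        )
        for row in df.itertuples()
    ]
    return LRDatabase(pairs)
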