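"""Tables and on-disk formats for the deconvolution pipeline.

Three table kinds flow through the pipeline:

* a single-cell reference (cells x genes counts plus per-cell type labels),
* a spot dataset (spots x genes expression plus 2-D spot coordinates),
* a proportion matrix (spots x cell-types, rows on the probability simplex).

Expression matrices are CSV (spots/cells as rows, header = gene ids) or
Matrix Market with plain-text id sidecars; coordinates and labels are CSV.
Gzip is handled transparently by file extension.  All ids are opaque,
case-sensitive strings; alignment is always by id, never by position.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SchemaError",
    "ValidationError",
    "CellReference",
    "SpotDataset",
    "ProportionMatrix",
    "read_spot_dataset",
    "read_cell_reference",
    "read_proportions",
    "write_spot_dataset",
    "write_cell_reference",
    "write_proportions",
]


class SchemaError(ValueError):
    """A file does not match the expected table schema."""


class ValidationError(ValueError):
    """An in-memory table violates a structural invariant."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class CellReference:
    """Cells x genes count matrix with a cell-type label per cell."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_types = [str(t) for t in self.cell_types]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (cells x genes)")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.cell_types) != n_cells:
            raise ValidationError("cell_ids/cell_types length must match counts rows")
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids length must match counts columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene_ids in reference")
        if n_cells == 0:
            raise ValidationError("reference has no cells")
        if np.any(self.counts < 0):
            raise ValidationError("negative entries in reference counts")

    @property
    def type_names(self) -> list[str]:
        """Cell-type vocabulary in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.cell_types:
            seen.setdefault(t, None)
        return list(seen)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class SpotDataset:
    """Spots x genes expression with 2-D spot coordinates."""

    expr: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    domain_tag: str = "simulated"

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.expr.ndim != 2:
            raise ValidationError("expr must be 2-D (spots x genes)")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must have exactly 2 columns")
        if self.coords.shape[0] != self.expr.shape[0]:
            raise ValidationError("one coordinate row required per spot")
        if len(self.spot_ids) != self.expr.shape[0]:
            raise ValidationError("spot_ids length must match expr rows")
        if len(self.gene_ids) != self.expr.shape[1]:
            raise ValidationError("gene_ids length must match expr columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids in spot dataset")
        if self.domain_tag not in ("simulated", "real"):
            raise ValidationError("domain_tag must be 'simulated' or 'real'")
        if np.any(self.expr < 0):
            raise ValidationError("negative entries in spot expression")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    def subset(self, idx) -> "SpotDataset":
        idx = np.asarray(idx)
        return SpotDataset(
            self.expr[idx],
            list(self.gene_ids),
            [self.spot_ids[i] for i in idx],
            self.coords[idx],
            self.domain_tag,
        )


@dataclass
class ProportionMatrix:
    """Spots x cell-types matrix; every row lies on the probability simplex."""

    values: np.ndarray
    cell_type_names: list[str]
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_type_names = [str(t) for t in self.cell_type_names]
        if self.values.ndim != 2:
            raise ValidationError("proportions must be 2-D (spots x cell types)")
        if len(self.cell_type_names) != self.values.shape[1]:
            raise ValidationError("cell_type_names length must match columns")
        if not self.spot_ids:
            self.spot_ids = [f"spot{i}" for i in range(self.values.shape[0])]
        if len(self.spot_ids) != self.values.shape[0]:
            raise ValidationError("spot_ids length must match rows")
        if np.any(self.values < 0):
            raise ValidationError("negative proportion entries")
        sums = self.values.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValidationError(
                f"proportion row {bad[0]} sums to {sums[bad[0]]:.6f}, not 1"
            )

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "ProportionMatrix":
        idx = np.asarray(idx)
        return ProportionMatrix(
            self.values[idx],
            list(self.cell_type_names),
            [self.spot_ids[i] for i in idx],
        )


# --------------------------------------------------------------------------
# readers


def _read_matrix(path: str | Path, genes_as_rows: bool = False):
    """Read an expression matrix from CSV or Matrix Market + sidecars.

    Returns (matrix, row_ids, col_ids) with rows = observations and
    columns = genes after the optional transpose.
    """
    path = Path(path)
    suffixes = path.suffixes
    is_mtx = ".mtx" in suffixes
    if is_mtx:
        raw = spio.mmread(str(path))
        mat = np.asarray(raw.todense() if sparse.issparse(raw) else raw, dtype=np.float64)
        stem = str(path)
        for ext in (".mtx.gz", ".mtx"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
                break
        row_ids = _read_id_file(stem + ".rows.txt")
        col_ids = _read_id_file(stem + ".cols.txt")
    else:
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=np.float64)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    if len(row_ids) != mat.shape[0] or len(col_ids) != mat.shape[1]:
        raise SchemaError(
            f"{path}: id sidecars ({len(row_ids)} x {len(col_ids)}) do not match "
            f"matrix shape {mat.shape}"
        )
    if genes_as_rows:
        mat = mat.T
        row_ids, col_ids = col_ids, row_ids
    return mat, row_ids, col_ids


def _read_id_file(path: str | Path) -> list[str]:
    path = Path(path)
    candidates = [path, Path(str(path) + ".gz")]
    for cand in candidates:
        if cand.exists():
            opener = gzip.open if cand.suffix == ".gz" else open
            with opener(cand, "rt") as fh:
                return [line.strip() for line in fh if line.strip()]
    raise SchemaError(f"missing id sidecar file: {path}")


def read_spot_dataset(
    expr_path: str | Path,
    coords_path: str | Path,
    domain_tag: str = "real",
    genes_as_rows: bool = False,
) -> SpotDataset:
    """Read a spot dataset from an expression table and a coordinate CSV.

    The coordinate file needs columns ``spot_id,x,y``; its rows are aligned
    to the expression table by spot id.
    """
    expr, spot_ids, gene_ids = _read_matrix(expr_path, genes_as_rows)
    coords_df = pd.read_csv(coords_path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise SchemaError(
            f"{coords_path}: expected columns spot_id,x,y; got {list(coords_df.columns)}"
        )
    coords_df = coords_df.astype({"spot_id": str}).set_index("spot_id")
    if coords_df.index.has_duplicates:
        dup = coords_df.index[coords_df.index.duplicated()][0]
        raise SchemaError(f"{coords_path}: duplicate spot_id {dup!r}")
    missing = [s for s in spot_ids if s not in coords_df.index]
    if missing:
        raise SchemaError(f"{coords_path}: no coordinates for spot_id {missing[0]!r}")
    coords = coords_df.loc[spot_ids, ["x", "y"]].to_numpy(dtype=np.float64)
    return SpotDataset(expr, gene_ids, spot_ids, coords, domain_tag)


def read_cell_reference(
    counts_path: str | Path,
    labels_path: str | Path,
    genes_as_rows: bool = False,
) -> CellReference:
    """Read a single-cell reference; labels CSV has columns cell_id,cell_type."""
    counts, cell_ids, gene_ids = _read_matrix(counts_path, genes_as_rows)
    labels_df = pd.read_csv(labels_path)
    if not {"cell_id", "cell_type"}.issubset(labels_df.columns):
        raise SchemaError(
            f"{labels_path}: expected columns cell_id,cell_type; got {list(labels_df.columns)}"
        )
    if labels_df.empty:
        raise ValidationError(f"{labels_path}: empty label file")
    labels_df = labels_df.astype({"cell_id": str, "cell_type": str})
    unknown = set(labels_df["cell_id"]) - set(cell_ids)
    if unknown:
        raise SchemaError(f"{labels_path}: unknown cell_id {sorted(unknown)[0]!r}")
    label_map = dict(zip(labels_df["cell_id"], labels_df["cell_type"]))
    missing = [c for c in cell_ids if c not in label_map]
    if missing:
        raise SchemaError(f"{labels_path}: no label for cell_id {missing[0]!r}")
    cell_types = [label_map[c] for c in cell_ids]
    return CellReference(counts, gene_ids, cell_ids, cell_types)


def read_proportions(path: str | Path) -> ProportionMatrix:
    """Read a proportion matrix CSV (spot_id index, cell-type header)."""
    df = pd.read_csv(path, index_col=0)
    return ProportionMatrix(
        df.to_numpy(dtype=np.float64),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


# --------------------------------------------------------------------------
# writers


def write_spot_dataset(ds: SpotDataset, expr_path: str | Path, coords_path: str | Path) -> None:
    pd.DataFrame(ds.expr, index=ds.spot_ids, columns=ds.gene_ids).to_csv(
        expr_path, index_label="spot_id"
    )
    pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    ).to_csv(coords_path, index=False)


def write_cell_reference(ref: CellReference, counts_path: str | Path, labels_path: str | Path) -> None:
    pd.DataFrame(ref.counts, index=ref.cell_ids, columns=ref.gene_ids).to_csv(
        counts_path, index_label="cell_id"
    )
    pd.DataFrame({"cell_id": ref.cell_ids, "cell_type": ref.cell_types}).to_csv(
        labels_path, index=False
    )


def write_proportions(p: ProportionMatrix, path: str | Path) -> None:
    """Write a proportion matrix as CSV; read-back equals input within 1e-9."""
    # __post_init__ already enforced the simplex constraint on construction.
    sums = p.values.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValidationError("proportion rows must sum to 1")
    pd.DataFrame(p.values, index=p.spot_ids, columns=p.cell_type_names).to_csv(
        path, index_label="spot_id", float_format="%.12g"
    )
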