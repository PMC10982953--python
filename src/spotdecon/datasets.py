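"""Core data containers and file I/O.

The package works with four kinds of expression tables:

* :class:`SingleCellDataset` — cells × genes counts with a cell-type label
  per cell (the scRNA-seq reference).
* :class:`SpatialDataset` — spots × genes counts with optional 2-D spot
  coordinates (the ST slide to deconvolve, or a reference slide for
  simulation).
* :class:`CellTypeProfile` — cell types × genes aggregate profiles (the
  ``C`` matrix of the deconvolution model).
* :class:`StackedMatrix` — the ``X = [C; S]`` matrix fed to the graph
  network, with a role flag per row.

All matrices are dense ``float64`` numpy arrays; gene identifiers are
opaque strings matched exactly and case-sensitively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SingleCellDataset",
    "SpatialDataset",
    "CellTypeProfile",
    "StackedMatrix",
    "SimulatedSpatialDataset",
    "read_single_cell",
    "read_spatial",
    "write_single_cell",
    "write_spatial",
]


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    if (arr < 0).any():
        raise ValueError(f"{name} contains negative entries")
    return arr


def _as_str_array(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=object)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(f"{name} must be 1-D of length {n}")
    return arr.astype(str)


def _check_unique(names: np.ndarray, what: str) -> None:
    if len(set(names)) != len(names):
        dupes = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class SingleCellDataset:
    """Non-negative cells × genes matrix with one cell-type label per cell."""

    counts: np.ndarray
    cell_types: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = _as_float_matrix(self.counts, "counts")
        n, g = self.counts.shape
        self.cell_types = _as_str_array(self.cell_types, n, "cell_types")
        self.gene_names = _as_str_array(self.gene_names, g, "gene_names")
        self.cell_ids = _as_str_array(self.cell_ids, n, "cell_ids")
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.cell_ids, "cell ids")
        if n == 0 or g == 0:
            raise ValueError("empty single-cell dataset")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def type_names(self) -> np.ndarray:
        """Distinct cell-type labels in order of first appearance."""
        return pd.unique(pd.Series(self.cell_types)).astype(str)

    def subset_cells(self, mask: np.ndarray) -> "SingleCellDataset":
        return SingleCellDataset(
            self.counts[mask], self.cell_types[mask],
            self.gene_names, self.cell_ids[mask],
        )

    def subset_genes(self, mask_or_names) -> "SingleCellDataset":
        idx = _gene_indexer(self.gene_names, mask_or_names)
        return SingleCellDataset(
            self.counts[:, idx], self.cell_types,
            self.gene_names[idx], self.cell_ids,
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts,
            obs=pd.DataFrame({"cell_type": self.cell_types},
                             index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.gene_names.astype(str)),
        )
        return adata


@dataclass
class SpatialDataset:
    """Non-negative spots × genes matrix with optional (x, y) coordinates."""

    counts: np.ndarray
    gene_names: np.ndarray
    spot_ids: np.ndarray
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = _as_float_matrix(self.counts, "counts")
        n, g = self.counts.shape
        self.gene_names = _as_str_array(self.gene_names, g, "gene_names")
        self.spot_ids = _as_str_array(self.spot_ids, n, "spot_ids")
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.spot_ids, "spot ids")
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=np.float64)
            if coords.shape != (n, 2):
                raise ValueError(
                    f"coordinates must be ({n}, 2), got {coords.shape}")
            if not np.all(np.isfinite(coords)):
                raise ValueError("coordinates contain non-finite values")
            self.coordinates = coords
        if n == 0 or g == 0:
            raise ValueError("empty spatial dataset")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, mask: np.ndarray) -> "SpatialDataset":
        coords = None if self.coordinates is None else self.coordinates[mask]
        return SpatialDataset(self.counts[mask], self.gene_names,
                              self.spot_ids[mask], coords)

    def subset_genes(self, mask_or_names) -> "SpatialDataset":
        idx = _gene_indexer(self.gene_names, mask_or_names)
        return SpatialDataset(self.counts[:, idx], self.gene_names[idx],
                              self.spot_ids, self.coordinates)

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts,
            obs=pd.DataFrame(index=self.spot_ids.astype(str)),
            var=pd.DataFrame(index=self.gene_names.astype(str)),
        )
        if self.coordinates is not None:
            adata.obsm["spatial"] = self.coordinates.copy()
        return adata


@dataclass
class CellTypeProfile:
    """Cell types × genes aggregate expression (the ``C`` matrix).

    ``marker_sets`` maps each type to its ordered marker gene list; the
    profile's gene set is the union of those markers (optionally
    intersected with the ST gene set downstream).
    """

    profile: np.ndarray
    type_names: np.ndarray
    gene_names: np.ndarray
    marker_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profile = _as_float_matrix(self.profile, "profile")
        m, g = self.profile.shape
        self.type_names = _as_str_array(self.type_names, m, "type_names")
        self.gene_names = _as_str_array(self.gene_names, g, "gene_names")
        _check_unique(self.type_names, "type names")
        _check_unique(self.gene_names, "gene names")

    @property
    def n_types(self) -> int:
        return self.profile.shape[0]

    def subset_genes(self, mask_or_names) -> "CellTypeProfile":
        idx = _gene_indexer(self.gene_names, mask_or_names)
        return CellTypeProfile(self.profile[:, idx], self.type_names,
                               self.gene_names[idx], self.marker_sets)


@dataclass
class StackedMatrix:
    """``X = [C; S]`` over the common genes, with a role flag per row.

    The first ``m`` rows are cell-type profiles, the remaining ``n`` rows
    are spots; both blocks share an identical gene column order.
    """

    X: np.ndarray
    node_roles: np.ndarray  # "celltype" | "spot" per row
    gene_names: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        r, g = self.X.shape
        self.node_roles = _as_str_array(self.node_roles, r, "node_roles")
        self.gene_names = _as_str_array(self.gene_names, g, "gene_names")
        roles = set(self.node_roles)
        if not roles <= {"celltype", "spot"}:
            raise ValueError(f"unknown node roles: {roles}")
        m = int((self.node_roles == "celltype").sum())
        if not (self.node_roles[:m] == "celltype").all():
            raise ValueError("cell-type rows must precede spot rows")

    @property
    def n_celltypes(self) -> int:
        return int((self.node_roles == "celltype").sum())

    @property
    def n_spots(self) -> int:
        return int((self.node_roles == "spot").sum())


@dataclass
class SimulatedSpatialDataset:
    """A simulated ST slide with its per-spot ground truth.

    ``proportions`` is a spots × cell-types DataFrame whose rows sum to 1;
    ``cell_assignment`` lists, per spot, the ids of the source cells pooled
    into it; ``provenance`` records the simulator name, seed and
    parameters so a run can be reproduced exactly.
    """

    counts: np.ndarray
    coordinates: np.ndarray
    proportions: pd.DataFrame
    gene_names: np.ndarray
    spot_ids: np.ndarray
    cell_assignment: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = _as_float_matrix(self.counts, "counts")
        n = self.counts.shape[0]
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.shape != (n, 2):
            raise ValueError("coordinates must be (n_spots, 2)")
        if self.proportions.shape[0] != n:
            raise ValueError("proportions row count mismatch")
        rs = self.proportions.to_numpy().sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-8):
            raise ValueError("proportion rows must sum to 1")
        if len(self.cell_assignment) != n:
            raise ValueError("cell_assignment length mismatch")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    def to_spatial(self) -> SpatialDataset:
        """Drop the ground truth, keeping counts + coordinates."""
        return SpatialDataset(self.counts, self.gene_names,
                              self.spot_ids, self.coordinates)


def _gene_indexer(gene_names: np.ndarray, mask_or_names) -> np.ndarray:
    arr = np.asarray(mask_or_names)
    if arr.dtype == bool:
        return np.where(arr)[0]
    pos = pd.Index(gene_names).get_indexer(arr.astype(str))
    if (pos < 0).any():
        missing = arr[pos < 0][:5].tolist()
        raise KeyError(f"unknown genes requested: {missing}")
    return pos


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_any(path: str, label_column: Optional[str], transpose: bool):
    """Return (matrix, row_ids, col_ids, labels_or_None) from h5ad, an MTX
    directory/prefix, or a dense CSV/TSV (rows = cells/spots)."""
    if path.endswith(".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        labels = None
        if label_column is not None:
            if label_column not in adata.obs:
                raise KeyError(
                    f"label column {label_column!r} not in obs of {path}")
            labels = adata.obs[label_column].astype(str).to_numpy()
        return (np.asarray(X, dtype=np.float64),
                adata.obs_names.to_numpy().astype(str),
                adata.var_names.to_numpy().astype(str), labels)
    if os.path.isdir(path):
        from scipy.io import mmread

        mtx = mmread(os.path.join(path, "matrix.mtx")).toarray()
        genes = pd.read_csv(os.path.join(path, "genes.tsv"),
                            sep="\t", header=None)[0].astype(str).to_numpy()
        barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"),
                               sep="\t", header=None)[0].astype(str).to_numpy()
        # MTX convention: genes × cells; transpose to cells × genes
        X = np.asarray(mtx, dtype=np.float64).T
        return X, barcodes, genes, None
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels = None
    if label_column is not None and label_column in df.columns:
        labels = df[label_column].astype(str).to_numpy()
        df = df.drop(columns=[label_column])
    X = df.to_numpy(dtype=np.float64)
    if transpose:
        X, rows, cols = X.T, df.columns.to_numpy(), df.index.to_numpy()
    else:
        rows, cols = df.index.to_numpy(), df.columns.to_numpy()
    return X, rows.astype(str), cols.astype(str), labels


def read_single_cell(path: str, label_column: str = "cell_type",
                     labels_path: Optional[str] = None,
                     transpose: bool = False) -> SingleCellDataset:
    """Read an scRNA-seq matrix from h5ad / MTX triplet / dense CSV-TSV.

    For formats without embedded labels, ``labels_path`` points to a
    one-column (or id,label two-column) CSV/TSV of per-cell labels.
    """
    X, cell_ids, gene_names, labels = _read_matrix_any(
        path, label_column, transpose)
    if labels is None:
        if labels_path is None:
            raise ValueError(
                "cell-type labels required: embed them in the matrix file "
                "or pass labels_path")
        sep = "\t" if labels_path.endswith((".tsv", ".txt")) else ","
        lab_df = pd.read_csv(labels_path, sep=sep, header=None)
        labels = lab_df.iloc[:, -1].astype(str).to_numpy()
        if len(labels) != len(cell_ids):
            raise ValueError("label file length mismatch")
    return SingleCellDataset(X, labels, gene_names, cell_ids)


def read_spatial(path: str, coords_path: Optional[str] = None,
                 transpose: bool = False) -> SpatialDataset:
    """Read an ST matrix; coordinates come from ``obsm['spatial']`` in h5ad
    or from a CSV/TSV with columns (id, x, y)."""
    coords = None
    if path.endswith(".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=np.float64)
        return SpatialDataset(np.asarray(X, dtype=np.float64),
                              adata.var_names.to_numpy().astype(str),
                              adata.obs_names.to_numpy().astype(str), coords)
    X, spot_ids, gene_names, _ = _read_matrix_any(path, None, transpose)
    if coords_path is not None:
        sep = "\t" if coords_path.endswith((".tsv", ".txt")) else ","
        cdf = pd.read_csv(coords_path, sep=sep, index_col=0)
        coords = cdf.loc[spot_ids].iloc[:, :2].to_numpy(dtype=np.float64)
    return SpatialDataset(X, gene_names, spot_ids, coords)


def write_single_cell(sc: SingleCellDataset, path: str) -> None:
    if path.endswith(".h5ad"):
        sc.to_anndata().write_h5ad(path)
        return
    df = pd.DataFrame(sc.counts, index=sc.cell_ids, columns=sc.gene_names)
    df.insert(0, "cell_type", sc.cell_types)
    df.to_csv(path)


def write_spatial(st: SpatialDataset, path: str,
                  coords_path: Optional[str] = None) -> None:
    if path.endswith(".h5ad"):
        st.to_anndata().write_h5ad(path)
        return
    pd.DataFrame(st.counts, index=st.spot_ids,
                 columns=st.gene_names).to_csv(path)
    if coords_path is not None and st.coordinates is not None:
        pd.DataFrame(st.coordinates, index=st.spot_ids,
                     columns=["x", "y"]).to_csv(coords_path)
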