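"""Quality control, normalization, marker selection and matrix stacking.

The pipeline order is: QC filters → per-cell normalization (scRNA only,
ST kept raw) → one-vs-rest marker ranking (top-200 per type by default) →
aggregation of normalized cells into the cell-type profile ``C`` → gene
alignment and stacking of ``C`` over the ST matrix ``S`` into ``X``.

Marker ranking uses a one-vs-rest Wilcoxon rank-sum z-score on
log1p-transformed normalized expression: standard for scRNA marker
detection and fully deterministic (ties broken by gene index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import (CellTypeProfile, SingleCellDataset, SpatialDataset,
                       StackedMatrix)

__all__ = [
    "apply_qc_filters",
    "normalize_cells",
    "select_marker_genes",
    "build_celltype_profile",
    "align_and_stack",
    "preprocess_pipeline",
]


class QCError(ValueError):
    """A QC filter removed every cell, spot or gene."""


def _mito_fraction(counts: np.ndarray, gene_names: np.ndarray) -> np.ndarray:
    is_mt = np.array([g.startswith(("MT-", "mt-")) for g in gene_names])
    total = counts.sum(axis=1)
    total[total == 0] = 1.0
    return counts[:, is_mt].sum(axis=1) / total


def apply_qc_filters(
    sc: SingleCellDataset,
    st: SpatialDataset,
    min_genes: int = 5,
    min_cells_per_gene: int = 1,
    min_cells_per_type: int = 2,
    mito_fraction_max: float = 0.2,
) -> Tuple[SingleCellDataset, SpatialDataset]:
    """Filter cells, spots, genes and underpopulated cell types.

    Retained cells/spots express at least ``min_genes`` genes; retained
    genes are detected in at least ``min_cells_per_gene`` cells (resp.
    spots); cell types with fewer than ``min_cells_per_type`` cells are
    dropped with their cells; cells whose mitochondrial count fraction
    (genes prefixed ``MT-``/``mt-``) exceeds ``mito_fraction_max`` are
    dropped. The two datasets are filtered independently; the operation is
    idempotent.
    """
    # --- scRNA side ---
    keep_cells = (sc.counts > 0).sum(axis=1) >= min_genes
    keep_cells &= _mito_fraction(sc.counts, sc.gene_names) <= mito_fraction_max
    if not keep_cells.any():
        raise QCError("all cells removed (min_genes / mito filter)")
    sc = sc.subset_cells(keep_cells)
    vc = pd.Series(sc.cell_types).value_counts()
    good_types = set(vc[vc >= min_cells_per_type].index)
    if not good_types:
        raise QCError("all cell types removed (min_cells_per_type filter)")
    sc = sc.subset_cells(np.array([t in good_types for t in sc.cell_types]))
    keep_genes_sc = (sc.counts > 0).sum(axis=0) >= min_cells_per_gene
    if not keep_genes_sc.any():
        raise QCError("all scRNA genes removed (min_cells_per_gene filter)")
    sc = sc.subset_genes(keep_genes_sc)
    # a gene drop cannot re-trigger the cell filter at min_cells_per_gene=1,
    # but re-check so the composite is idempotent for any threshold
    still = (sc.counts > 0).sum(axis=1) >= min_genes
    if not still.any():
        raise QCError("all cells removed after gene filtering")
    sc = sc.subset_cells(still)

    # --- ST side ---
    keep_spots = (st.counts > 0).sum(axis=1) >= min_genes
    if not keep_spots.any():
        raise QCError("all spots removed (min_genes filter)")
    st = st.subset_spots(keep_spots)
    keep_genes_st = (st.counts > 0).sum(axis=0) >= min_cells_per_gene
    if not keep_genes_st.any():
        raise QCError("all ST genes removed (min_cells_per_gene filter)")
    st = st.subset_genes(keep_genes_st)
    still = (st.counts > 0).sum(axis=1) >= min_genes
    if not still.any():
        raise QCError("all spots removed after gene filtering")
    st = st.subset_spots(still)
    return sc, st


def normalize_cells(sc: SingleCellDataset) -> SingleCellDataset:
    """Scale each cell so its expression sums to 1 (library-size
    normalization; within-cell proportions are preserved)."""
    sums = sc.counts.sum(axis=1)
    if (sums == 0).any():
        bad = sc.cell_ids[sums == 0][:5].tolist()
        raise ValueError(f"all-zero cells present (run QC first): {bad}")
    return SingleCellDataset(sc.counts / sums[:, None], sc.cell_types,
                             sc.gene_names, sc.cell_ids)


def _wilcoxon_z(expr: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized one-vs-rest Wilcoxon rank-sum z per gene column.

    Positive z means higher expression inside the group. Tie correction
    is omitted (only the ordering matters for marker selection).
    """
    n1 = int(in_group.sum())
    n2 = expr.shape[0] - n1
    ranks = rankdata(expr, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (r1 - mu) / sigma


def select_marker_genes(sc: SingleCellDataset, top_n: int = 200,
                        fraction: Optional[float] = None
                        ) -> Dict[str, list]:
    """Rank genes per cell type one-vs-rest; return ordered marker lists.

    ``fraction`` (e.g. 0.05) overrides ``top_n`` with a per-type count
    proportional to that type's number of detectable genes. Types with
    fewer expressed genes than requested contribute all of them.
    """
    types = sc.type_names
    if len(types) < 2:
        raise ValueError("marker selection requires >= 2 cell types")
    logx = np.log1p(sc.counts)
    markers: Dict[str, list] = {}
    for t in types:
        in_group = sc.cell_types == t
        z = _wilcoxon_z(logx, in_group)
        detectable = np.where(sc.counts[in_group].sum(axis=0) > 0)[0]
        if fraction is not None:
            n_take = max(1, int(round(fraction * len(detectable))))
        else:
            n_take = top_n
        # rank detectable genes by descending z, ties by gene index
        order = detectable[np.lexsort((detectable, -z[detectable]))]
        markers[str(t)] = sc.gene_names[order[:n_take]].tolist()
    return markers


def build_celltype_profile(sc: SingleCellDataset,
                           genes) -> CellTypeProfile:
    """Sum normalized expression of cells sharing a type over ``genes``.

    ``genes`` is an ordered gene list (typically the marker union); the
    profile row for type ``t`` is the column sum of that type's cells.
    """
    genes = np.asarray(list(genes), dtype=object).astype(str)
    missing = [g for g in genes if g not in set(sc.gene_names)]
    if missing:
        raise KeyError(f"unknown genes requested: {missing[:5]}")
    sub = sc.subset_genes(genes)
    types = sc.type_names
    profile = np.vstack([
        sub.counts[sub.cell_types == t].sum(axis=0) for t in types
    ])
    marker_sets = {str(t): genes.tolist() for t in types}
    return CellTypeProfile(profile, types, genes, marker_sets)


def marker_union(markers: Dict[str, list]) -> list:
    """Deduplicated union of per-type marker lists, order of first
    appearance across types (deterministic canonical gene order)."""
    seen, out = set(), []
    for t in markers:
        for g in markers[t]:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def align_and_stack(C: CellTypeProfile,
                    st: SpatialDataset) -> StackedMatrix:
    """Stack ``C`` over ``S`` on their common genes, in ``C``'s gene order.

    ST counts are kept raw. Raises on an empty gene intersection.
    """
    st_set = set(st.gene_names)
    common = [g for g in C.gene_names if g in st_set]
    if not common:
        raise ValueError("no common genes between profile and ST data")
    Csub = C.subset_genes(common)
    Ssub = st.subset_genes(common)
    X = np.vstack([Csub.profile, Ssub.counts])
    roles = np.array(["celltype"] * Csub.n_types + ["spot"] * Ssub.n_spots)
    return StackedMatrix(X, roles, np.asarray(common, dtype=object))


@dataclass
class PreprocessResult:
    sc: SingleCellDataset          # filtered + normalized
    st: SpatialDataset             # filtered (raw counts)
    markers: Dict[str, list]
    profile: CellTypeProfile       # C, restricted to common genes
    stacked: StackedMatrix         # X = [C; S]


def preprocess_pipeline(
    sc: SingleCellDataset,
    st: SpatialDataset,
    top_n: int = 200,
    marker_fraction: Optional[float] = None,
    min_genes: int = 5,
    min_cells_per_gene: int = 1,
    min_cells_per_type: int = 2,
    mito_fraction_max: float = 0.2,
    normalize_sc: bool = True,
    normalize_st: bool = False,
) -> PreprocessResult:
    """QC → normalize → markers → profile → align/stack.

    ``normalize_sc`` / ``normalize_st`` expose the four normalization
    configurations; the default (scRNA normalized, ST raw) is the one
    that performs best.
    """
    sc_f, st_f = apply_qc_filters(sc, st, min_genes, min_cells_per_gene,
                                  min_cells_per_type, mito_fraction_max)
    sc_n = normalize_cells(sc_f) if normalize_sc else sc_f
    if normalize_st:
        sums = st_f.counts.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        st_f = SpatialDataset(st_f.counts / sums, st_f.gene_names,
                              st_f.spot_ids, st_f.coordinates)
    markers = select_marker_genes(sc_n, top_n=top_n,
                                  fraction=marker_fraction)
    union = marker_union(markers)
    profile = build_celltype_profile(sc_n, union)
    profile.marker_sets = markers
    stacked = align_and_stack(profile, st_f)
    profile_common = profile.subset_genes(stacked.gene_names)
    profile_common.marker_sets = markers
    return PreprocessResult(sc_n, st_f, markers, profile_common, stacked)
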