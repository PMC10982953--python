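"""ST data simulators.

Two complementary generators of pseudo-spots with exact ground truth:

* :func:`simulate_regular` — the classical reference-free procedure:
  each spot pools 5–15 cells of 2–6 types drawn from the scRNA
  reference, counts are summed, and spots receive arbitrary row-major
  grid coordinates (column wraps at 40). No spatial structure survives.

* :func:`simulate_spatial` — the spatially aware procedure: cells and
  reference-slide spots are co-embedded with the VAE, each cell receives
  the midpoint of its k = 2 nearest reference spots as predicted 2-D
  coordinates, cells are binned on a hexagonal grid (flat-top hexes,
  axial indexing, origin at the bounding-box minimum), overfull bins
  shed uniformly chosen extra cells to their six hexagonal neighbors,
  bins outside the 4–15-cell range after rebalancing are dropped, and
  per-spot expression is the member-cell average rescaled to the spot's
  median member library size ("sum" mode keeps the plain sum). Spatial
  expression autocorrelation of the reference slide is preserved.

:func:`add_neighbor_noise` blends a seeded subset of spots with their
neighbor mean, Ē_i = (1−α)·E_i + α·mean(neighbors), emulating RNA
diffusion during permeation. :func:`blur_bins` fabricates low-resolution
spots from single-cell-resolution slides by square binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .coembed import encode, train_vae
from .config import RunConfig
from .datasets import (SimulatedSpatialDataset, SingleCellDataset,
                       SpatialDataset, StackedMatrix)

__all__ = ["CellCoordinates", "HexAssignment", "simulate_regular",
           "predict_cell_coordinates", "hex_bin_cells", "rebalance_bins",
           "simulate_spatial", "add_neighbor_noise", "blur_bins"]

_HEX_DIRS = np.array([(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)])


@dataclass
class CellCoordinates:
    """Predicted (x, y) per cell plus the reference spots used."""

    coords: np.ndarray
    ref_spot_ids: np.ndarray  # n_cells × k
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite predicted coordinates")


@dataclass
class HexAssignment:
    """Per-cell hexagon (axial q, r), plus the geometry to recover
    centers in the original coordinate frame."""

    axial: np.ndarray          # n_cells × 2 int
    kept: np.ndarray           # bool mask (cells in surviving bins)
    hex_size: float
    origin: np.ndarray         # (x, y) of the axial (0, 0) center
    dropped_bins: int = 0

    def centers(self) -> Dict[Tuple[int, int], np.ndarray]:
        out = {}
        for q, r in {tuple(a) for a in self.axial[self.kept]}:
            out[(q, r)] = self.origin + _axial_to_xy(q, r, self.hex_size)
        return out

    def bins(self) -> Dict[Tuple[int, int], np.ndarray]:
        """Hex -> indices of member (kept) cells."""
        out: Dict[Tuple[int, int], list] = {}
        for i in np.where(self.kept)[0]:
            out.setdefault(tuple(self.axial[i]), []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}


def _axial_to_xy(q, r, size: float) -> np.ndarray:
    # flat-top hexagons: x spacing 3/2·s, y spacing √3·s
    return np.array([size * 1.5 * q, size * np.sqrt(3) * (r + q / 2.0)])


def _xy_to_axial(xy: np.ndarray, size: float) -> np.ndarray:
    q = (2.0 / 3.0) * xy[:, 0] / size
    r = (-1.0 / 3.0 * xy[:, 0] + np.sqrt(3) / 3.0 * xy[:, 1]) / size
    return _cube_round(q, r)


def _cube_round(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    s = -q - r
    rq, rr, rs = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    return np.stack([rq, rr], axis=1).astype(int)


# ---------------------------------------------------------------------------
# Regular simulator
# ---------------------------------------------------------------------------

def simulate_regular(sc: SingleCellDataset, n_spots: int, seed: int = 0,
                     cells_range: Tuple[int, int] = (5, 15),
                     types_range: Tuple[int, int] = (2, 6),
                     max_col: int = 40) -> SimulatedSpatialDataset:
    """Pool random cells into grid spots with no spatial structure.

    Per spot: N ~ U{cells_range} cells and T ~ U{types_range} distinct
    types (capped at the available type count and at N); each chosen
    type contributes at least one cell, the remaining cells are split
    uniformly among the chosen types, and cells are drawn with
    replacement from each type's pool. Spot counts are the member-cell
    sums; coordinates are 1-based row-major integers wrapping after
    ``max_col`` columns.
    """
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    rng = np.random.default_rng(seed)
    types = sc.type_names
    m = len(types)
    pools = {t: np.where(sc.cell_types == t)[0] for t in types}

    counts = np.zeros((n_spots, sc.n_genes))
    props = np.zeros((n_spots, m))
    assignment = []
    for i in range(n_spots):
        N = int(rng.integers(cells_range[0], cells_range[1] + 1))
        t_hi = min(types_range[1], m, N)
        t_lo = min(types_range[0], t_hi)
        T = int(rng.integers(t_lo, t_hi + 1))
        chosen = rng.choice(m, size=T, replace=False)
        alloc = chosen.tolist() + rng.choice(chosen, size=N - T).tolist()
        members = []
        for t_idx in alloc:
            cell = int(rng.choice(pools[types[t_idx]]))
            members.append(cell)
            counts[i] += sc.counts[cell]
            props[i, t_idx] += 1
        props[i] /= N
        assignment.append(sc.cell_ids[members].tolist())

    rows = np.arange(n_spots) // max_col + 1
    cols = np.arange(n_spots) % max_col + 1
    coords = np.stack([rows, cols], axis=1).astype(float)
    spot_ids = np.array([f"spot{i}" for i in range(n_spots)])
    proportions = pd.DataFrame(props, index=spot_ids, columns=types)
    return SimulatedSpatialDataset(
        counts, coords, proportions, sc.gene_names, spot_ids, assignment,
        provenance={"simulator": "regular", "seed": seed,
                    "cells_range": cells_range, "types_range": types_range,
                    "max_col": max_col})


# ---------------------------------------------------------------------------
# Spatially aware simulator
# ---------------------------------------------------------------------------

def predict_cell_coordinates(sc: SingleCellDataset, ref_st: SpatialDataset,
                             k: int = 2, seed: int = 0,
                             config: Optional[RunConfig] = None
                             ) -> CellCoordinates:
    """Place each cell at the mean coordinate of its k nearest reference
    spots in the VAE co-embedding space (midpoint for k = 2; k = 1 snaps
    cells onto existing spots)."""
    if ref_st.coordinates is None:
        raise ValueError("reference ST data has no coordinates")
    config = config or RunConfig()
    common = [g for g in sc.gene_names if g in set(ref_st.gene_names)]
    if not common:
        raise ValueError("no common genes between cells and reference")
    sums = sc.counts.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    cells_norm = (sc.counts / sums)
    sc_norm = SingleCellDataset(cells_norm, sc.cell_types, sc.gene_names,
                                sc.cell_ids).subset_genes(common)
    st_sub = ref_st.subset_genes(common)
    # spots are scaled to unit sum as well: cell-to-spot latent distances
    # must reflect composition, not sequencing depth (a spot pools the
    # counts of many cells)
    spot_sums = st_sub.counts.sum(axis=1, keepdims=True)
    spot_sums[spot_sums == 0] = 1.0
    spots_norm = st_sub.counts / spot_sums
    # individual cells take the non-spot block of the stacked matrix
    X = np.vstack([sc_norm.counts, spots_norm])
    roles = np.array(["celltype"] * sc_norm.n_cells
                     + ["spot"] * st_sub.n_spots)
    stacked = StackedMatrix(X, roles, np.asarray(common, dtype=object))
    vae = train_vae(stacked, latent_dim=config.latent_dim,
                    hidden_dim=config.vae_hidden_dim,
                    epochs=config.vae_epochs,
                    learning_rate=config.vae_learning_rate,
                    seed=seed, log1p=config.vae_log1p)
    Z = encode(vae, stacked).Z
    Zc, Zs = Z[:sc_norm.n_cells], Z[sc_norm.n_cells:]
    k_eff = min(k, st_sub.n_spots)
    tree = cKDTree(Zs)
    _, nn = tree.query(Zc, k=k_eff)
    nn = nn.reshape(sc_norm.n_cells, k_eff)
    coords = st_sub.coordinates[nn].mean(axis=1)
    return CellCoordinates(coords, st_sub.spot_ids[nn], sc.cell_ids)


def hex_bin_cells(coords: Union[CellCoordinates, np.ndarray],
                  hex_size: float) -> HexAssignment:
    """Assign each cell to a flat-top hexagon of circumradius
    ``hex_size`` on a grid anchored at the coordinate bounding-box
    minimum."""
    if hex_size <= 0:
        raise ValueError("hex_size must be positive")
    xy = coords.coords if isinstance(coords, CellCoordinates) \
        else np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite cell coordinates")
    origin = xy.min(axis=0)
    axial = _xy_to_axial(xy - origin, hex_size)
    return HexAssignment(axial, np.ones(len(xy), dtype=bool),
                         hex_size, origin)


def rebalance_bins(assignment: HexAssignment, max_cells: int = 15,
                   min_cells: int = 4, seed: int = 0,
                   max_passes: int = 10) -> HexAssignment:
    """Move extra cells of overfull hexes to random hexagonal neighbors;
    drop bins still under ``min_cells`` afterwards.

    Up to ``max_passes`` sweeps are made (a transfer can overfill a
    neighbor); residual overfull bins after that trigger a warning.
    Dropped cells are flagged in the ``kept`` mask.
    """
    rng = np.random.default_rng(seed)
    axial = assignment.axial.copy()
    n = len(axial)
    for _ in range(max_passes):
        bins: Dict[Tuple[int, int], list] = {}
        for i in range(n):
            bins.setdefault(tuple(axial[i]), []).append(i)
        overfull = sorted(b for b, mem in bins.items()
                          if len(mem) > max_cells)
        if not overfull:
            break
        for b in overfull:
            members = np.asarray(bins[b])
            extras = rng.choice(members, size=len(members) - max_cells,
                                replace=False)
            for cell in extras:
                d = _HEX_DIRS[rng.integers(0, 6)]
                axial[cell] = (b[0] + d[0], b[1] + d[1])
    else:
        final = pd.Series([tuple(a) for a in axial]).value_counts()
        if (final > max_cells).any():
            warnings.warn("overfull hex bins remain after rebalancing",
                          stacklevel=2)

    sizes: Dict[Tuple[int, int], int] = {}
    for i in range(n):
        sizes[tuple(axial[i])] = sizes.get(tuple(axial[i]), 0) + 1
    kept = np.array([sizes[tuple(axial[i])] >= min_cells
                     for i in range(n)])
    dropped = sum(1 for v in sizes.values() if v < min_cells)
    return HexAssignment(axial, kept, assignment.hex_size,
                         assignment.origin, dropped_bins=dropped)


def simulate_spatial(sc: SingleCellDataset, ref_st: SpatialDataset,
                     hex_size: float, seed: int = 0,
                     aggregation: str = "average",
                     config: Optional[RunConfig] = None
                     ) -> SimulatedSpatialDataset:
    """Coordinate prediction → hexagonal binning → rebalancing →
    per-spot aggregation, with exact per-spot ground truth.

    ``aggregation="average"`` averages member-cell expression and
    rescales the spot to its median member library size; ``"sum"``
    keeps the plain member sum (mass-conserving).
    """
    if aggregation not in ("average", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    cc = predict_cell_coordinates(sc, ref_st, k=2, seed=seed,
                                  config=config)
    hexes = rebalance_bins(hex_bin_cells(cc, hex_size), seed=seed + 1)
    bins = hexes.bins()
    centers = hexes.centers()
    types = sc.type_names
    keys = sorted(bins)
    counts, coords, props, assignment = [], [], [], []
    for key in keys:
        members = bins[key]
        expr = sc.counts[members]
        if aggregation == "sum":
            row = expr.sum(axis=0)
        else:
            row = expr.mean(axis=0)
            lib = np.median(expr.sum(axis=1))
            rs = row.sum()
            if rs > 0:
                row = row * (lib / rs)
        counts.append(row)
        coords.append(centers[key])
        labels = sc.cell_types[members]
        props.append([np.mean(labels == t) for t in types])
        assignment.append(sc.cell_ids[members].tolist())
    if not counts:
        raise ValueError("no hex bin survived the 4-15 cell constraint; "
                         "adjust hex_size")
    spot_ids = np.array([f"hex{q}_{r}" for q, r in keys])
    proportions = pd.DataFrame(np.asarray(props), index=spot_ids,
                               columns=types)
    return SimulatedSpatialDataset(
        np.asarray(counts), np.asarray(coords), proportions,
        sc.gene_names, spot_ids, assignment,
        provenance={"simulator": "spatial", "seed": seed,
                    "hex_size": hex_size, "aggregation": aggregation,
                    "axial": [list(k) for k in keys],
                    "dropped_bins": hexes.dropped_bins})


# ---------------------------------------------------------------------------
# Noise and blurring
# ---------------------------------------------------------------------------

def _neighbor_sets(sim: SimulatedSpatialDataset) -> list:
    """Neighbor indices per spot: hexagonal adjacency when the dataset
    is hex-gridded, otherwise spots within the base radius (median
    nearest-neighbor distance)."""
    if "axial" in sim.provenance:
        axial = {tuple(a): i for i, a in enumerate(sim.provenance["axial"])}
        out = []
        for a in sim.provenance["axial"]:
            out.append([axial[(a[0] + d[0], a[1] + d[1])]
                        for d in _HEX_DIRS if
                        (a[0] + d[0], a[1] + d[1]) in axial])
        return out
    tree = cKDTree(sim.coordinates)
    d, _ = tree.query(sim.coordinates, k=2)
    r = float(np.median(d[:, 1])) * (1 + 1e-9)
    return [[j for j in tree.query_ball_point(sim.coordinates[i], r)
             if j != i] for i in range(sim.n_spots)]


def add_neighbor_noise(sim: SimulatedSpatialDataset, fraction: float,
                       alpha: float, seed: int = 0
                       ) -> SimulatedSpatialDataset:
    """Blend selected spots with their neighbor mean:
    Ē_i = (1 − α)·E_i + α·(Σⱼ Eⱼ)/J, computed synchronously from the
    original matrix. Exactly round(fraction·n) distinct spots are
    selected; spots without neighbors are left unchanged (logged in
    the provenance). Proportions metadata is untouched.
    """
    if not (0 <= fraction <= 1 and 0 <= alpha <= 1):
        raise ValueError("fraction and alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = sim.n_spots
    n_sel = int(round(fraction * n))
    selected = np.sort(rng.choice(n, size=n_sel, replace=False))
    neighbors = _neighbor_sets(sim)
    counts = sim.counts.copy()
    isolated = []
    for i in selected:
        nbrs = neighbors[i]
        if not nbrs:
            isolated.append(int(i))
            continue
        counts[i] = (1 - alpha) * sim.counts[i] \
            + alpha * sim.counts[nbrs].mean(axis=0)
    prov = dict(sim.provenance)
    prov.update({"noise_fraction": fraction, "noise_alpha": alpha,
                 "noise_seed": seed, "noise_selected": selected.tolist(),
                 "noise_isolated_spots": isolated})
    return SimulatedSpatialDataset(
        counts, sim.coordinates.copy(), sim.proportions.copy(),
        sim.gene_names, sim.spot_ids, list(sim.cell_assignment), prov)


def blur_bins(st: SpatialDataset, bin_x: float, bin_y: float,
              labels: Optional[np.ndarray] = None):
    """Sum single-cell-resolution measurements within axis-aligned
    rectangular bins anchored at the coordinate origin.

    With per-cell type ``labels``, returns a
    :class:`SimulatedSpatialDataset` whose ground-truth proportions are
    the per-bin label counts; without labels only the blurred
    :class:`SpatialDataset` is produced. Empty bins are omitted.
    """
    if bin_x <= 0 or bin_y <= 0:
        raise ValueError("bin sizes must be positive")
    if st.coordinates is None:
        raise ValueError("coordinates required for blurring")
    ix = np.floor(st.coordinates[:, 0] / bin_x).astype(int)
    iy = np.floor(st.coordinates[:, 1] / bin_y).astype(int)
    bins: Dict[Tuple[int, int], list] = {}
    for i, key in enumerate(zip(ix, iy)):
        bins.setdefault(key, []).append(i)
    keys = sorted(bins)
    counts = np.vstack([st.counts[bins[k]].sum(axis=0) for k in keys])
    coords = np.array([((k[0] + 0.5) * bin_x, (k[1] + 0.5) * bin_y)
                       for k in keys])
    spot_ids = np.array([f"bin{k[0]}_{k[1]}" for k in keys])
    if labels is None:
        return SpatialDataset(counts, st.gene_names, spot_ids, coords)
    labels = np.asarray(labels).astype(str)
    types = pd.unique(pd.Series(labels)).astype(str)
    props = np.vstack([
        [np.mean(labels[bins[k]] == t) for t in types] for k in keys])
    proportions = pd.DataFrame(props, index=spot_ids, columns=types)
    assignment = [st.spot_ids[bins[k]].tolist() for k in keys]
    return SimulatedSpatialDataset(
        counts, coords, proportions, st.gene_names, spot_ids, assignment,
        provenance={"simulator": "blur", "bin_x": bin_x, "bin_y": bin_y})
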