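"""Seeded synthetic fixtures: marker-structured scRNA-seq counts and
spatially zoned reference ST slides.

The scRNA generator draws negative-binomial counts around log-normal
per-gene baselines and elevates a disjoint block of marker genes per cell
type by a fold change, giving overdispersed data with planted, recoverable
cell-type structure. The spatial reference places spots on a grid over a
rectangular slide divided into zones (striped, concentric or random), each
dominated by one or two cell types, so that gene expression is spatially
autocorrelated — the property the spatially aware simulator is meant to
preserve and the regular simulator destroys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SingleCellDataset, SpatialDataset

__all__ = ["SyntheticConfig", "make_synthetic_scrna",
           "make_synthetic_spatial_reference"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic generators.

    Defaults are sized for desk-scale runs: 5 types × 600 cells × 1500
    genes with 50 tenfold-elevated markers per type, and a 300-spot
    striped reference slide.
    """

    n_types: int = 5
    n_cells: int = 600
    n_genes: int = 1500
    markers_per_type: int = 50
    marker_fold_change: float = 10.0
    dispersion: float = 0.3
    zone_layout: str = "striped"  # striped | concentric | random
    slide_width: float = 20.0
    slide_height: float = 20.0
    n_ref_spots: int = 300
    cells_per_spot_range: tuple = (4, 15)
    dominant_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_types, self.n_cells, self.n_genes,
               self.markers_per_type, self.n_ref_spots) <= 0:
            raise ValueError("all counts must be positive")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                "marker allocation infeasible: "
                f"{self.markers_per_type} markers × {self.n_types} types "
                f"> {self.n_genes} genes")
        if self.zone_layout not in ("striped", "concentric", "random"):
            raise ValueError(f"unknown zone layout {self.zone_layout!r}")

    @property
    def marker_blocks(self) -> dict:
        """Type index -> planted marker gene indices (disjoint blocks)."""
        k = self.markers_per_type
        return {t: np.arange(t * k, (t + 1) * k)
                for t in range(self.n_types)}


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and Var = mean + disp·mean²."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.float64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.float64)


def make_synthetic_scrna(cfg: SyntheticConfig) -> SingleCellDataset:
    """Cell-type-structured counts with planted markers.

    Type sizes are balanced to within one cell; marker genes of type ``t``
    have their NB mean multiplied by ``marker_fold_change`` in cells of
    that type. ``marker_fold_change = 1`` yields exchangeable types.
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.exp(rng.normal(loc=0.0, scale=0.8, size=cfg.n_genes))
    base *= 2.0 / base.mean()  # ~2 counts per gene per cell on average

    sizes = np.full(cfg.n_types, cfg.n_cells // cfg.n_types)
    sizes[: cfg.n_cells % cfg.n_types] += 1
    labels = np.repeat([f"type{t}" for t in range(cfg.n_types)], sizes)

    means = np.tile(base, (cfg.n_cells, 1))
    start = 0
    for t, size in enumerate(sizes):
        idx = cfg.marker_blocks[t]
        means[start:start + size][:, idx] *= cfg.marker_fold_change
        start += size

    counts = _nb_sample(rng, means, cfg.dispersion)
    # guarantee QC survivability: every cell expresses >=5 genes
    low = (counts > 0).sum(axis=1) < 5
    if low.any():
        counts[low, :5] += 1.0

    gene_names = np.array([f"gene{j}" for j in range(cfg.n_genes)])
    cell_ids = np.array([f"cell{i}" for i in range(cfg.n_cells)])
    return SingleCellDataset(counts, labels, gene_names, cell_ids)


def _zone_of(cfg: SyntheticConfig, xy: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Zone index per spot for the configured layout."""
    x, y = xy[:, 0], xy[:, 1]
    k = cfg.n_types
    if cfg.zone_layout == "striped":
        frac = np.clip(x / cfg.slide_width, 0, 1 - 1e-9)
        return (frac * k).astype(int)
    if cfg.zone_layout == "concentric":
        cx, cy = cfg.slide_width / 2, cfg.slide_height / 2
        r = np.hypot(x - cx, y - cy)
        rmax = np.hypot(cx, cy) + 1e-9
        return np.minimum((r / rmax * k).astype(int), k - 1)
    return rng.integers(0, k, size=len(x))


def make_synthetic_spatial_reference(cfg: SyntheticConfig,
                                     sc: SingleCellDataset):
    """Zoned reference slide built by pooling cells from ``sc``.

    Spots sit on a near-square grid over the slide; each zone is dominated
    by one cell type (probability ``dominant_prob``, with its cyclic
    successor sharing the remainder ahead of the others), and each spot
    pools 4–15 cells drawn with zone-dependent type probabilities.

    Returns ``(st, zone_map, proportions)``: the slide, the per-spot zone
    index, and the realized per-spot type proportions for assertions.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_ref_spots
    ncol = int(np.ceil(np.sqrt(n * cfg.slide_width / cfg.slide_height)))
    nrow = int(np.ceil(n / ncol))
    xs = (np.arange(ncol) + 0.5) * cfg.slide_width / ncol
    ys = (np.arange(nrow) + 0.5) * cfg.slide_height / nrow
    grid = np.array([(x, y) for y in ys for x in xs])[:n]
    zones = _zone_of(cfg, grid, rng)

    types = sc.type_names
    m = len(types)
    pools = {t: np.where(sc.cell_types == t)[0] for t in types}
    lo, hi = cfg.cells_per_spot_range

    counts = np.zeros((n, sc.n_genes))
    props = np.zeros((n, m))
    for i in range(n):
        z = zones[i] % m
        probs = np.full(m, (1 - cfg.dominant_prob) / max(m - 2, 1) * 0.5
                        if m > 2 else 0.0)
        rem = 1 - cfg.dominant_prob
        if m == 1:
            probs = np.array([1.0])
        else:
            probs = np.full(m, rem * 0.4 / max(m - 2, 1)) if m > 2 \
                else np.zeros(m)
            probs[z] = cfg.dominant_prob
            probs[(z + 1) % m] = rem * 0.6 if m > 2 else 1 - cfg.dominant_prob
            probs /= probs.sum()
        ncells = int(rng.integers(lo, hi + 1))
        chosen_types = rng.choice(m, size=ncells, p=probs)
        for t_idx in chosen_types:
            cell = rng.choice(pools[types[t_idx]])
            counts[i] += sc.counts[cell]
            props[i, t_idx] += 1
        props[i] /= ncells

    st = SpatialDataset(counts, sc.gene_names,
                        np.array([f"refspot{i}" for i in range(n)]), grid)
    proportions = pd.DataFrame(props, index=st.spot_ids, columns=types)
    return st, zones, proportions
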