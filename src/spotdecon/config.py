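"""Run configuration: every pipeline hyperparameter with its default,
plus seed fan-out so each stage draws from an independent stream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Optional

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable knobs of the deconvolution pipeline.

    Defaults follow the recommended settings: top-200 markers per type,
    scRNA normalized / ST raw, 30-dimensional latent space, k = 20
    mutual nearest neighbors, and a 64-unit hidden GCN layer trained for
    2000 epochs.
    """

    # preprocessing
    top_n_markers: int = 200
    marker_fraction: Optional[float] = None  # e.g. 0.05 for top 5 %
    min_genes: int = 5
    min_cells_per_gene: int = 1
    min_cells_per_type: int = 2
    mito_fraction_max: float = 0.2
    normalize_sc: bool = True
    normalize_st: bool = False
    # VAE co-embedding
    latent_dim: int = 30
    vae_hidden_dim: int = 512
    vae_epochs: int = 300
    vae_learning_rate: float = 5e-4
    vae_log1p: bool = False
    # link graph
    k_neighbors: int = 20
    max_distance_scope: str = "edges"  # or "global"
    # co-GCN
    gcn_hidden_dim: int = 64
    gcn_epochs: int = 2000
    gcn_learning_rate: float = 1e-2
    gcn_row_scale: bool = True  # unit-sum rows as GCN input conditioning
    degree_of: str = "A_tilde"  # or "A"
    # global
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Counter-based per-stage seed derived from the global seed."""
        offsets = {"vae": 1, "gcn": 2, "simulate": 3, "cv": 4, "noise": 5,
                   "synthetic": 6}
        if stage not in offsets:
            raise KeyError(f"unknown stage {stage!r}")
        return (self.seed * 1009 + offsets[stage]) % (2 ** 31)
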