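"""Two-layer co-graph convolution network and the deconvolution /
gene-recovery entry points.

The network propagates the stacked expression matrix ``X = [C; S]``
through the symmetrically normalized link-graph adjacency

    Â = D̃^{-1/2} (A + I) D̃^{-1/2},

with layer rule X⁽ˡ⁺¹⁾ = σ(Â X⁽ˡ⁾ W⁽ˡ⁾): a ReLU hidden layer followed by
a softplus output, whose spot block M̃ is row-normalized into the
row-stochastic mapping matrix M (Mᵢⱼ ≥ 0, Σⱼ Mᵢⱼ = 1). Training is
self-supervised: the loss compares the reconstruction ``MC`` with the
observed ST matrix ``S`` per gene column and per spot row,

    L = (1/g) Σ_genes [(1 − PCC) + (1 − COSSIM)]
      + (1/n) Σ_spots [(1 − PCC) + (1 − COSSIM)],

which is invariant to positive rescaling of S. Gradients of the PCC and
cosine terms are derived in closed form and the two weight matrices are
optimized with Adam; the VAE embedding and the link graph stay frozen.

PCC of a zero-variance vector is defined as 0 (contributing 1 to the
loss, gradient 0), the same convention as the metrics module.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit

from .coembed import encode, train_vae
from .config import RunConfig
from .datasets import (CellTypeProfile, SingleCellDataset, SpatialDataset,
                       StackedMatrix)
from .linkgraph import LinkGraph, build_link_graph
from .preprocess import (PreprocessResult, apply_qc_filters,
                         build_celltype_profile, normalize_cells,
                         preprocess_pipeline)

__all__ = ["CoGCNModel", "NormalizedAdjacency", "GCNOutput",
           "MappingMatrix", "TrainingLog", "normalize_adjacency",
           "gcn_forward", "extract_and_normalize_mapping",
           "reconstruction_loss", "fit", "deconvolve", "recover_genes",
           "crossval_gene_recovery"]


@dataclass
class CoGCNModel:
    """Learnable weights of the two convolutional layers."""

    W0: np.ndarray  # g × h
    W1: np.ndarray  # h × m
    activation: str = "relu"
    seed: int = 0

    @property
    def hidden_dim(self) -> int:
        return self.W0.shape[1]

    @property
    def n_types(self) -> int:
        return self.W1.shape[1]


@dataclass
class NormalizedAdjacency:
    """Â = D̃^{-1/2} (A + I) D̃^{-1/2}, stored sparse; symmetric with
    spectral radius ≤ 1."""

    A_hat: sparse.csr_matrix

    def __matmul__(self, other):
        return self.A_hat @ other

    def toarray(self) -> np.ndarray:
        return self.A_hat.toarray()


@dataclass
class GCNOutput:
    """Final-layer output Y = [Y_sc; Y_st] with the role split."""

    Y: np.ndarray
    node_roles: np.ndarray

    @property
    def Y_sc(self) -> np.ndarray:
        m = int((self.node_roles == "celltype").sum())
        return self.Y[:m]

    @property
    def Y_st(self) -> np.ndarray:
        m = int((self.node_roles == "celltype").sum())
        return self.Y[m:]


@dataclass
class MappingMatrix:
    """Row-stochastic spots × cell-types proportions."""

    values: np.ndarray
    spot_ids: np.ndarray
    type_names: np.ndarray
    raw: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if (v < 0).any():
            raise ValueError("mapping matrix must be non-negative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("mapping matrix rows must sum to 1")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids,
                            columns=self.type_names)


@dataclass
class TrainingLog:
    losses: list
    config: dict
    seed: int
    wall_clock: float = 0.0


def normalize_adjacency(A: Union[LinkGraph, np.ndarray],
                        degree_of: str = "A_tilde") -> NormalizedAdjacency:
    """Symmetric GCN normalization with self-loops.

    ``degree_of="A_tilde"`` (default) uses the degrees of Ã = A + I,
    which are strictly positive; ``"A"`` uses the degrees of A with an
    epsilon guard for isolated nodes.
    """
    Aarr = A.A if isinstance(A, LinkGraph) else np.asarray(A, float)
    if (Aarr < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not np.allclose(Aarr, Aarr.T):
        raise ValueError("adjacency must be symmetric")
    At = Aarr + np.eye(Aarr.shape[0])
    if degree_of == "A_tilde":
        deg = At.sum(axis=1)
    elif degree_of == "A":
        deg = np.maximum(Aarr.sum(axis=1), 1e-12)
    else:
        raise ValueError(f"unknown degree_of {degree_of!r}")
    dinv = 1.0 / np.sqrt(deg)
    A_hat = sparse.csr_matrix(At * dinv[:, None] * dinv[None, :])
    return NormalizedAdjacency(A_hat)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _init_gcn(g: int, h: int, m: int, seed: int) -> CoGCNModel:
    rng = np.random.default_rng(seed)

    def glorot(fi, fo):
        s = np.sqrt(6.0 / (fi + fo))
        return rng.uniform(-s, s, size=(fi, fo))

    return CoGCNModel(W0=glorot(g, h), W1=glorot(h, m), seed=seed)


def gcn_forward(X: Union[StackedMatrix, np.ndarray],
                A_hat: NormalizedAdjacency,
                model: CoGCNModel) -> GCNOutput:
    """Y = softplus(Â · relu(Â X W⁽⁰⁾) · W⁽¹⁾); row count preserved."""
    if isinstance(X, StackedMatrix):
        Xarr, roles = X.X, X.node_roles
    else:
        Xarr = np.asarray(X, dtype=np.float64)
        roles = np.array(["spot"] * Xarr.shape[0])
    if Xarr.shape[1] != model.W0.shape[0]:
        raise ValueError(
            f"feature width {Xarr.shape[1]} != W0 rows {model.W0.shape[0]}")
    H = np.maximum(A_hat @ (Xarr @ model.W0), 0.0)
    Y = _softplus(A_hat @ (H @ model.W1))
    return GCNOutput(Y, roles)


def extract_and_normalize_mapping(Y: GCNOutput) -> np.ndarray:
    """Row-normalize the spot block Y_st into proportions; an all-zero
    row (impossible after softplus, possible for raw input) becomes the
    uniform distribution."""
    raw = np.asarray(Y.Y_st if isinstance(Y, GCNOutput) else Y, float)
    if (raw < 0).any():
        raise ValueError("Y_st must be non-negative")
    sums = raw.sum(axis=1)
    m = raw.shape[1]
    out = np.empty_like(raw)
    zero = sums == 0
    out[zero] = 1.0 / m
    nz = ~zero
    out[nz] = raw[nz] / sums[nz, None]
    return out


# ---------------------------------------------------------------------------
# Loss: Σ (1-PCC)+(1-COSSIM) over columns, with closed-form gradients
# ---------------------------------------------------------------------------

def _sim_loss_and_grad(P: np.ndarray, S: np.ndarray
                       ) -> Tuple[float, np.ndarray]:
    """Column-wise Σ[(1−PCC)+(1−COSSIM)](P_col, S_col) and ∂/∂P.

    Zero-variance (for PCC) or zero-norm (for COSSIM) columns contribute
    the convention value 0 for the similarity, hence 1 to the loss, with
    zero gradient.
    """
    Pc = P - P.mean(axis=0)
    Sc = S - S.mean(axis=0)
    sp = np.sqrt((Pc ** 2).sum(axis=0))
    ss = np.sqrt((Sc ** 2).sum(axis=0))
    ok_p = (sp > 0) & (ss > 0)
    denom_p = np.where(ok_p, sp * ss, 1.0)
    pcc = np.where(ok_p, (Pc * Sc).sum(axis=0) / denom_p, 0.0)

    npn = np.sqrt((P ** 2).sum(axis=0))
    nsn = np.sqrt((S ** 2).sum(axis=0))
    ok_c = (npn > 0) & (nsn > 0)
    denom_c = np.where(ok_c, npn * nsn, 1.0)
    cos = np.where(ok_c, (P * S).sum(axis=0) / denom_c, 0.0)

    loss = float(((1.0 - pcc) + (1.0 - cos)).sum())
    # ∂pcc/∂P = Sc/(sp·ss) − pcc·Pc/sp²  (already centered)
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = np.where(ok_p, 1.0, 0.0) * (
            Sc / denom_p - pcc * Pc / np.where(ok_p, sp ** 2, 1.0))
        gc = np.where(ok_c, 1.0, 0.0) * (
            S / denom_c - cos * P / np.where(ok_c, npn ** 2, 1.0))
    grad = -(gp + gc)  # loss carries 1 − similarity
    return loss, grad


def _loss_and_grad_M(M: np.ndarray, Cmat: np.ndarray, Smat: np.ndarray
                     ) -> Tuple[float, np.ndarray]:
    n, g = Smat.shape
    P = M @ Cmat
    l_genes, g_genes = _sim_loss_and_grad(P, Smat)
    l_spots, g_spots_T = _sim_loss_and_grad(P.T, Smat.T)
    loss = l_genes / g + l_spots / n
    G_P = g_genes / g + g_spots_T.T / n
    return loss, G_P @ Cmat.T


def reconstruction_loss(M: Union[MappingMatrix, np.ndarray],
                        C: Union[CellTypeProfile, np.ndarray],
                        S: Union[SpatialDataset, np.ndarray]) -> float:
    """The self-supervised objective L(M) between MC and S."""
    Marr = M.values if isinstance(M, MappingMatrix) else np.asarray(M, float)
    if isinstance(C, CellTypeProfile) and isinstance(S, SpatialDataset):
        S = S.subset_genes([g for g in C.gene_names
                            if g in set(S.gene_names)])
        C = C.subset_genes(S.gene_names)
    Cmat = C.profile if isinstance(C, CellTypeProfile) else np.asarray(C, float)
    Smat = S.counts if isinstance(S, SpatialDataset) else np.asarray(S, float)
    loss, _ = _loss_and_grad_M(Marr, Cmat, Smat)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite reconstruction loss")
    return loss


def fit(X: StackedMatrix, A: Union[LinkGraph, NormalizedAdjacency],
        C: CellTypeProfile, S: SpatialDataset,
        config: Optional[RunConfig] = None
        ) -> Tuple[MappingMatrix, CoGCNModel, TrainingLog]:
    """Minimize the self-supervised loss over W⁽⁰⁾, W⁽¹⁾ with Adam.

    ``C`` and ``S`` are aligned to the gene order of ``X``; the VAE and
    link graph are frozen — only the two GCN weight matrices move.
    """
    config = config or RunConfig()
    t0 = time.time()
    A_hat = A if isinstance(A, NormalizedAdjacency) else \
        normalize_adjacency(A, config.degree_of)
    Cmat = C.subset_genes(X.gene_names).profile
    Smat = S.subset_genes(X.gene_names).counts
    m, n = Cmat.shape[0], Smat.shape[0]
    g = X.X.shape[1]
    model = _init_gcn(g, config.gcn_hidden_dim, m,
                      config.stage_seed("gcn"))

    # input conditioning: profile rows and raw-count spot rows differ by
    # orders of magnitude; unit-sum rows keep activations in a trainable
    # range (the loss still targets the raw S)
    Xfeat = X.X
    if config.gcn_row_scale:
        rs = Xfeat.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        Xfeat = Xfeat / rs
    AX = A_hat @ Xfeat  # constant across epochs
    W0, W1 = model.W0, model.W1
    adam = {k: [np.zeros_like(v), np.zeros_like(v)]
            for k, v in (("W0", W0), ("W1", W1))}
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.gcn_learning_rate
    losses = []
    spot_rows = X.node_roles == "spot"

    for epoch in range(config.gcn_epochs):
        H = np.maximum(AX @ W0, 0.0)
        AH = A_hat @ H
        Z = AH @ W1
        Yst = _softplus(Z[spot_rows])
        rowsum = Yst.sum(axis=1, keepdims=True)
        M = Yst / rowsum

        loss, G_M = _loss_and_grad_M(M, Cmat, Smat)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"GCN loss diverged (non-finite) at epoch {epoch}")
        losses.append(loss)

        # back through row normalization and softplus
        G_raw = (G_M - (G_M * M).sum(axis=1, keepdims=True)) / rowsum
        dZ_st = G_raw * expit(Z[spot_rows])
        dZ = np.zeros((m + n, m))
        dZ[spot_rows] = dZ_st
        gW1 = AH.T @ dZ
        dH = (A_hat @ (dZ @ W1.T)) * (H > 0)
        gW0 = AX.T @ dH

        t = epoch + 1
        for key, W, gW in (("W0", W0, gW0), ("W1", W1, gW1)):
            mm, vv = adam[key]
            mm[:] = b1 * mm + (1 - b1) * gW
            vv[:] = b2 * vv + (1 - b2) * gW ** 2
            W -= lr * (mm / (1 - b1 ** t)) / (
                np.sqrt(vv / (1 - b2 ** t)) + eps)

    out = gcn_forward(StackedMatrix(Xfeat, X.node_roles, X.gene_names),
                      A_hat, model)
    raw = out.Y_st
    Mfinal = extract_and_normalize_mapping(out)
    mapping = MappingMatrix(Mfinal, S.spot_ids, C.type_names, raw=raw)
    log = TrainingLog(losses=losses, config=config.to_dict(),
                      seed=config.seed, wall_clock=time.time() - t0)
    return mapping, model, log


@dataclass
class DeconvolutionResult:
    mapping: MappingMatrix
    model: CoGCNModel
    log: TrainingLog
    preprocess: PreprocessResult
    link_graph: LinkGraph


def _prepare(sc: SingleCellDataset, st: SpatialDataset,
             config: RunConfig) -> PreprocessResult:
    if len(pd.unique(pd.Series(sc.cell_types))) == 1:
        # one-vs-rest ranking is undefined with a single type; use every
        # shared gene as the profile (M is forced to the all-ones column
        # by row normalization regardless)
        sc_f, st_f = apply_qc_filters(
            sc, st, config.min_genes, config.min_cells_per_gene,
            config.min_cells_per_type, config.mito_fraction_max)
        sc_n = normalize_cells(sc_f) if config.normalize_sc else sc_f
        profile = build_celltype_profile(sc_n, sc_n.gene_names)
        from .preprocess import align_and_stack

        stacked = align_and_stack(profile, st_f)
        prof_c = profile.subset_genes(stacked.gene_names)
        return PreprocessResult(sc_n, st_f,
                                {str(sc_n.type_names[0]):
                                 list(stacked.gene_names)},
                                prof_c, stacked)
    return preprocess_pipeline(
        sc, st, top_n=config.top_n_markers,
        marker_fraction=config.marker_fraction,
        min_genes=config.min_genes,
        min_cells_per_gene=config.min_cells_per_gene,
        min_cells_per_type=config.min_cells_per_type,
        mito_fraction_max=config.mito_fraction_max,
        normalize_sc=config.normalize_sc,
        normalize_st=config.normalize_st)


def deconvolve(sc: SingleCellDataset, st: SpatialDataset,
               config: Optional[RunConfig] = None,
               return_details: bool = False
               ) -> Union[MappingMatrix, DeconvolutionResult]:
    """End-to-end deconvolution: preprocess → VAE co-embed → mutual-NN
    link graph → self-supervised GCN fit. Fully determined by
    ``(sc, st, config)`` including the seed."""
    config = config or RunConfig()
    try:
        prep = _prepare(sc, st, config)
    except Exception as e:
        raise RuntimeError(f"preprocess stage failed: {e}") from e
    try:
        vae = train_vae(prep.stacked, latent_dim=config.latent_dim,
                        hidden_dim=config.vae_hidden_dim,
                        epochs=config.vae_epochs,
                        learning_rate=config.vae_learning_rate,
                        seed=config.stage_seed("vae"),
                        log1p=config.vae_log1p)
        Z = encode(vae, prep.stacked)
    except Exception as e:
        raise RuntimeError(f"co-embedding stage failed: {e}") from e
    try:
        graph = build_link_graph(Z, k=config.k_neighbors,
                                 max_distance_scope=config.max_distance_scope)
    except Exception as e:
        raise RuntimeError(f"link-graph stage failed: {e}") from e
    try:
        mapping, model, log = fit(prep.stacked, graph, prep.profile,
                                  prep.st, config)
    except Exception as e:
        raise RuntimeError(f"GCN stage failed: {e}") from e
    if return_details:
        return DeconvolutionResult(mapping, model, log, prep, graph)
    return mapping


def recover_genes(M: MappingMatrix,
                  C_full: CellTypeProfile) -> pd.DataFrame:
    """Predict spot expression as ``M · C_full`` (spots × genes).

    ``C_full`` may cover genes absent from training — that is the point:
    the mapping transfers the reference profile of any gene onto the
    slide. Type names must match the mapping's columns.
    """
    if set(M.type_names) != set(C_full.type_names):
        unmatched = set(M.type_names) ^ set(C_full.type_names)
        raise ValueError(f"cell-type name mismatch: {sorted(unmatched)}")
    order = pd.Index(C_full.type_names).get_indexer(M.type_names)
    pred = M.values @ C_full.profile[order]
    return pd.DataFrame(pred, index=M.spot_ids, columns=C_full.gene_names)


def crossval_gene_recovery(sc: SingleCellDataset, st: SpatialDataset,
                           folds: int = 10, seed: int = 0,
                           config: Optional[RunConfig] = None
                           ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Hold-out gene recovery by k-fold cross-validation over ST genes.

    ST genes are shuffled (seeded) into ``folds`` disjoint fractions;
    for each fold the mapping is trained on the other fractions and the
    held-out genes are predicted via ``recover_genes`` from the full
    reference profile. Predictions cover every ST gene exactly once;
    genes absent from the scRNA reference are predicted as zero.

    Returns ``(predictions, per-gene metric table)``.
    """
    from .metrics import evaluate_gene_recovery

    config = config or RunConfig()
    genes = np.asarray(st.gene_names)
    if len(genes) < folds:
        raise ValueError("fewer ST genes than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    fold_ids = np.arange(len(genes)) % folds
    assignment = np.empty(len(genes), dtype=int)
    assignment[perm] = fold_ids
    if min(np.bincount(assignment, minlength=folds)) == 0:
        raise ValueError("a fold received zero genes")

    # full-gene reference profile for prediction
    sc_f, _ = apply_qc_filters(sc, st, config.min_genes,
                               config.min_cells_per_gene,
                               config.min_cells_per_type,
                               config.mito_fraction_max)
    sc_n = normalize_cells(sc_f) if config.normalize_sc else sc_f
    C_full = build_celltype_profile(sc_n, sc_n.gene_names)

    pred = pd.DataFrame(0.0, index=st.spot_ids, columns=genes)
    for f in range(folds):
        held = genes[assignment == f]
        train = genes[assignment != f]
        st_train = st.subset_genes(train)
        cfg = RunConfig.from_dict({**config.to_dict(),
                                   "seed": config.seed + f + 1})
        mapping = deconvolve(sc, st_train, cfg)
        predictable = [g for g in held if g in set(C_full.gene_names)]
        if predictable:
            cols = recover_genes(mapping, C_full.subset_genes(predictable))
            pred.loc[cols.index, predictable] = cols.values
    table = evaluate_gene_recovery(pred, st)
    return pred, table
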