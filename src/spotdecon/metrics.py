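"""Deconvolution and gene-recovery evaluation metrics.

Per-unit (spot or gene) similarity measures between a prediction and a
ground truth: Pearson correlation (PCC), a scalar structural-similarity
index (SSIM) on max-scaled vectors, cosine similarity (COSSIM), RMSE and
the Jensen–Shannon divergence (JSD, base-2 logarithm so it lies in
[0, 1]). Methods are compared with the average rank score (ARS): per
metric the best of M methods receives rank M, and ARS is the mean of the
five ranks divided by M.

Conventions for degenerate input: the PCC of a zero-variance vector is 0
(shared with the training loss); cosine similarity with a zero vector is
0; JSD inputs are renormalized to sum to 1.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import jensenshannon
from scipy.stats import rankdata

from .datasets import SpatialDataset

__all__ = ["pcc", "ssim", "cossim", "rmse", "jsd", "ars",
           "evaluate_deconvolution", "evaluate_gene_recovery",
           "spatial_expression_correlation"]

METRIC_NAMES = ("PCC", "SSIM", "COSSIM", "RMSE", "JSD")
HIGHER_BETTER = {"PCC": True, "SSIM": True, "COSSIM": True,
                 "RMSE": False, "JSD": False}


def _pair(a, b) -> tuple:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def pcc(a, b) -> float:
    """Pearson correlation; 0 if either vector has zero variance."""
    a, b = _pair(a, b)
    ac, bc = a - a.mean(), b - b.mean()
    sa, sb = np.sqrt((ac ** 2).sum()), np.sqrt((bc ** 2).sum())
    if sa == 0 or sb == 0:
        return 0.0
    return float((ac * bc).sum() / (sa * sb))


def ssim(a, b, alpha: float = 0.01, beta: float = 0.03) -> float:
    """Scalar SSIM on vectors scaled by their own maxima.

    Each vector is divided by its maximum (zero-max vectors are left as
    zeros); means, variances and the covariance are population moments of
    the scaled vectors; the stabilizers are ``alpha²`` and ``beta²``.
    """
    a, b = _pair(a, b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("ssim expects non-negative vectors")
    sa = a / a.max() if a.max() > 0 else a
    sb = b / b.max() if b.max() > 0 else b
    mu_a, mu_b = sa.mean(), sb.mean()
    var_a, var_b = sa.var(), sb.var()
    cov = ((sa - mu_a) * (sb - mu_b)).mean()
    a2, b2 = alpha ** 2, beta ** 2
    return float((2 * mu_a * mu_b + a2) * (2 * cov + b2)
                 / ((mu_a ** 2 + mu_b ** 2 + a2) * (var_a + var_b + b2)))


def cossim(a, b) -> float:
    """Cosine similarity; 0 if either vector is all zeros."""
    a, b = _pair(a, b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def rmse(a, b) -> float:
    a, b = _pair(a, b)
    return float(np.sqrt(((a - b) ** 2).mean()))


def jsd(p, q, base: float = 2.0) -> float:
    """Jensen–Shannon divergence between two distributions.

    Inputs must be non-negative; each is renormalized to sum to 1.
    With base-2 logarithm the value lies in [0, 1].
    """
    p, q = _pair(p, q)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("jsd expects non-negative inputs")
    d = jensenshannon(p, q, base=base)  # sqrt of the divergence
    return float(d ** 2)


def ars(metric_means: pd.DataFrame) -> pd.DataFrame:
    """Average rank score per method.

    ``metric_means``: methods × the five metric columns. Per metric,
    ranks are assigned so the best method receives rank M (ascending
    ranks on higher-is-better metrics, descending on RMSE/JSD); ties get
    averaged ranks. ARS = sum of the five ranks / (5·M).
    """
    missing = [m for m in METRIC_NAMES if m not in metric_means.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    if len(metric_means) < 2:
        raise ValueError("ars requires >= 2 methods")
    M = len(metric_means)
    ranks = pd.DataFrame(index=metric_means.index, dtype=float)
    for m in METRIC_NAMES:
        vals = metric_means[m].to_numpy(dtype=float)
        ranks[f"R_{m}"] = rankdata(vals if HIGHER_BETTER[m] else -vals)
    out = ranks.copy()
    out["ARS"] = ranks.sum(axis=1) / (5.0 * M)
    for m in METRIC_NAMES:
        out[m] = metric_means[m]
    return out


def _metric_row(pred: np.ndarray, true: np.ndarray) -> dict:
    return {
        "PCC": pcc(pred, true),
        "SSIM": ssim(pred, true),
        "COSSIM": cossim(pred, true),
        "RMSE": rmse(pred, true),
        "JSD": jsd(pred, true) if pred.sum() > 0 and true.sum() > 0
        else (0.0 if pred.sum() == true.sum() else 1.0),
    }


def evaluate_deconvolution(predicted: pd.DataFrame,
                           truth: pd.DataFrame) -> pd.DataFrame:
    """Per-spot metrics between predicted and true proportion vectors.

    Rows are spots, columns cell types; types are matched by name, spots
    by index. Returns one row per spot plus a ``mean`` row.
    """
    if set(predicted.columns) != set(truth.columns):
        unmatched = set(predicted.columns) ^ set(truth.columns)
        raise ValueError(f"cell-type name mismatch: {sorted(unmatched)}")
    if len(predicted) != len(truth):
        raise ValueError("spot count mismatch")
    truth = truth.loc[:, predicted.columns]
    rows = [_metric_row(predicted.iloc[i].to_numpy(),
                        truth.iloc[i].to_numpy())
            for i in range(len(predicted))]
    table = pd.DataFrame(rows, index=predicted.index)
    table.loc["mean"] = table.mean()
    return table


def evaluate_gene_recovery(pred: pd.DataFrame,
                           observed: SpatialDataset) -> pd.DataFrame:
    """Per-gene metrics across spots between predicted and observed
    expression. ``pred``: spots × genes. JSD is computed on per-gene
    vectors renormalized over spots; genes absent from either side are
    skipped, zero-sum genes get JSD NaN.
    """
    obs = pd.DataFrame(observed.counts, index=observed.spot_ids,
                       columns=observed.gene_names)
    shared = [g for g in pred.columns if g in set(obs.columns)]
    if not shared:
        raise ValueError("no shared genes between prediction and observed")
    rows = {}
    for g in shared:
        p, o = pred[g].to_numpy(), obs[g].to_numpy()
        row = {
            "PCC": pcc(p, o),
            "SSIM": ssim(p, o),
            "COSSIM": cossim(p, o),
            "RMSE": rmse(p, o),
            "JSD": jsd(p, o) if p.sum() > 0 and o.sum() > 0 else np.nan,
        }
        rows[g] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean()
    return table


def spatial_expression_correlation(
    st: SpatialDataset,
    radius_multiples: Sequence[float] = (1, 2, 4),
    base_radius: float = None,
) -> Dict[float, float]:
    """Mean per-spot expression correlation with spatial neighbors.

    The base radius ``r`` defaults to the median nearest-neighbor spot
    distance. For each multiple ``f``, each spot's value is the mean PCC
    between its profile and each neighbor within ``f·r`` (self excluded);
    the statistic is the mean over spots with at least one neighbor.
    """
    if st.coordinates is None:
        raise ValueError("spatial coordinates required")
    if st.n_spots < 2:
        raise ValueError("need >= 2 spots")
    tree = cKDTree(st.coordinates)
    if base_radius is None:
        d, _ = tree.query(st.coordinates, k=2)
        base_radius = float(np.median(d[:, 1]))
    out: Dict[float, float] = {}
    for f in radius_multiples:
        rad = f * base_radius * (1 + 1e-9)  # include exact-radius neighbors
        vals = []
        for i in range(st.n_spots):
            nbrs = [j for j in tree.query_ball_point(st.coordinates[i], rad)
                    if j != i]
            if not nbrs:
                continue
            vals.append(np.mean([pcc(st.counts[i], st.counts[j])
                                 for j in nbrs]))
        if not vals:
            if f == max(radius_multiples):
                raise ValueError(
                    f"no spot has a neighbor within {f}×base radius")
            out[float(f)] = np.nan
            continue
        out[float(f)] = float(np.mean(vals))
    return out
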