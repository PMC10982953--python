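"""Variational autoencoder co-embedding of cell-type and spot profiles.

The stacked matrix ``X = [C; S]`` is treated as draws from a single
mixture distribution — no row is told whether it is a cell type or a
spot — and encoded into a shared 30-dimensional latent space. The
training objective is the evidence lower bound

    ELBO = E_q[log p(x|z)] − KL(q(z|x) ‖ N(0, I)),

with a Gaussian (mean-squared-error) reconstruction likelihood and the
closed-form KL term ½ Σ (μ² + σ² − 1 − log σ²). The latent sample uses
the standard reparameterization z = μ + σ⊙ε, ε ~ N(0, I). Downstream
steps consume the posterior mean μ only, so embeddings — and therefore
link graphs — are deterministic given a trained model.

The network is a single-hidden-layer encoder/decoder (width 512, ReLU)
trained full-batch with Adam; forward and backward passes are written
directly in numpy, which at these problem sizes (hundreds of rows, a few
thousand genes) is fast and gives bitwise-reproducible results under a
fixed seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from .datasets import StackedMatrix

__all__ = ["VAEModel", "LatentEmbedding", "train_vae", "encode",
           "elbo_terms"]

_LOGVAR_CLIP = 10.0


@dataclass
class VAEModel:
    """Encoder/decoder parameters of the trained VAE."""

    params: dict
    latent_dim: int
    hidden_dim: int
    input_dim: int
    seed: int
    log1p: bool = False
    losses: list = field(default_factory=list)

    def save(self, path: str) -> None:
        np.savez(path, latent_dim=self.latent_dim,
                 hidden_dim=self.hidden_dim, input_dim=self.input_dim,
                 seed=self.seed, log1p=self.log1p,
                 losses=np.asarray(self.losses), **self.params)

    @classmethod
    def load(cls, path: str) -> "VAEModel":
        z = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
        keys = ("W_enc", "b_enc", "W_mu", "b_mu", "W_lv", "b_lv",
                "W_dec", "b_dec", "W_out", "b_out")
        return cls(params={k: z[k] for k in keys},
                   latent_dim=int(z["latent_dim"]),
                   hidden_dim=int(z["hidden_dim"]),
                   input_dim=int(z["input_dim"]), seed=int(z["seed"]),
                   log1p=bool(z["log1p"]), losses=list(z["losses"]))


@dataclass
class LatentEmbedding:
    """Rows × latent_dim posterior means, with node roles carried along."""

    Z: np.ndarray
    node_roles: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("latent embedding contains non-finite values")
        if len(self.node_roles) != self.Z.shape[0]:
            raise ValueError("node_roles length mismatch")


def elbo_terms(x_batch, reconstruction, mu, var) -> Tuple[float, float]:
    """Gaussian reconstruction loss and closed-form KL to N(0, I).

    Per-row quantities are summed over dimensions and averaged over rows:
    reconstruction = mean_i ½‖x_i − x̂_i‖², KL = mean_i ½ Σ_l (μ² + σ² −
    1 − log σ²). Raises on non-positive variances.
    """
    x = np.atleast_2d(np.asarray(x_batch, dtype=np.float64))
    xr = np.atleast_2d(np.asarray(reconstruction, dtype=np.float64))
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    var = np.atleast_2d(np.asarray(var, dtype=np.float64))
    if (var <= 0).any():
        raise ValueError("variances must be strictly positive")
    recon = float(0.5 * ((x - xr) ** 2).sum(axis=1).mean())
    kl = float(0.5 * (mu ** 2 + var - 1.0 - np.log(var)).sum(axis=1).mean())
    if not (np.isfinite(recon) and np.isfinite(kl)):
        raise FloatingPointError("non-finite ELBO terms")
    return recon, kl


def _init_params(rng: np.random.Generator, g: int, h: int,
                 L: int) -> dict:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    return {
        "W_enc": glorot(g, h), "b_enc": np.zeros(h),
        "W_mu": glorot(h, L), "b_mu": np.zeros(L),
        "W_lv": glorot(h, L), "b_lv": np.zeros(L),
        "W_dec": glorot(L, h), "b_dec": np.zeros(h),
        "W_out": glorot(h, g), "b_out": np.zeros(g),
    }


def _forward_encoder(p: dict, X: np.ndarray):
    h = np.maximum(X @ p["W_enc"] + p["b_enc"], 0.0)
    mu = h @ p["W_mu"] + p["b_mu"]
    logvar = np.clip(h @ p["W_lv"] + p["b_lv"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
    return h, mu, logvar


def train_vae(X: Union[StackedMatrix, np.ndarray], latent_dim: int = 30,
              hidden_dim: int = 512, epochs: int = 300,
              learning_rate: float = 5e-4, seed: int = 0,
              log1p: bool = False) -> VAEModel:
    """Train the VAE full-batch on the stacked matrix.

    Rows of any origin are mixed together; ``log1p`` optionally
    compresses the input scale before encoding. Identical seed and input
    give bitwise-identical parameters. Raises if the loss goes
    non-finite (e.g. a degenerate all-zero input with exploding
    gradients).
    """
    Xarr = X.X if isinstance(X, StackedMatrix) else np.asarray(X, float)
    if Xarr.ndim != 2 or Xarr.shape[0] < 2:
        raise ValueError("X must be 2-D with >= 2 rows")
    if not np.all(np.isfinite(Xarr)):
        raise ValueError("X contains non-finite values")
    if log1p:
        Xarr = np.log1p(Xarr)
    N, g = Xarr.shape
    rng = np.random.default_rng(seed)
    p = _init_params(rng, g, hidden_dim, latent_dim)

    m1 = {k: np.zeros_like(v) for k, v in p.items()}
    m2 = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    losses = []

    for epoch in range(epochs):
        h, mu, logvar = _forward_encoder(p, Xarr)
        sigma = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        hd = np.maximum(z @ p["W_dec"] + p["b_dec"], 0.0)
        xhat = hd @ p["W_out"] + p["b_out"]

        recon, kl = elbo_terms(Xarr, xhat, mu, np.exp(logvar))
        loss = recon + kl
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"VAE loss non-finite at epoch {epoch}: recon={recon}, "
                f"kl={kl}")
        losses.append(loss)

        # --- backward ---
        dxhat = (xhat - Xarr) / N
        g_ = {}
        g_["W_out"] = hd.T @ dxhat
        g_["b_out"] = dxhat.sum(axis=0)
        dhd = (dxhat @ p["W_out"].T) * (hd > 0)
        g_["W_dec"] = z.T @ dhd
        g_["b_dec"] = dhd.sum(axis=0)
        dz = dhd @ p["W_dec"].T
        dmu = dz + mu / N
        dlogvar = dz * eps * 0.5 * sigma + 0.5 * (np.exp(logvar) - 1.0) / N
        dlogvar *= (np.abs(logvar) < _LOGVAR_CLIP)  # clip gradient gate
        g_["W_mu"] = h.T @ dmu
        g_["b_mu"] = dmu.sum(axis=0)
        g_["W_lv"] = h.T @ dlogvar
        g_["b_lv"] = dlogvar.sum(axis=0)
        dh = (dmu @ p["W_mu"].T + dlogvar @ p["W_lv"].T) * (h > 0)
        g_["W_enc"] = Xarr.T @ dh
        g_["b_enc"] = dh.sum(axis=0)

        t = epoch + 1
        for k in p:
            m1[k] = b1 * m1[k] + (1 - b1) * g_[k]
            m2[k] = b2 * m2[k] + (1 - b2) * g_[k] ** 2
            mhat = m1[k] / (1 - b1 ** t)
            vhat = m2[k] / (1 - b2 ** t)
            p[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps_adam)

    return VAEModel(params=p, latent_dim=latent_dim, hidden_dim=hidden_dim,
                    input_dim=g, seed=seed, log1p=log1p, losses=losses)


def encode(model: VAEModel, X: Union[StackedMatrix, np.ndarray]
           ) -> LatentEmbedding:
    """Posterior means μ(X) — deterministic, no latent sampling."""
    if isinstance(X, StackedMatrix):
        Xarr, roles = X.X, X.node_roles
    else:
        Xarr = np.asarray(X, dtype=np.float64)
        roles = np.array(["spot"] * Xarr.shape[0])
    if Xarr.shape[1] != model.input_dim:
        raise ValueError(
            f"input width {Xarr.shape[1]} != model width {model.input_dim}")
    if model.log1p:
        Xarr = np.log1p(Xarr)
    _, mu, _ = _forward_encoder(model.params, Xarr)
    return LatentEmbedding(mu, roles)
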