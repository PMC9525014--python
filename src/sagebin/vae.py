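"""Variational auto-encoder over contig composition + abundance features.

The encoder maps each contig's feature vector (z-scored canonical 4-mer
frequencies concatenated with normalized abundance) to a Gaussian
posterior N(mu, diag(exp(logvar))); the decoder reconstructs the input
from a reparameterized sample. The reconstruction loss is split between
the two feature blocks with weights 0.1 (composition) and 0.9
(abundance), plus a KL divergence to the standard normal prior.

Both reconstruction terms are Gaussian (mean-squared error over the
block); the contig embedding returned after training is the posterior
mean, so downstream clustering is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, dense_backward, dense_forward, dense_init, relu


@dataclass
class VAEConfig:
    latent_dim: int = 32
    hidden_dims: list[int] = field(default_factory=lambda: [512, 512])
    composition_weight: float = 0.1
    abundance_weight: float = 0.9
    # None: 1 / (latent_dim * input_dim), i.e. the usual 1/latent_dim KL
    # weight for sum-reconstruction, re-expressed for block-mean MSE;
    # linearly warmed up over the first 10% of epochs
    kl_weight: float | None = None
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if abs(self.composition_weight + self.abundance_weight - 1.0) > 1e-12:
            raise ValueError("composition_weight + abundance_weight must equal 1")
        if self.latent_dim <= 0 or any(h <= 0 for h in self.hidden_dims):
            raise ValueError("dimensions must be positive")

    def effective_kl_weight(self, input_dim: int) -> float:
        if self.kl_weight is not None:
            return self.kl_weight
        return 1.0 / (self.latent_dim * input_dim)


@dataclass
class EmbeddingMatrix:
    """Per-contig latent vectors with a provenance tag (vae | gnn | concat)."""

    contig_ids: list[str]
    matrix: np.ndarray
    provenance: str

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, contig_id: str) -> np.ndarray:
        return self.matrix[self.contig_ids.index(contig_id)]

    def __post_init__(self):
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")
        if len(self.contig_ids) != self.matrix.shape[0]:
            raise ValueError("one row per contig required")


def vae_loss(x, xhat, mu, logvar, config: VAEConfig, composition_dim: int, kl_weight: float | None = None):
    """Weighted two-block reconstruction + KL loss.

    Returns ``(total, breakdown)`` where breakdown holds the composition
    MSE, abundance MSE and KL terms. Each MSE is the mean squared error
    over its feature block; the KL term is the per-contig closed form
    -1/2 * sum(1 + logvar - mu^2 - exp(logvar)), averaged over the batch.
    """
    x, xhat, mu, logvar = (np.asarray(a, dtype=float) for a in (x, xhat, mu, logvar))
    for a in (x, xhat, mu, logvar):
        if not np.isfinite(a).all():
            raise ValueError("non-finite input to vae_loss")
    klw = config.effective_kl_weight(x.shape[1]) if kl_weight is None else kl_weight
    diff = xhat - x
    recon_comp = float(np.mean(diff[:, :composition_dim] ** 2)) if composition_dim else 0.0
    recon_ab = float(np.mean(diff[:, composition_dim:] ** 2)) if composition_dim < x.shape[1] else 0.0
    kl = float(np.mean(-0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)))
    total = config.composition_weight * recon_comp + config.abundance_weight * recon_ab + klw * kl
    return total, {"recon_composition": recon_comp, "recon_abundance": recon_ab, "kl": kl}


class _VAENet:
    def __init__(self, input_dim: int, config: VAEConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict = {}
        dims = [input_dim, *config.hidden_dims]
        for i in range(len(dims) - 1):
            dense_init(rng, dims[i], dims[i + 1], f"enc{i}", self.params)
        h = dims[-1]
        dense_init(rng, h, config.latent_dim, "mu", self.params)
        dense_init(rng, h, config.latent_dim, "logvar", self.params)
        ddims = [config.latent_dim, *reversed(config.hidden_dims), input_dim]
        for i in range(len(ddims) - 1):
            dense_init(rng, ddims[i], ddims[i + 1], f"dec{i}", self.params)
        self.n_enc = len(config.hidden_dims)
        self.n_dec = len(ddims) - 1

    def encode(self, x):
        hs = [x]
        for i in range(self.n_enc):
            hs.append(relu(dense_forward(hs[-1], f"enc{i}", self.params)))
        mu = dense_forward(hs[-1], "mu", self.params)
        logvar = np.clip(dense_forward(hs[-1], "logvar", self.params), -10.0, 10.0)
        return mu, logvar, hs

    def decode(self, z):
        ds = [z]
        for i in range(self.n_dec):
            h = dense_forward(ds[-1], f"dec{i}", self.params)
            ds.append(relu(h) if i < self.n_dec - 1 else h)
        return ds

    def step_gradients(self, x, comp_dim, klw, rng):
        """One forward/backward pass; returns (loss, grads, breakdown)."""
        cfg = self.config
        b = x.shape[0]
        mu, logvar, hs = self.encode(x)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        ds = self.decode(z)
        xhat = ds[-1]
        total, parts = vae_loss(x, xhat, mu, logvar, cfg, comp_dim, kl_weight=klw)

        grads: dict = {}
        # d(total)/d(xhat): block-weighted MSE gradients
        dxhat = np.zeros_like(xhat)
        if comp_dim:
            dxhat[:, :comp_dim] = cfg.composition_weight * 2.0 * (xhat - x)[:, :comp_dim] / (b * comp_dim)
        ab_dim = x.shape[1] - comp_dim
        if ab_dim:
            dxhat[:, comp_dim:] = cfg.abundance_weight * 2.0 * (xhat - x)[:, comp_dim:] / (b * ab_dim)
        # decoder backprop
        dh = dxhat
        for i in reversed(range(self.n_dec)):
            if i < self.n_dec - 1:
                dh = dh * (ds[i + 1] > 0)
            dh = dense_backward(ds[i], dh, f"dec{i}", self.params, grads)
        dz = dh
        # reparameterization + KL gradients
        dmu = dz + klw * mu / b
        dlogvar = dz * eps * 0.5 * std + klw * 0.5 * (np.exp(logvar) - 1.0) / b
        dh_enc = dense_backward(hs[-1], dmu, "mu", self.params, grads)
        dh_enc += dense_backward(hs[-1], dlogvar, "logvar", self.params, grads)
        for i in reversed(range(self.n_enc)):
            dh_enc = dh_enc * (hs[i + 1] > 0)
            dh_enc = dense_backward(hs[i], dh_enc, f"enc{i}", self.params, grads)
        return total, grads, parts


def train_vae(features: np.ndarray, contig_ids: list[str], config: VAEConfig, composition_dim: int):
    """Train the VAE and return ``(EmbeddingMatrix('vae'), loss_trace)``.

    Deterministic given ``config.seed``. The loss trace holds one mean
    batch loss per epoch. The KL weight is linearly warmed up over the
    first 10% of epochs to its configured value.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    net = _VAENet(x.shape[1], config, rng)
    batch = min(config.batch_size, n)
    opt = Adam(net.params, lr=config.learning_rate)
    warmup = max(1, config.epochs // 10)
    trace: list[float] = []
    for epoch in range(config.epochs):
        klw = config.effective_kl_weight(x.shape[1]) * min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            xb = x[order[start : start + batch]]
            loss, grads, _ = net.step_gradients(xb, composition_dim, klw, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf VAE loss at epoch {epoch}, batch rows "
                    f"{order[start:start + batch][:8].tolist()}..."
                )
            opt.step(grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    mu, _, _ = net.encode(x)
    return EmbeddingMatrix(list(contig_ids), mu, "vae"), trace
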