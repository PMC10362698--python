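"""Variational autoencoder over aligned protein families.

The encoder (a temporal convolutional network, :mod:`tvae.tcn`) maps a
21 x L one-hot sequence to the mean and log-variance of a diagonal
Gaussian posterior q(z|s); a sample z = mu + sigma * eps (the
reparameterization trick) is decoded through a fully connected network
into per-column categorical distributions over the 21 residue tokens.
Training maximizes the sequence-weighted evidence lower bound

    ELBO(s) = E_q[log p(s|z)] - KL(q(z|s) || N(0, I))

with Adam and L2 weight decay; all randomness flows from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np

from .autodiff import Adam, Parameter, Tensor, categorical_logprob
from .msa_prep import AlignedFamily, family_onehot
from .tcn import Linear, TcnConfig, TcnEncoder

logger = logging.getLogger(__name__)


@dataclass
class LatentGaussian:
    """Diagonal Gaussian posterior q(z|s) for one sequence."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.log_var = np.atleast_1d(np.asarray(self.log_var, dtype=float))
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have equal shape")

    @property
    def d(self) -> int:
        return self.mu.size

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class ElboComponents:
    reconstruction: float
    kl: float

    @property
    def elbo(self) -> float:
        return self.reconstruction - self.kl


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the reference configuration
    (weight decay 1e-4, dim_z 3, hidden layer 100, seed 42), with epoch
    counts meant to be set per run (the full-scale reference used 20000
    pretraining and 8000 fine-tuning epochs)."""

    epochs: int = 2000
    finetune_epochs: int = 8000
    weight_decay: float = 1e-4
    seed: int = 42
    dim_z: int = 3
    hidden_layer: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 128


def kl_to_standard_normal(g: LatentGaussian) -> float:
    """Closed-form KL(q || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - log sigma^2 - 1)."""
    return float(0.5 * np.sum(g.mu**2 + np.exp(g.log_var) - g.log_var - 1.0))


def reparameterize(g: LatentGaussian, seed: int) -> np.ndarray:
    """z = mu + sigma * eps with eps from a seeded standard-normal stream."""
    rng = np.random.default_rng(seed)
    return g.mu + g.sigma * rng.standard_normal(g.d)


class Decoder:
    """z -> tanh hidden layer -> linear logits -> per-column softmax."""

    def __init__(self, dim_z: int, hidden: int, length: int, alphabet_size: int,
                 rng: np.random.Generator):
        self.length = length
        self.alphabet_size = alphabet_size
        self.fc1 = Linear(dim_z, hidden, rng)
        self.fc2 = Linear(hidden, length * alphabet_size, rng)

    def params(self) -> list[Parameter]:
        return self.fc1.params() + self.fc2.params()

    def logits(self, z: Tensor) -> Tensor:
        h = self.fc1(z).tanh()
        out = self.fc2(h)
        return out.reshape(z.data.shape[0], self.length, self.alphabet_size)


class TVAE:
    """Temporal-convolutional VAE bound to a fixed alignment length."""

    def __init__(self, tcn_cfg: TcnConfig, train_cfg: TrainConfig, length: int):
        # the training config owns dim_z / hidden_layer; keep the caller's
        # TcnConfig untouched
        tcn_cfg = replace(tcn_cfg, dim_z=train_cfg.dim_z,
                          hidden_layer=train_cfg.hidden_layer)
        self.tcn_cfg = tcn_cfg
        self.train_cfg = train_cfg
        self.length = length
        rng = np.random.default_rng(train_cfg.seed)
        self.encoder = TcnEncoder(tcn_cfg, rng)
        self.decoder = Decoder(train_cfg.dim_z, train_cfg.hidden_layer, length,
                               tcn_cfg.in_channels, rng)
        self._optimizer: Adam | None = None

    # -- basic operations ---------------------------------------------

    def params(self) -> list[Parameter]:
        return self.encoder.params() + self.decoder.params()

    def encode(self, onehot: np.ndarray) -> list[LatentGaussian]:
        """Posterior parameters for a (B, 21, L) one-hot stack, eval mode."""
        x = np.asarray(onehot, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        mu, logvar = self.encoder(Tensor(x), train=False)
        return [LatentGaussian(m, lv) for m, lv in zip(mu.data, logvar.data)]

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Latent point(s) -> per-column categorical probabilities.

        Returns (L, 21) for a single vector or (B, L, 21) for a batch;
        each column's 21 probabilities sum to 1.
        """
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        if single:
            z = z[None]
        logits = self.decoder.logits(Tensor(z)).data
        logits -= logits.max(axis=2, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=2, keepdims=True)
        return p[0] if single else p

    def elbo_components(self, onehot: np.ndarray, seed: int = 0,
                        n_samples: int = 1) -> ElboComponents:
        """ELBO of one sequence: closed-form KL plus a Monte-Carlo estimate
        of E_q[log p(s|z)] over ``n_samples`` posterior draws.

        One draw is the standard training estimator; more draws tighten
        the estimate of the expectation (useful when checking the
        variational bound itself, whose statement is about E_q, not a
        single draw).
        """
        g = self.encode(onehot)[0]
        rng = np.random.default_rng(seed)
        z = g.mu + g.sigma * rng.standard_normal((n_samples, g.d))
        probs = self.decode(z)  # (S, L, 21)
        target = np.argmax(onehot, axis=0)
        logp = np.log(probs[:, np.arange(self.length), target] + 1e-300)
        recon = float(np.mean(logp.sum(axis=1)))
        return ElboComponents(reconstruction=recon, kl=kl_to_standard_normal(g))

    def embed_family(self, fam: AlignedFamily) -> np.ndarray:
        """N x dim_z matrix of posterior means, eval mode."""
        x = family_onehot(fam)
        mus = []
        for start in range(0, x.shape[0], 512):
            mu, _ = self.encoder(Tensor(x[start : start + 512]), train=False)
            mus.append(mu.data)
        return np.concatenate(mus, axis=0)

    # -- training ------------------------------------------------------

    def train(self, fam: AlignedFamily, epochs: int | None = None,
              reset_optimizer: bool = True) -> list[dict]:
        """Maximize the weighted ELBO by Adam; returns the loss trace.

        The trace has one entry per epoch with the weighted mean
        reconstruction, KL, and ELBO.  All randomness (batch order,
        posterior samples, dropout masks) derives from the config seed,
        so identical config + data gives identical traces.
        """
        cfg = self.train_cfg
        if fam.n < 2:
            raise ValueError("training requires at least 2 sequences")
        if fam.length != self.length:
            raise ValueError(
                f"family length {fam.length} does not match model length {self.length}")
        n_epochs = cfg.epochs if epochs is None else epochs
        x_all = family_onehot(fam)
        targets_all = fam.matrix.astype(np.int64)
        w_all = fam.weights
        if self._optimizer is None or reset_optimizer:
            self._optimizer = Adam(self.params(), lr=cfg.learning_rate,
                                   weight_decay=cfg.weight_decay)
        opt = self._optimizer
        rng = np.random.default_rng(cfg.seed + 1)
        trace: list[dict] = []
        for epoch in range(n_epochs):
            order = rng.permutation(fam.n)
            tot_recon = tot_kl = tot_w = 0.0
            for start in range(0, fam.n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x = Tensor(x_all[idx])
                w = w_all[idx]
                mu, logvar = self.encoder(x, train=True, rng=rng)
                eps = rng.standard_normal(mu.data.shape)
                z = mu + (logvar * 0.5).exp() * eps
                logits = self.decoder.logits(z)
                recon = categorical_logprob(logits, targets_all[idx])  # (B,)
                kl = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1)
                loss = ((kl - recon) * w).sum() * (1.0 / w.sum())
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot_recon += float((recon.data * w).sum())
                tot_kl += float((kl.data * w).sum())
                tot_w += float(w.sum())
            trace.append({
                "epoch": epoch,
                "reconstruction": tot_recon / tot_w,
                "kl": tot_kl / tot_w,
                "elbo": (tot_recon - tot_kl) / tot_w,
            })
        return trace

    def fine_tune(self, fam: AlignedFamily, epochs: int | None = None) -> list[dict]:
        """Continue training on a (typically labeled) family of the same length."""
        if fam.length != self.length:
            raise ValueError(
                f"fine-tune family length {fam.length} != model length {self.length}")
        n = self.train_cfg.finetune_epochs if epochs is None else epochs
        if n == 0:
            return []
        return self.train(fam, epochs=n, reset_optimizer=False)

    def reconstruct(self, fam: AlignedFamily) -> np.ndarray:
        """Argmax reconstruction of each sequence through mu -> decode."""
        mus = self.embed_family(fam)
        probs = self.decode(mus)
        return np.argmax(probs, axis=2).astype(np.int8)

    # -- persistence ---------------------------------------------------

    def save(self, path: str) -> None:
        """Write parameters + config echo to a single .npz checkpoint."""
        meta = {
            "format": "tvae-checkpoint-v1",
            "length": self.length,
            "tcn": asdict(self.tcn_cfg),
            "train": asdict(self.train_cfg),
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TVAE":
        with np.load(path, allow_pickle=False) as ckpt:
            meta = json.loads(str(ckpt["meta"]))
            if meta.get("format") != "tvae-checkpoint-v1":
                raise ValueError(f"{path}: not a tvae checkpoint")
            model = cls(TcnConfig(**meta["tcn"]), TrainConfig(**meta["train"]),
                        meta["length"])
            for i, p in enumerate(model.params()):
                data = ckpt[f"p{i}"]
                if data.shape != p.data.shape:
                    raise ValueError(f"{path}: parameter {i} shape mismatch")
                p.data = data.astype(np.float64)
        return model


def mean_reconstruction_identity(fam: AlignedFamily, model: TVAE) -> float:
    """Mean positional identity (%) between inputs and argmax reconstructions."""
    recon = model.reconstruct(fam)
    return float(100.0 * np.mean(recon == fam.matrix))


def write_embeddings_tsv(fam: AlignedFamily, embeddings: np.ndarray, path: str) -> None:
    d = embeddings.shape[1]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"z{i+1}" for i in range(d)) + "\n")
        for name, row in zip(fam.ids, embeddings):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_loss_trace_csv(trace: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,reconstruction,kl,elbo\n")
        for row in trace:
            fh.write(f"{row['epoch']},{row['reconstruction']:.6f},"
                     f"{row['kl']:.6f},{row['elbo']:.6f}\n")
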