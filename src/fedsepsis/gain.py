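"""Generative adversarial imputation (GAIN) for sparse tabular features.

A generator sees the observed entries plus noise in the missing slots and
proposes a complete matrix; a discriminator, assisted by a hint matrix that
reveals most of the true mask, tries to recover which entries were imputed.
The generator is trained against the discriminator's judgement on missing
entries plus an ``alpha``-weighted squared reconstruction error on observed
entries.  Both networks are fully connected with two hidden layers of width
equal to the feature count, trained with Adam on min–max-normalized columns.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._nn import MLP, Adam
from ._rng import child_rng

_EPS = 1e-8


@dataclasses.dataclass(frozen=True)
class GainConfig:
    alpha: float = 100.0
    batch_size: int = 512
    hint_rate: float = 0.9
    iterations: int = 15_000
    hidden_dims: Sequence[int] | None = None  # default: (d, d)
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.hint_rate <= 1.0:
            raise ValueError("hint_rate must lie in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def desk_scale_config(**overrides) -> GainConfig:
    """Reduced training profile (2000 iterations, batch 128) for small cohorts."""
    defaults = dict(iterations=2000, batch_size=128)
    defaults.update(overrides)
    return GainConfig(**defaults)


@dataclasses.dataclass
class GainModel:
    generator: MLP
    discriminator: MLP
    col_min: np.ndarray
    col_max: np.ndarray
    config: GainConfig

    def normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.col_min) / (self.col_max - self.col_min + _EPS)

    def denormalize(self, Xn: np.ndarray) -> np.ndarray:
        return Xn * (self.col_max - self.col_min + _EPS) + self.col_min


def sample_hint(rng: np.random.Generator, mask: np.ndarray, hint_rate: float):
    """Hint matrix H = B*M + 0.5*(1-B), B ~ Bernoulli(hint_rate) elementwise."""
    b = (rng.random(mask.shape) < hint_rate).astype(float)
    return b * mask + 0.5 * (1.0 - b), b


def _noise(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.uniform(0.0, 0.01, size=shape)


def train_gain(
    X: np.ndarray, M: np.ndarray, config: GainConfig
) -> tuple[GainModel, dict[str, list[float]]]:
    """Train GAIN on a (samples, features) matrix with observation mask ``M``.

    Returns the trained model and per-iteration generator/discriminator loss
    traces.  A feature column with no observed entry is rejected: its
    normalization (and any imputation target) would be undefined.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError("data and mask shapes differ")
    if not np.all(np.isfinite(X[M == 1])):
        raise ValueError("observed entries must be finite")
    n, d = X.shape
    obs_count = M.sum(axis=0)
    if (obs_count == 0).any():
        empty = np.flatnonzero(obs_count == 0).tolist()
        raise ValueError(f"columns with zero observed entries: {empty}")

    col_min = np.nanmin(np.where(M == 1, X, np.nan), axis=0)
    col_max = np.nanmax(np.where(M == 1, X, np.nan), axis=0)

    rng = child_rng(config.seed, "gain")
    hidden = list(config.hidden_dims) if config.hidden_dims else [d, d]
    gen = MLP([2 * d, *hidden, d], rng)
    disc = MLP([2 * d, *hidden, d], rng)
    opt_g = Adam(gen.params, lr=config.learning_rate)
    opt_d = Adam(disc.params, lr=config.learning_rate)

    Xn = (X - col_min) / (col_max - col_min + _EPS)
    Xn = np.where(M == 1, Xn, 0.0)

    trace: dict[str, list[float]] = {"d_loss": [], "g_loss": [], "recon": []}
    batch = min(config.batch_size, n)
    for _ in range(config.iterations):
        idx = rng.choice(n, size=batch, replace=False)
        x, m = Xn[idx], M[idx]
        z = _noise(rng, x.shape)
        x_tilde = m * x + (1.0 - m) * z
        hint, _ = sample_hint(rng, m, config.hint_rate)

        # --- discriminator step (generator frozen) ---
        g = gen.forward(np.concatenate([x_tilde, m], axis=1))
        x_hat = m * x_tilde + (1.0 - m) * g
        d_prob = disc.forward(np.concatenate([x_hat, hint], axis=1))
        d_loss = -np.mean(
            m * np.log(d_prob + _EPS) + (1.0 - m) * np.log(1.0 - d_prob + _EPS)
        )
        d_dout = -(m / (d_prob + _EPS) - (1.0 - m) / (1.0 - d_prob + _EPS)) / d_prob.size
        d_grads, _ = disc.backward(d_dout)
        opt_d.step(d_grads)

        # --- generator step (discriminator frozen) ---
        g = gen.forward(np.concatenate([x_tilde, m], axis=1))
        x_hat = m * x_tilde + (1.0 - m) * g
        d_prob = disc.forward(np.concatenate([x_hat, hint], axis=1))
        adv_loss = -np.mean((1.0 - m) * np.log(d_prob + _EPS))
        recon = np.sum(m * (x - g) ** 2) / max(m.sum(), 1.0)
        g_loss = adv_loss + config.alpha * recon

        d_dout = -((1.0 - m) / (d_prob + _EPS)) / d_prob.size
        _, d_dx = disc.backward(d_dout)
        dg = d_dx[:, :d] * (1.0 - m)  # adversarial path through x_hat
        dg += config.alpha * 2.0 * m * (g - x) / max(m.sum(), 1.0)
        g_grads, _ = gen.backward(dg)
        opt_g.step(g_grads)

        trace["d_loss"].append(float(d_loss))
        trace["g_loss"].append(float(g_loss))
        trace["recon"].append(float(recon))
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise FloatingPointError("GAIN training diverged (non-finite loss)")

    model = GainModel(gen, disc, col_min, col_max, config)
    return model, trace


def grids_to_matrix(grids) -> tuple[np.ndarray, np.ndarray]:
    """Stack episode window grids row-wise into one (windows, channels) matrix."""
    X = np.concatenate([g.values for g in grids], axis=0)
    M = np.concatenate([g.mask for g in grids], axis=0).astype(float)
    return np.where(M == 1, X, 0.0), M


def impute_grids(model: GainModel, grids, seed: int = 0):
    """GAIN-impute every grid in a list; returns new grids with all-ones masks."""
    out = []
    for i, g in enumerate(grids):
        filled = impute(
            model, np.where(g.mask == 1, g.values, 0.0), g.mask.astype(float),
            seed=seed + i,
        )
        new = g.copy()
        new.values = filled
        new.mask = np.ones_like(g.mask)
        out.append(new)
    return out


def impute(model: GainModel, X: np.ndarray, M: np.ndarray, seed: int = 0) -> np.ndarray:
    """Fill missing entries with generator output; observed entries untouched."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError("data and mask shapes differ")
    if X.shape[1] != model.col_min.shape[0]:
        raise ValueError("feature count differs from the trained model")
    rng = child_rng(seed, "gain-impute")
    Xn = model.normalize(np.where(M == 1, X, 0.0))
    Xn = np.where(M == 1, Xn, 0.0)
    z = _noise(rng, Xn.shape)
    x_tilde = M * Xn + (1.0 - M) * z
    g = model.generator.forward(np.concatenate([x_tilde, M], axis=1))
    filled = model.denormalize(g)
    return np.where(M == 1, X, filled)
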