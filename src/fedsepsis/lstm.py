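"""Per-window sepsis prediction with a recurrent LSTM, trained on balanced batches.

The network is the standard gated recurrence: for window t with input X_t and
previous hidden state h_{t-1},

    gate_f = sigmoid(W_fx X_t + W_fh h_{t-1} + b_f)
    gate_i = sigmoid(W_ix X_t + W_ih h_{t-1} + b_i)
    gate_o = sigmoid(W_ox X_t + W_oh h_{t-1} + b_o)
    C*     = tanh(W_cx X_t + W_ch h_{t-1} + b_c)
    C_t    = gate_f * C_{t-1} + gate_i * C*
    h_t    = gate_o * tanh(C_t)

``eq8_literal=True`` swaps the output gate for the forget gate in the last
line (a variant that circulates in some write-ups of the model); the output
gate is the default.  A log-softmax head maps h_t to two class logits; the
training target of every window is its episode's label, and the loss is the
negative log-likelihood averaged over valid windows and batch.

Training batches are oversampled to exactly 50% positive episodes.  One epoch
covers the negative class once; positives are resampled with replacement.
Forward, backward (truncated-nowhere BPTT over the whole episode), and Adam
are implemented directly on ndarrays so the model has no framework
dependency and is bit-reproducible under a seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, sigmoid
from ._rng import child_rng

GATE_ORDER = ("forget", "input", "out", "cell")  # slices of the stacked matrices


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    hidden_layers: int = 1
    neurons: int = 32
    dropout: float = 0.0  # percent, as in the search grid {0, 10, 20, 30}
    epochs: int = 1
    batch_size: int = 100
    learning_rate: float = 1e-2
    eq8_literal: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers < 1 or self.neurons < 1:
            raise ValueError("hidden_layers and neurons must be positive")
        if not 0 <= self.dropout < 100:
            raise ValueError("dropout is a percentage in [0, 100)")


#: The full published hyper-parameter search space.
FULL_SEARCH_GRID = {
    "hidden_layers": (1, 2, 3),
    "neurons": (512, 800, 1024, 2048),
    "dropout": (0, 10, 20, 30),
    "epochs": (1, 2),
}

#: Reduced space for desk-scale experiments.
DESK_SEARCH_GRID = {
    "hidden_layers": (1,),
    "neurons": (16, 32),
    "dropout": (0, 10),
    "epochs": (1, 2),
}


@dataclasses.dataclass
class LstmModel:
    params: dict[str, np.ndarray]
    config: TrainConfig
    input_dim: int

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


@dataclasses.dataclass
class PredictionTrace:
    episode_id: str
    probabilities: np.ndarray  # per-window positive-class probability
    lock_window: int | None  # first window with p > 0.5 (strict), if any
    episode_score: float  # p at lock window, else max over windows


def init_params(
    input_dim: int, config: TrainConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    d = input_dim
    h = config.neurons
    for layer in range(config.hidden_layers):
        scale_x = 1.0 / math.sqrt(d)
        scale_h = 1.0 / math.sqrt(h)
        params[f"Wx{layer}"] = rng.normal(0.0, scale_x, size=(d, 4 * h))
        params[f"Wh{layer}"] = rng.normal(0.0, scale_h, size=(h, 4 * h))
        params[f"b{layer}"] = np.zeros(4 * h)
        d = h
    params["Wy"] = rng.normal(0.0, 1.0 / math.sqrt(h), size=(h, 2))
    params["by"] = np.zeros(2)
    return params


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
    eq8_literal: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One recurrence step; returns (h_t, C_t).  Gate order: forget, input, out, cell."""
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))):
        raise ValueError("non-finite input to lstm_step")
    hsz = h_prev.shape[-1]
    z = x_t @ Wx + h_prev @ Wh + b
    f = sigmoid(z[..., 0 * hsz : 1 * hsz])
    i = sigmoid(z[..., 1 * hsz : 2 * hsz])
    o = sigmoid(z[..., 2 * hsz : 3 * hsz])
    c_bar = np.tanh(z[..., 3 * hsz : 4 * hsz])
    c_t = f * c_prev + i * c_bar
    h_t = (f if eq8_literal else o) * np.tanh(c_t)
    return h_t, c_t


def _forward(params, X, config: TrainConfig, dropout_rng=None):
    """Unrolled forward pass; returns per-layer caches and final hidden states."""
    B, T, _ = X.shape
    H = config.neurons
    keep = 1.0 - config.dropout / 100.0
    layer_input = X
    caches = []
    for layer in range(config.hidden_layers):
        Wx, Wh, b = params[f"Wx{layer}"], params[f"Wh{layer}"], params[f"b{layer}"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        hs = np.empty((B, T, H))
        for t in range(T):
            x_t = layer_input[:, t, :]
            z = x_t @ Wx + h @ Wh + b
            f = sigmoid(z[:, 0 * H : 1 * H])
            i = sigmoid(z[:, 1 * H : 2 * H])
            o = sigmoid(z[:, 2 * H : 3 * H])
            c_bar = np.tanh(z[:, 3 * H : 4 * H])
            c_prev = c
            c = f * c_prev + i * c_bar
            tanh_c = np.tanh(c)
            h = (f if config.eq8_literal else o) * tanh_c
            steps.append((x_t, f, i, o, c_bar, c_prev, tanh_c))
            hs[:, t, :] = h
        drop_mask = None
        out = hs
        if dropout_rng is not None and keep < 1.0 and layer < config.hidden_layers - 1:
            drop_mask = (dropout_rng.random(hs.shape) < keep) / keep
            out = hs * drop_mask
        caches.append((layer_input, steps, drop_mask))
        layer_input = out
    logits = layer_input @ params["Wy"] + params["by"]
    return caches, layer_input, logits


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def forward_probabilities(model: LstmModel, X: np.ndarray) -> np.ndarray:
    """Per-window positive-class probabilities, shape (B, T)."""
    _, _, logits = _forward(model.params, X, model.config, dropout_rng=None)
    return np.exp(_log_softmax(logits))[..., 1]


def _loss_and_grads(params, X, valid, labels, config: TrainConfig, dropout_rng):
    B, T, _ = X.shape
    H = config.neurons
    caches, top_h, logits = _forward(params, X, config, dropout_rng)
    log_probs = _log_softmax(logits)
    probs = np.exp(log_probs)
    targets = np.repeat(labels[:, None].astype(int), T, axis=1)
    n_valid = max(valid.sum(), 1.0)
    picked = np.take_along_axis(log_probs, targets[..., None], axis=-1)[..., 0]
    loss = -float((picked * valid).sum() / n_valid)

    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
    dlogits = (probs - onehot) * valid[..., None] / n_valid

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["Wy"] = np.einsum("bth,btk->hk", top_h, dlogits)
    grads["by"] = dlogits.sum(axis=(0, 1))
    dlayer_out = dlogits @ params["Wy"].T

    for layer in range(config.hidden_layers - 1, -1, -1):
        layer_input, steps, drop_mask = caches[layer]
        if drop_mask is not None:
            dlayer_out = dlayer_out * drop_mask
        Wx, Wh = params[f"Wx{layer}"], params[f"Wh{layer}"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(params[f"b{layer}"])
        dx_all = np.empty_like(layer_input)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(len(steps) - 1, -1, -1):
            x_t, f, i, o, c_bar, c_prev, tanh_c = steps[t]
            dh = dlayer_out[:, t, :] + dh_next
            if config.eq8_literal:
                df_out = dh * tanh_c
                do = np.zeros_like(o)
                dtanh_c = dh * f
            else:
                df_out = 0.0
                do = dh * tanh_c
                dtanh_c = dh * o
            dc = dc_next + dtanh_c * (1.0 - tanh_c**2)
            df = dc * c_prev + df_out
            di = dc * c_bar
            dc_bar = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    do * o * (1.0 - o),
                    dc_bar * (1.0 - c_bar**2),
                ],
                axis=1,
            )
            h_prev = steps[t - 1][6] * (
                steps[t - 1][1] if config.eq8_literal else steps[t - 1][3]
            ) if t > 0 else np.zeros((B, H))
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_all[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
        grads[f"Wx{layer}"] = dWx
        grads[f"Wh{layer}"] = dWh
        grads[f"b{layer}"] = db
        dlayer_out = dx_all
    return loss, grads


def _pack_batch(grids: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad episode grids to a common length; returns (X, valid, labels)."""
    B = len(grids)
    T = max(g.n_windows for g in grids)
    D = grids[0].values.shape[1]
    X = np.zeros((B, T, D))
    valid = np.zeros((B, T))
    labels = np.zeros(B, dtype=bool)
    for b, g in enumerate(grids):
        if not np.all(np.isfinite(g.values)):
            raise ValueError(
                f"episode {g.episode_id} has non-finite features; impute first"
            )
        X[b, : g.n_windows] = g.values
        valid[b, : g.n_windows] = 1.0
        labels[b] = g.label
    return X, valid, labels


def make_balanced_batches(
    grids: Sequence, batch_size: int, seed: int = 0
) -> list[list]:
    """Mini-batches with exactly ceil(b/2) positive and floor(b/2) negative episodes.

    The negative class is covered once per pass (shuffled, without
    replacement; the final short chunk is topped up by resampling); positives
    are resampled with replacement as needed.
    """
    pos = [g for g in grids if g.label]
    neg = [g for g in grids if not g.label]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance batches")
    n_pos_per = math.ceil(batch_size / 2)
    n_neg_per = batch_size - n_pos_per
    rng = child_rng(seed, "batches")
    neg_order = rng.permutation(len(neg))
    n_batches = math.ceil(len(neg) / n_neg_per)
    batches = []
    for i in range(n_batches):
        chunk = neg_order[i * n_neg_per : (i + 1) * n_neg_per].tolist()
        while len(chunk) < n_neg_per:
            chunk.append(int(rng.integers(0, len(neg))))
        pos_idx = rng.integers(0, len(pos), size=n_pos_per)
        batch = [neg[j] for j in chunk] + [pos[j] for j in pos_idx]
        batches.append(batch)
    return batches


def train(
    grids: Sequence,
    config: TrainConfig,
    init: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
) -> tuple[LstmModel, list[float]]:
    """Train on balanced batches; returns the model and the per-batch loss trace."""
    if not grids:
        raise ValueError("empty training set")
    seed = config.seed if seed is None else seed
    input_dim = grids[0].values.shape[1]
    params = (
        {k: v.copy() for k, v in init.items()}
        if init is not None
        else init_params(input_dim, config, child_rng(seed, "init"))
    )
    keys = sorted(params)
    opt = Adam([params[k] for k in keys], lr=config.learning_rate)
    losses: list[float] = []
    for epoch in range(config.epochs):
        batches = make_balanced_batches(grids, config.batch_size, seed=seed * 1000 + epoch)
        for bi, batch in enumerate(batches):
            X, valid, labels = _pack_batch(batch)
            dropout_rng = (
                child_rng(seed, "dropout", epoch, bi) if config.dropout > 0 else None
            )
            loss, grads = _loss_and_grads(params, X, valid, labels, config, dropout_rng)
            opt.step([grads[k] for k in keys])
            losses.append(loss)
    return LstmModel(params=params, config=config, input_dim=input_dim), losses


def lock_and_score(probs: np.ndarray) -> tuple[int | None, float]:
    """Apply the >0.5 lock rule (strict) and derive the episode score.

    The score is the probability at the lock window when a lock fired (later
    windows are ignored), otherwise the maximum window probability.
    """
    probs = np.asarray(probs, dtype=float)
    above = np.flatnonzero(probs > 0.5)
    lock = int(above[0]) if above.size else None
    score = float(probs[lock]) if lock is not None else float(probs.max())
    return lock, score


def predict_episode(grid, model: LstmModel) -> PredictionTrace:
    """Window probabilities with the >0.5 lock rule and an episode-level score."""
    if grid.values.shape[1] != model.input_dim:
        raise ValueError(
            f"episode has {grid.values.shape[1]} channels, model expects {model.input_dim}"
        )
    X, _, _ = _pack_batch([grid])
    probs = forward_probabilities(model, X)[0, : grid.n_windows]
    lock, score = lock_and_score(probs)
    return PredictionTrace(grid.episode_id, probs, lock, score)


def predict_cohort(grids: Sequence, model: LstmModel) -> list[PredictionTrace]:
    return [predict_episode(g, model) for g in grids]


def random_search(
    train_grids: Sequence,
    tune_grids: Sequence,
    grid: dict[str, Sequence] | None = None,
    n_draws: int = 100,
    seed: int = 0,
    base_config: TrainConfig = TrainConfig(),
) -> tuple[TrainConfig, list[tuple[TrainConfig, float]]]:
    """Uniform random search (without replacement) maximizing tune-split AUPRC.

    Ties are broken by draw order.  Returns the winning config and the full
    (config, tune AUPRC) history.
    """
    from .metrics import auprc

    grid = dict(grid or DESK_SEARCH_GRID)
    names = sorted(grid)
    space = list(itertools.product(*(grid[k] for k in names)))
    if n_draws > len(space):
        warnings.warn(
            f"n_draws={n_draws} exceeds grid size {len(space)}; searching exhaustively"
        )
        n_draws = len(space)
    rng = child_rng(seed, "random-search")
    chosen = rng.choice(len(space), size=n_draws, replace=False)
    history: list[tuple[TrainConfig, float]] = []
    best: tuple[float, int] | None = None
    labels = np.array([g.label for g in tune_grids], dtype=bool)
    for draw, idx in enumerate(chosen):
        overrides = dict(zip(names, space[int(idx)]))
        cfg = dataclasses.replace(base_config, **overrides)
        model, _ = train(train_grids, cfg, seed=seed)
        scores = np.array([predict_episode(g, model).episode_score for g in tune_grids])
        value = auprc(scores, labels)
        history.append((cfg, value))
        if best is None or value > best[0]:
            best = (value, draw)
    return history[best[1]][0], history


def save_model(model: LstmModel, path: str | Path) -> None:
    """Single-file checkpoint: weight arrays plus a JSON config header."""
    header = json.dumps(
        {"config": dataclasses.asdict(model.config), "input_dim": model.input_dim}
    )
    np.savez(Path(path), __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **model.params)


def load_model(path: str | Path) -> LstmModel:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        params = {k: data[k] for k in data.files if k != "__header__"}
    return LstmModel(
        params=params,
        config=TrainConfig(**header["config"]),
        input_dim=int(header["input_dim"]),
    )
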