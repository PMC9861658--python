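"""Per-window clinical-text embeddings with short/long pooling.

Notes are tokenized, truncated to ``max_tokens``, and mapped to per-token
states for each of the last ``layer_count`` encoder layers.  Tokens are
mean-pooled within each layer; the *short* representation is the mean of the
layer vectors (dim = hidden_size), the *long* one their concatenation in
layer order (dim = layer_count * hidden_size).

The default backend is a deterministic surrogate: each (token, layer) pair
maps to a fixed pseudo-random Gaussian vector derived from a seeded hash, so
embeddings are reproducible with no pre-trained weights while still carrying
whatever class signal the token distributions carry.  A ``pretrained`` backend
slot exists for loading an external clinical transformer; it is an optional
adapter and is not required by any part of the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import warnings

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class EmbedderSpec:
    backend: str = "surrogate"
    mode: str = "short"
    layer_count: int = 4
    hidden_size: int = 768
    max_tokens: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.backend not in ("surrogate", "pretrained"):
            raise ValueError("backend must be 'surrogate' or 'pretrained'")
        if self.mode not in ("short", "long"):
            raise ValueError("mode must be 'short' or 'long'")

    @property
    def dim(self) -> int:
        return self.hidden_size if self.mode == "short" else self.layer_count * self.hidden_size


_token_cache: dict[tuple, np.ndarray] = {}


def _token_layer_vector(token: str, layer: int, spec: EmbedderSpec) -> np.ndarray:
    """Fixed pseudo-state for a (token, layer): seeded-hash-derived Gaussian."""
    key = (token, layer, spec.seed, spec.hidden_size)
    vec = _token_cache.get(key)
    if vec is None:
        digest = hashlib.blake2b(
            f"{spec.seed}\x1f{layer}\x1f{token}".encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        vec = rng.standard_normal(spec.hidden_size)
        _token_cache[key] = vec
    return vec


def tokenize(text: str) -> list[str]:
    return text.split()


def embed_note(text: str, spec: EmbedderSpec) -> np.ndarray:
    """Embed one note; empty text yields a zero vector (with a warning)."""
    tokens = tokenize(text)[: spec.max_tokens]
    if not tokens:
        warnings.warn("embedding empty text: returning a zero vector")
        return np.zeros(spec.dim)
    if spec.backend == "pretrained":
        return _embed_pretrained(tokens, spec)
    layers = []
    for layer in range(spec.layer_count):
        states = np.stack([_token_layer_vector(t, layer, spec) for t in tokens])
        layers.append(states.mean(axis=0))
    if spec.mode == "short":
        return np.mean(layers, axis=0)
    return np.concatenate(layers)


def _embed_pretrained(tokens: list[str], spec: EmbedderSpec) -> np.ndarray:
    try:
        import transformers  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional adapter
        raise ImportError(
            "the pretrained backend needs the optional 'transformers' package; "
            "use backend='surrogate' for a self-contained run"
        ) from exc
    raise NotImplementedError(
        "wire a clinical transformer checkpoint here; out of scope for the core pipeline"
    )  # pragma: no cover


def window_pool(vectors: list[np.ndarray], dim: int) -> np.ndarray:
    """Mean of the note vectors in one window; zero vector when there are none."""
    if not vectors:
        return np.zeros(dim)
    dims = {v.shape[0] for v in vectors}
    if dims != {dim}:
        raise ValueError(f"mixed embedding dims {sorted(dims)} (expected {dim})")
    return np.mean(vectors, axis=0)


def embed_episode(
    note_events, episode, spec: EmbedderSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(windows x dim) embedding matrix and per-window note-presence flags."""
    start = float(episode["start_h"])
    n_windows = int(episode["n_windows"])
    per_window: dict[int, list[np.ndarray]] = {}
    for rec in note_events.itertuples(index=False):
        k = int(math.floor(float(rec.time_h) - start))
        if 0 <= k < n_windows:
            per_window.setdefault(k, []).append(embed_note(str(rec.value), spec))
    matrix = np.zeros((n_windows, spec.dim))
    presence = np.zeros(n_windows, dtype=np.int8)
    for k, vecs in per_window.items():
        matrix[k] = window_pool(vecs, spec.dim)
        presence[k] = 1
    return matrix, presence


def embed_cohort(note_events, episodes, spec: EmbedderSpec) -> dict[str, np.ndarray]:
    """Embedding matrices keyed by episode id."""
    groups = (
        dict(tuple(note_events.groupby("patient_id", sort=True)))
        if len(note_events)
        else {}
    )
    out = {}
    for _, episode in episodes.iterrows():
        pid = episode["patient_id"]
        notes = groups.get(pid)
        if notes is None:
            notes = pd.DataFrame(
                columns=["patient_id", "time_h", "kind", "channel", "value"]
            )
        matrix, _ = embed_episode(notes, episode, spec)
        out[pid] = matrix
    return out
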