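"""Care-episode window grids, missingness handling, and stratified splits.

A :class:`WindowGrid` is the per-episode feature matrix over half-open 1 h
windows [k, k+1) with an observation mask.  Missing cells are NaN in
``values`` and 0 in ``mask``.  Two of the three missingness strategies live
here (carry-forward + global mean, distinct sentinel value); the adversarial
imputer has its own module.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import events as ev
from ._rng import child_rng

logger = logging.getLogger(__name__)

MAX_WINDOWS = 48
DEFAULT_MISSINGNESS_THRESHOLD = 0.90


@dataclasses.dataclass
class WindowGrid:
    episode_id: str
    channels: tuple[str, ...]
    values: np.ndarray  # (windows, channels), NaN where mask == 0
    mask: np.ndarray  # (windows, channels) in {0, 1}
    label: bool
    onset_window: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be congruent")
        if self.values.shape[0] < 1:
            raise ValueError("a grid needs at least one window")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel names must match the value matrix width")
        if not np.all(np.isfinite(self.values[self.mask == 1])):
            raise ValueError("observed cells must be finite")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def missing_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())

    def copy(self) -> "WindowGrid":
        return WindowGrid(
            self.episode_id,
            self.channels,
            self.values.copy(),
            self.mask.copy(),
            self.label,
            self.onset_window,
        )


def bin_events(
    patient_events: pd.DataFrame,
    episode: pd.Series | dict,
    channels: Sequence[str],
) -> WindowGrid:
    """Average per-window values of numeric channels over one care episode.

    Multiple observations of a channel inside the same window are averaged;
    windows with no observation are masked out.  Non-numeric payloads in
    numeric channels are dropped with a log message.
    """
    start = float(episode["start_h"])
    n_windows = int(episode["n_windows"])
    channels = tuple(channels)
    index = {c: j for j, c in enumerate(channels)}
    sums = np.zeros((n_windows, len(channels)))
    counts = np.zeros((n_windows, len(channels)))
    numeric = patient_events[
        patient_events["kind"].isin((ev.KIND_VITAL, ev.KIND_LAB, ev.KIND_DEMOGRAPHIC))
    ]
    for rec in numeric.itertuples(index=False):
        j = index.get(rec.channel)
        if j is None:
            continue
        k = int(math.floor(float(rec.time_h) - start))
        if not 0 <= k < n_windows:
            continue
        try:
            v = float(rec.value)
        except (TypeError, ValueError):
            logger.warning(
                "dropping non-numeric value %r in channel %s", rec.value, rec.channel
            )
            continue
        sums[k, j] += v
        counts[k, j] += 1.0
    mask = (counts > 0).astype(np.int8)
    with np.errstate(invalid="ignore"):
        values = np.where(mask == 1, sums / np.maximum(counts, 1.0), np.nan)
    return WindowGrid(
        episode_id=str(episode["patient_id"]),
        channels=channels,
        values=values,
        mask=mask,
        label=bool(episode["label"]),
        onset_window=None if pd.isna(episode.get("onset_window")) else int(episode["onset_window"]),
    )


def build_grids(
    events: pd.DataFrame, episodes: pd.DataFrame, channels: Sequence[str]
) -> list[WindowGrid]:
    """bin_events over every episode of a cohort."""
    events = ev.validate_stream(events)
    by_patient = dict(tuple(events.groupby("patient_id", sort=True)))
    grids = []
    for _, episode in episodes.iterrows():
        pid = episode["patient_id"]
        patient_events = by_patient.get(pid, ev.empty_stream())
        grids.append(bin_events(patient_events, episode, channels))
    return grids


def compute_global_means(grids: Iterable[WindowGrid]) -> dict[str, float]:
    """Per-channel mean of observed cells; intended for the training split only."""
    grids = list(grids)
    if not grids:
        return {}
    channels = grids[0].channels
    total = np.zeros(len(channels))
    count = np.zeros(len(channels))
    for g in grids:
        obs = g.mask == 1
        total += np.where(obs, g.values, 0.0).sum(axis=0)
        count += obs.sum(axis=0)
    means = {}
    for j, c in enumerate(channels):
        means[c] = float(total[j] / count[j]) if count[j] > 0 else math.nan
    return means


def impute_carry_forward_mean(
    grid: WindowGrid, global_means: dict[str, float]
) -> WindowGrid:
    """Carry the last observation forward; never-observed cells get the global mean.

    Cells before a channel's first observation (no value to carry) also fall
    back to the global training mean.  Output mask is all ones.
    """
    missing = [c for c in grid.channels if c not in global_means]
    if missing:
        raise KeyError(f"global means missing for channels: {missing}")
    out = grid.copy()
    for j, c in enumerate(grid.channels):
        col = out.values[:, j]
        obs = out.mask[:, j] == 1
        last = math.nan
        for k in range(len(col)):
            if obs[k]:
                last = col[k]
            elif not math.isnan(last):
                col[k] = last
        col[np.isnan(col)] = global_means[c]
        if np.isnan(col).any():
            raise ValueError(f"global mean for {c!r} is undefined (no training data)")
    out.mask = np.ones_like(out.mask)
    return out


def default_sentinel(grids: Iterable[WindowGrid]) -> int:
    """floor(global max over observed values) + 1: guaranteed absent integer."""
    best = 0.0
    for g in grids:
        obs = g.values[g.mask == 1]
        if obs.size:
            best = max(best, float(obs.max()))
    return int(math.floor(best)) + 1


def check_sentinel(grids: Iterable[WindowGrid], sentinel: int) -> None:
    for g in grids:
        if (g.values[g.mask == 1] == float(sentinel)).any():
            raise ValueError(f"sentinel {sentinel} collides with an observed value")


def impute_distinct_value(grid: WindowGrid, sentinel: int) -> WindowGrid:
    """Mark missing cells with an integer absent from the whole dataset."""
    if (grid.values[grid.mask == 1] == float(sentinel)).any():
        raise ValueError(f"sentinel {sentinel} collides with an observed value")
    out = grid.copy()
    out.values[out.mask == 0] = float(sentinel)
    out.mask = np.ones_like(out.mask)
    return out


def filter_missingness(
    grids: Sequence[WindowGrid],
    threshold: float = DEFAULT_MISSINGNESS_THRESHOLD,
    mode: str = "episode",
) -> list[WindowGrid]:
    """Drop episodes whose non-text missingness reaches ``threshold``.

    ``episode`` mode (default) pools all channels of an episode; ``feature``
    mode drops an episode as soon as any single channel reaches the threshold
    within it.
    """
    if mode not in ("episode", "feature"):
        raise ValueError("mode must be 'episode' or 'feature'")
    kept = []
    for g in grids:
        if mode == "episode":
            drop = g.missing_fraction() >= threshold
        else:
            per_channel = 1.0 - g.mask.mean(axis=0)
            drop = bool((per_channel >= threshold).any())
        if not drop:
            kept.append(g)
    return kept


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    base = [int(math.floor(q)) for q in quotas]
    short = n - sum(base)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - base[i]), i)
    )
    for i in order[:short]:
        base[i] += 1
    return base


def split_episodes(
    grids: Sequence[WindowGrid],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    min_stratum: int = 5,
) -> dict[str, str]:
    """Stratified train/test/tune assignment by (label, episode length).

    Strata with ``min_stratum`` or fewer episodes are omitted entirely so the
    class and length distributions stay comparable across the three splits;
    within each stratum counts follow largest-remainder rounding.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("split fractions must sum to 1")
    names = ("train", "test", "tune")
    strata: dict[tuple[bool, int], list[str]] = {}
    for g in grids:
        strata.setdefault((g.label, g.n_windows), []).append(g.episode_id)
    assignment: dict[str, str] = {}
    for key in sorted(strata):
        ids = sorted(strata[key])
        if len(ids) <= min_stratum:
            continue
        rng = child_rng(seed, "split", key[0], key[1])
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), fractions)
        pos = 0
        for name, c in zip(names, counts):
            for eid in ids[pos : pos + c]:
                assignment[eid] = name
            pos += c
    return assignment


def compute_standardizer(grids: Iterable[WindowGrid]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/sd over all cells of (imputed) training grids.

    Fitted on the training split only; constant channels get sd 1 so the
    transform stays defined.
    """
    stacked = np.concatenate([g.values for g in grids], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return mean, sd


def standardize(grid: WindowGrid, mean: np.ndarray, sd: np.ndarray) -> WindowGrid:
    """Z-score every channel; keeps the recurrent model's inputs on a sane scale."""
    out = grid.copy()
    out.values = (out.values - mean) / sd
    return out


def assemble_multimodal(grid: WindowGrid, window_embeddings: np.ndarray) -> WindowGrid:
    """Concatenate per-window text embeddings onto the non-text features."""
    emb = np.asarray(window_embeddings, dtype=float)
    if emb.ndim != 2 or emb.shape[0] != grid.n_windows:
        raise ValueError(
            f"embedding rows ({emb.shape}) must align with windows ({grid.n_windows})"
        )
    emb_channels = tuple(f"emb_{j:04d}" for j in range(emb.shape[1]))
    values = np.concatenate([grid.values, emb], axis=1)
    mask = np.concatenate(
        [grid.mask, np.ones(emb.shape, dtype=np.int8)], axis=1
    )
    return WindowGrid(
        episode_id=grid.episode_id,
        channels=grid.channels + emb_channels,
        values=values,
        mask=mask,
        label=grid.label,
        onset_window=grid.onset_window,
    )
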