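"""End-to-end experiment composition: generate -> label -> featurize -> train -> evaluate.

An :class:`ExperimentPreset` names one of the three input-feature regimes
(*non_text*, *clinical_text*, *multi_modal*), one of the three missingness
strategies (*cfmean*, *distinct*, *gain*), and the training setting
(single-server or federated with *simple* / *opt* aggregation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import embed, features, fed, gain, lstm, metrics, sepsis3, synth

MODALITIES = ("non_text", "clinical_text", "multi_modal")
MISSINGNESS = ("cfmean", "distinct", "gain")


@dataclasses.dataclass(frozen=True)
class ExperimentPreset:
    modality: str = "non_text"
    missingness: str = "cfmean"
    setting: str = "single_server"  # "single_server" | "federated"
    aggregation: str = "simple"
    n_clients: int = 2
    n_rounds: int = 5
    train: lstm.TrainConfig = dataclasses.field(default_factory=lstm.TrainConfig)
    gain: gain.GainConfig = dataclasses.field(default_factory=gain.desk_scale_config)
    embedder: embed.EmbedderSpec = dataclasses.field(default_factory=embed.EmbedderSpec)
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    filter_threshold: float = features.DEFAULT_MISSINGNESS_THRESHOLD
    onset_policy: str = "latest"
    seed: int = 0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.missingness not in MISSINGNESS:
            raise ValueError(f"missingness must be one of {MISSINGNESS}")
        if self.setting not in ("single_server", "federated"):
            raise ValueError("setting must be 'single_server' or 'federated'")


@dataclasses.dataclass
class Dataset:
    """Featurized, imputed, split cohort ready for training."""

    splits: dict[str, list]  # split name -> list of WindowGrid
    episodes: pd.DataFrame
    truth: pd.DataFrame
    channels: tuple[str, ...]


def _apply_missingness(split_grids: dict[str, list], preset: ExperimentPreset):
    all_grids = [g for gs in split_grids.values() for g in gs]
    if preset.missingness == "cfmean":
        means = features.compute_global_means(split_grids["train"])
        return {
            name: [features.impute_carry_forward_mean(g, means) for g in gs]
            for name, gs in split_grids.items()
        }
    if preset.missingness == "distinct":
        sentinel = features.default_sentinel(all_grids)
        features.check_sentinel(all_grids, sentinel)
        return {
            name: [features.impute_distinct_value(g, sentinel) for g in gs]
            for name, gs in split_grids.items()
        }
    X, M = gain.grids_to_matrix(split_grids["train"])
    model, _ = gain.train_gain(
        X, M, dataclasses.replace(preset.gain, seed=preset.seed)
    )
    return {
        name: gain.impute_grids(model, gs, seed=preset.seed)
        for name, gs in split_grids.items()
    }


def _grid_from_embeddings(grid, emb_matrix):
    return features.WindowGrid(
        episode_id=grid.episode_id,
        channels=tuple(f"emb_{j:04d}" for j in range(emb_matrix.shape[1])),
        values=emb_matrix,
        mask=np.ones(emb_matrix.shape, dtype=np.int8),
        label=grid.label,
        onset_window=grid.onset_window,
    )


def build_dataset(config: synth.SynthConfig, preset: ExperimentPreset) -> Dataset:
    """Generate a synthetic cohort and run it through labeling and featurization."""
    events_df, truth = synth.generate_cohort(config)
    onsets = sepsis3.label_cohort(events_df, policy=preset.onset_policy)
    episodes = sepsis3.select_cohort(synth.admissions_from_truth(truth), onsets)
    channels = tuple(config.feature_channels)
    grids = features.build_grids(events_df, episodes, channels)
    grids = features.filter_missingness(grids, preset.filter_threshold)
    assignment = features.split_episodes(
        grids, preset.split_fractions, seed=preset.seed
    )
    split_grids: dict[str, list] = {"train": [], "test": [], "tune": []}
    kept = {g.episode_id: g for g in grids}
    for eid, name in assignment.items():
        split_grids[name].append(kept[eid])
    split_grids = _apply_missingness(split_grids, preset)

    if preset.modality != "non_text":
        notes = synth.generate_notes(config, truth)
        kept_ids = set(assignment)
        ep_kept = episodes[episodes["patient_id"].isin(kept_ids)]
        embeddings = embed.embed_cohort(notes, ep_kept, preset.embedder)
        for name, gs in split_grids.items():
            if preset.modality == "multi_modal":
                split_grids[name] = [
                    features.assemble_multimodal(g, embeddings[g.episode_id]) for g in gs
                ]
            else:
                split_grids[name] = [
                    _grid_from_embeddings(g, embeddings[g.episode_id]) for g in gs
                ]
    # Standardize last so text-embedding channels end up on the same scale as
    # the imputed tabular ones; statistics come from the training split only.
    if split_grids["train"]:
        mean, sd = features.compute_standardizer(split_grids["train"])
        split_grids = {
            name: [features.standardize(g, mean, sd) for g in gs]
            for name, gs in split_grids.items()
        }
    return Dataset(split_grids, episodes, truth, channels)


def manifest(preset: ExperimentPreset, config: synth.SynthConfig) -> dict:
    """All seeds and configuration needed to re-run an experiment, plus a hash."""
    payload = {
        "preset": dataclasses.asdict(preset),
        "synth": dataclasses.asdict(config),
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    return payload


def run_experiment(
    preset: ExperimentPreset, config: synth.SynthConfig
) -> tuple[pd.DataFrame, dict]:
    """Execute a preset end to end; returns (report table, manifest)."""
    data = build_dataset(config, preset)
    train_grids = data.splits["train"]
    test_grids = data.splits["test"]
    if not train_grids or not test_grids:
        raise RuntimeError("empty train or test split; enlarge the cohort")
    rows = []
    if preset.setting == "single_server":
        model, _ = lstm.train(train_grids, preset.train, seed=preset.seed)
        traces = lstm.predict_cohort(test_grids, model)
        report = metrics.report_from_traces(traces, test_grids)
        rows.append(metrics.report_row(report))
    else:
        fed_config = fed.FederationConfig(
            n_clients=preset.n_clients,
            n_rounds=preset.n_rounds,
            local=preset.train,
            aggregation=preset.aggregation,
            seed=preset.seed,
        )
        _, reports = fed.run_federation(fed_config, train_grids, test_grids)
        for r, report in enumerate(reports, start=1):
            rows.append(metrics.report_row(report, round_index=r))
    return pd.DataFrame(rows), manifest(preset, config)
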