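"""Seeded synthetic sparse-EHR cohorts with planted Sepsis-3 ground truth.

The generator emulates the statistical shape the downstream pipeline assumes —
roughly 9.5% of care episodes septic, variable episode lengths capped at 48
one-hour windows, heavy per-channel missingness, antimicrobial / culture /
SOFA event streams that do (or deliberately do not) satisfy the Sepsis-3
rules, and free-text notes whose token mixture carries a class signal.  It
makes no attempt at physiological realism: values are Gaussian per channel,
with a linear mean-shift ramp over the pre-onset windows of septic patients
so that a sequence model has a learnable temporal pattern.  Tabular signal
strength (``signal_effect``) and note-token signal strength
(``note_signal_effect``) are separate dials: clinical notes are far weaker
predictors than vitals and labs in comparable cohorts.

Every septic patient gets exactly one planted qualifying (suspected
infection, organ dysfunction) pair whose dysfunction time is the true onset;
every non-septic patient violates at least one Sepsis-3 rule.  This makes the
labeler-recovery test exact rather than statistical.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import events as ev
from ._rng import child_rng

#: Non-text channels used by default; a desk-scale subset of the vital and
#: laboratory features typical of ICU early-warning models.
DEFAULT_CHANNELS = (
    "heart_rate",
    "respiratory_rate",
    "systolic_bp",
    "diastolic_bp",
    "mean_bp",
    "temperature_c",
    "spo2",
    "lactate",
    "creatinine",
    "bilirubin",
    "platelet_count",
    "white_blood_cells",
    "bicarbonate",
    "hemoglobin",
    "glucose",
)

# Two small vocabularies for note synthesis; septic-tilted tokens first.
_VOCAB_SEPTIC = (
    "fever", "rigors", "hypotension", "tachycardia", "confusion",
    "oliguria", "mottling", "lethargy", "tachypnea", "hypoxia",
    "cultures", "antibiotics", "lactate", "pressors", "deterioration", "icu",
)
_VOCAB_NEUTRAL = (
    "stable", "comfortable", "ambulating", "tolerating", "diet",
    "afebrile", "alert", "oriented", "plan", "discharge",
    "routine", "monitoring", "unchanged", "baseline", "family", "rest",
)
VOCABULARY = _VOCAB_SEPTIC + _VOCAB_NEUTRAL


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    ``missing_rate_per_channel`` may be a single fraction applied to every
    channel or a mapping channel -> fraction.  When left as ``None`` the rates
    are spread linearly from 0.30 to 0.85 across channels, emulating the
    long-tailed sparsity of real EHR feature matrices.
    """

    n_patients: int = 500
    target_prevalence: float = 0.095
    episode_length_range: tuple[float, float] = (12.0, 48.0)
    feature_channels: Sequence[str] = DEFAULT_CHANNELS
    missing_rate_per_channel: float | Mapping[str, float] | None = None
    note_rate: float = 1.0
    signal_effect: float = 2.0
    note_signal_effect: float = 0.4
    ramp_windows: int = 48
    note_tokens_range: tuple[int, int] = (8, 25)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0.0 <= self.target_prevalence <= 1.0:
            raise ValueError("target_prevalence must lie in [0, 1]")
        lo, hi = self.episode_length_range
        if not (lo >= 1.0 and hi >= lo):
            raise ValueError("episode_length_range must satisfy 1 <= min <= max")
        if self.note_rate < 0:
            raise ValueError("note_rate must be non-negative")
        if self.ramp_windows < 1:
            raise ValueError("ramp_windows must be >= 1")
        rates = self.missing_rates()
        if rates and min(rates.values()) >= 1.0:
            raise ValueError("at least one channel needs a missing rate < 1")
        if rates and (min(rates.values()) < 0 or max(rates.values()) > 1.0):
            raise ValueError("missing rates must lie in [0, 1]")

    def missing_rates(self) -> dict[str, float]:
        chans = list(self.feature_channels)
        if self.missing_rate_per_channel is None:
            if len(chans) == 1:
                return {chans[0]: 0.5}
            rates = np.linspace(0.30, 0.85, len(chans))
            return dict(zip(chans, rates.tolist()))
        if isinstance(self.missing_rate_per_channel, Mapping):
            return {c: float(self.missing_rate_per_channel.get(c, 0.0)) for c in chans}
        return {c: float(self.missing_rate_per_channel) for c in chans}

    def channel_stats(self) -> dict[str, tuple[float, float]]:
        """Per-channel (mean, sd) on an arbitrary but fixed scale."""
        chans = list(self.feature_channels)
        means = np.linspace(5.0, 50.0, max(len(chans), 1))
        sds = np.linspace(0.8, 4.0, max(len(chans), 1))
        return {c: (float(m), float(s)) for c, m, s in zip(chans, means, sds)}


TRUTH_COLUMNS = [
    "patient_id", "age_years", "discharge_h", "death_h",
    "true_septic", "true_onset_h", "suspicion_h", "dysfunction_h",
]


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TRUTH_COLUMNS})


def _plant_septic_events(rng, pid, onset_h):
    """One qualifying suspicion/dysfunction pair with dysfunction at onset."""
    rows = []
    suspicion_h = max(0.0, onset_h - float(rng.uniform(0.0, 24.0)))
    d1 = float(rng.uniform(0.5, 12.0))
    d2 = d1 + float(rng.uniform(0.5, 12.0))
    rows.append((pid, suspicion_h, ev.KIND_CULTURE, "culture", 1.0))
    rows.append((pid, suspicion_h + d1, ev.KIND_ABX, "antimicrobial", 1.0))
    rows.append((pid, suspicion_h + d2, ev.KIND_ABX, "antimicrobial", 1.0))
    # Low SOFA before onset, the >=2-point rise exactly at onset.
    for t in sorted(rng.uniform(0.0, max(onset_h - 1.0, 0.5), size=2).tolist()):
        if t < onset_h - 0.5:
            rows.append((pid, t, ev.KIND_SOFA, "sofa", float(rng.integers(0, 2))))
    rows.append((pid, onset_h, ev.KIND_SOFA, "sofa", 3.0))
    return rows, suspicion_h


def _plant_nonseptic_events(rng, pid, discharge_h):
    """Background treatment events that each violate one Sepsis-3 rule."""
    rows = []
    mode = int(rng.integers(0, 4))
    t0 = float(rng.uniform(0.0, max(discharge_h - 1.0, 0.5)))
    if mode == 1:  # single antimicrobial dose: fails the two-dose requirement
        rows.append((pid, t0, ev.KIND_ABX, "antimicrobial", 1.0))
        rows.append((pid, min(t0 + 2.0, discharge_h), ev.KIND_CULTURE, "culture", 1.0))
        rows.append((pid, t0, ev.KIND_SOFA, "sofa", 3.0))
    elif mode == 2:  # culture 30 h after first dose: exceeds the 24 h bound
        rows.append((pid, t0, ev.KIND_ABX, "antimicrobial", 1.0))
        rows.append((pid, t0 + 1.0, ev.KIND_ABX, "antimicrobial", 1.0))
        rows.append((pid, t0 + 30.0, ev.KIND_CULTURE, "culture", 1.0))
        rows.append((pid, t0, ev.KIND_SOFA, "sofa", 3.0))
    elif mode == 3:  # valid suspicion but SOFA never rises 2 above baseline
        rows.append((pid, t0, ev.KIND_CULTURE, "culture", 1.0))
        rows.append((pid, t0 + 1.0, ev.KIND_ABX, "antimicrobial", 1.0))
        rows.append((pid, t0 + 2.0, ev.KIND_ABX, "antimicrobial", 1.0))
        rows.append((pid, t0, ev.KIND_SOFA, "sofa", 1.0))
    else:  # mode 0: no treatment events at all
        rows.append((pid, t0, ev.KIND_SOFA, "sofa", 0.0))
    return rows


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (event stream, ground truth) for a seeded synthetic cohort.

    The event stream contains vitals/labs on the 1 h grid (subject to the
    configured missingness), antimicrobial-dose, culture-order, and SOFA
    events.  The ground-truth table has one row per patient with the planted
    septic flag, onset hour, and suspicion/dysfunction times; it doubles as
    the admission table (age, discharge, death).
    """
    if config.n_patients == 0:
        return ev.empty_stream(), _empty_truth()

    rates = config.missing_rates()
    stats = config.channel_stats()
    lo, hi = config.episode_length_range
    rows: list[tuple] = []
    truth_rows: list[dict] = []

    # Episode lengths cluster on a handful of typical durations (6 h apart)
    # rather than spreading uniformly: care-episode length distributions are
    # peaked in practice, and the length-stratified splitter assumes strata
    # large enough to survive its small-stratum omission rule.
    length_classes = np.arange(math.ceil(lo), math.floor(hi) + 1, 6, dtype=float)
    if len(length_classes) == 0:
        length_classes = np.asarray([float(math.ceil(lo))])

    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        rng = child_rng(config.seed, "cohort", i)
        age = float(rng.uniform(16.0, 90.0))
        length = float(rng.choice(length_classes))
        discharge_h = length - float(rng.uniform(0.05, 0.75))
        septic = bool(rng.random() < config.target_prevalence)

        onset_h = suspicion_h = dysfunction_h = math.nan
        if septic:
            # The onset ends the episode, so it lands in the last window of
            # the drawn length class; sepsis develops deep into the stay.
            onset_h = discharge_h - float(rng.uniform(0.0, 0.2))
            planted, suspicion_h = _plant_septic_events(rng, pid, onset_h)
            dysfunction_h = onset_h
            rows.extend(planted)
        else:
            rows.extend(_plant_nonseptic_events(rng, pid, discharge_h))

        end_h = onset_h if septic else discharge_h
        n_windows = int(math.floor(end_h)) + 1
        onset_window = int(math.floor(onset_h)) if septic else None
        for k in range(n_windows):
            for ch in config.feature_channels:
                if rng.random() < rates[ch]:
                    continue
                mean, sd = stats[ch]
                value = mean + sd * float(rng.standard_normal())
                if septic and onset_window - config.ramp_windows < k <= onset_window:
                    ramp = (config.ramp_windows - (onset_window - k)) / config.ramp_windows
                    value += config.signal_effect * sd * ramp
                kind = ev.KIND_LAB if ch in DEFAULT_CHANNELS[7:] else ev.KIND_VITAL
                rows.append((pid, k + 0.5, kind, ch, value))

        truth_rows.append(
            {
                "patient_id": pid,
                "age_years": age,
                "discharge_h": discharge_h,
                "death_h": math.nan,
                "true_septic": septic,
                "true_onset_h": onset_h,
                "suspicion_h": suspicion_h,
                "dysfunction_h": dysfunction_h,
            }
        )

    stream = pd.DataFrame(rows, columns=ev.COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return ev.validate_stream(stream), truth


def _note_token_probs(signal_effect: float) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional token distributions (septic, non-septic).

    At ``signal_effect == 0`` the two distributions are identical (uniform);
    positive values tilt septic notes toward the septic-flavoured half of the
    vocabulary via an exponential weighting.
    """
    v = len(VOCABULARY)
    tilt = np.where(np.arange(v) < len(_VOCAB_SEPTIC), 1.0, -1.0)
    p_sep = np.exp(signal_effect * tilt)
    p_sep /= p_sep.sum()
    p_neg = np.full(v, 1.0 / v)
    return p_sep, p_neg


def generate_notes(config: SynthConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Synthesize note events as token bags from two class-conditional mixtures."""
    if len(truth) == 0 or config.note_rate == 0:
        return ev.empty_stream()
    p_sep, p_neg = _note_token_probs(config.note_signal_effect)
    vocab = np.asarray(VOCABULARY, dtype=object)
    lo_tok, hi_tok = config.note_tokens_range
    rows: list[tuple] = []
    for i, rec in enumerate(truth.itertuples(index=False)):
        rng = child_rng(config.seed, "notes", i)
        septic = bool(rec.true_septic)
        end_h = rec.true_onset_h if septic else rec.discharge_h
        probs = p_sep if septic else p_neg
        for k in range(int(math.floor(end_h)) + 1):
            for _ in range(rng.poisson(config.note_rate)):
                n_tok = int(rng.integers(lo_tok, hi_tok + 1))
                tokens = rng.choice(len(vocab), size=n_tok, p=probs)
                text = " ".join(vocab[tokens])
                rows.append((rec.patient_id, k + 0.5, ev.KIND_NOTE, "note", text))
    if not rows:
        return ev.empty_stream()
    return ev.validate_stream(pd.DataFrame(rows, columns=ev.COLUMNS))


def admissions_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Admission metadata view (patient_id, age_years, discharge_h, death_h)."""
    return truth[["patient_id", "age_years", "discharge_h", "death_h"]].copy()
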