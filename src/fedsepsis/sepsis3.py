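"""Sepsis-3 operationalization: suspected infection, organ dysfunction, onset.

Suspected infection requires at least two antimicrobial doses paired with a
culture order: culture within 24 h after the first dose when the dose comes
first, or the first dose within 72 h after the culture when the culture comes
first.  Organ dysfunction is a SOFA score at least 2 points above baseline
inside [suspicion - 48 h, suspicion + 24 h], the baseline being the latest
score strictly before suspicion - 72 h (zero if none).  The onset is assigned
to the time-window of the qualifying dysfunction; when several
suspicion/dysfunction pairs qualify, the latest window wins by default (the
``earliest`` policy is available).  All boundary comparisons are inclusive and
windows are half-open [k, k+1) hours.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from . import events as ev

ABX_CULTURE_MAX_GAP_H = 24.0
CULTURE_ABX_MAX_GAP_H = 72.0
SOFA_LOOKBACK_H = 48.0
SOFA_LOOKAHEAD_H = 24.0
BASELINE_LOOKBACK_H = 72.0
SOFA_RISE_POINTS = 2.0
MIN_AGE_YEARS = 15.0
MAX_EPISODE_WINDOWS = 48


@dataclasses.dataclass(frozen=True)
class SuspicionWindow:
    patient_id: str
    suspicion_h: float
    abx_times: tuple[float, ...]
    culture_time: float
    ordering: str  # "abx_first" | "culture_first"


@dataclasses.dataclass(frozen=True)
class DysfunctionResult:
    flag: bool
    dysfunction_h: float | None
    baseline: float


@dataclasses.dataclass(frozen=True)
class SepsisOnset:
    patient_id: str
    onset_h: float | None
    onset_window: int | None
    suspicion_h: float | None
    baseline: float | None

    @property
    def septic(self) -> bool:
        return self.onset_h is not None


def _check_sorted(times: np.ndarray, what: str) -> None:
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError(f"{what} events must be time-sorted")


def detect_suspected_infection(
    abx_times, culture_times, patient_id: str = ""
) -> list[SuspicionWindow]:
    """All (antimicrobial pair, culture) combinations satisfying the pairing rule.

    One window per culture order; the dose clock runs from the first
    antimicrobial dose.  Two doses means two dose events at distinct times.
    """
    abx = np.asarray(sorted(set(float(t) for t in abx_times)))
    cultures = np.asarray([float(t) for t in culture_times])
    _check_sorted(cultures, "culture")
    if len(abx) < 2 or len(cultures) == 0:
        return []
    first_abx = float(abx[0])
    windows = []
    for c in cultures:
        if first_abx <= c:
            ok = (c - first_abx) <= ABX_CULTURE_MAX_GAP_H
            ordering = "abx_first"
        else:
            ok = (first_abx - c) <= CULTURE_ABX_MAX_GAP_H
            ordering = "culture_first"
        if ok:
            windows.append(
                SuspicionWindow(
                    patient_id=patient_id,
                    suspicion_h=min(first_abx, float(c)),
                    abx_times=tuple(abx.tolist()),
                    culture_time=float(c),
                    ordering=ordering,
                )
            )
    return windows


def organ_dysfunction(sofa_times, sofa_scores, suspicion_h: float) -> DysfunctionResult:
    """SOFA rise >= 2 points over baseline inside [-48 h, +24 h] around suspicion.

    Baseline is the latest score strictly before ``suspicion_h - 72``; with no
    prior assessment the baseline is zero.  The earliest qualifying time is
    reported.
    """
    times = np.asarray([float(t) for t in sofa_times])
    scores = np.asarray([float(s) for s in sofa_scores])
    if len(times) != len(scores):
        raise ValueError("SOFA times and scores must align")
    _check_sorted(times, "SOFA")
    if len(times) == 0:
        return DysfunctionResult(False, None, 0.0)
    before = times < suspicion_h - BASELINE_LOOKBACK_H
    baseline = float(scores[before][-1]) if before.any() else 0.0
    in_window = (times >= suspicion_h - SOFA_LOOKBACK_H) & (
        times <= suspicion_h + SOFA_LOOKAHEAD_H
    )
    qualifying = in_window & (scores - baseline >= SOFA_RISE_POINTS)
    if not qualifying.any():
        return DysfunctionResult(False, None, baseline)
    return DysfunctionResult(True, float(times[qualifying][0]), baseline)


def assign_onset(
    suspicions: list[SuspicionWindow],
    sofa_times,
    sofa_scores,
    policy: str = "latest",
    patient_id: str = "",
) -> SepsisOnset:
    """Pick the onset among all qualifying suspicion/dysfunction pairs."""
    if policy not in ("latest", "earliest"):
        raise ValueError("policy must be 'latest' or 'earliest'")
    candidates = []
    for susp in suspicions:
        res = organ_dysfunction(sofa_times, sofa_scores, susp.suspicion_h)
        if res.flag:
            candidates.append((res.dysfunction_h, susp.suspicion_h, res.baseline))
    if not candidates:
        return SepsisOnset(patient_id, None, None, None, None)
    pick = max(candidates) if policy == "latest" else min(candidates)
    onset_h, suspicion_h, baseline = pick
    return SepsisOnset(
        patient_id, onset_h, int(math.floor(onset_h)), suspicion_h, baseline
    )


def label_patient(patient_events: pd.DataFrame, policy: str = "latest") -> SepsisOnset:
    """Run the full Sepsis-3 rule set on one patient's event stream."""
    pid = str(patient_events["patient_id"].iloc[0]) if len(patient_events) else ""
    kinds = patient_events["kind"]
    abx = patient_events.loc[kinds == ev.KIND_ABX, "time_h"].astype(float)
    cult = patient_events.loc[kinds == ev.KIND_CULTURE, "time_h"].astype(float)
    sofa = patient_events.loc[kinds == ev.KIND_SOFA, ["time_h", "value"]]
    suspicions = detect_suspected_infection(
        abx.tolist(), sorted(cult.tolist()), patient_id=pid
    )
    return assign_onset(
        suspicions,
        sofa["time_h"].astype(float).tolist(),
        sofa["value"].astype(float).tolist(),
        policy=policy,
        patient_id=pid,
    )


def label_cohort(events: pd.DataFrame, policy: str = "latest") -> pd.DataFrame:
    """Onset table (patient_id, septic, onset_h, onset_window, suspicion_h, baseline)."""
    events = ev.validate_stream(events)
    rows = []
    for pid, grp in events.groupby("patient_id", sort=True):
        onset = label_patient(grp, policy=policy)
        rows.append(
            {
                "patient_id": pid,
                "septic": onset.septic,
                "onset_h": onset.onset_h if onset.septic else math.nan,
                "onset_window": onset.onset_window if onset.septic else pd.NA,
                "suspicion_h": onset.suspicion_h if onset.septic else math.nan,
                "baseline": onset.baseline if onset.septic else math.nan,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "septic", "onset_h", "onset_window", "suspicion_h", "baseline"]
        )
    return pd.DataFrame(rows)


def select_cohort(admissions: pd.DataFrame, onsets: pd.DataFrame) -> pd.DataFrame:
    """Care-episode endpoints: age > 15, endpoint = earliest of onset/death/discharge.

    The episode covers [max(0, endpoint - 48), endpoint], later binned into
    1 h windows; ``onset_window`` is re-expressed relative to episode start.
    """
    merged = admissions.merge(onsets, on="patient_id", how="left")
    rows = []
    for rec in merged.itertuples(index=False):
        if pd.isna(rec.discharge_h):
            warnings.warn(f"skipping {rec.patient_id}: missing admission times")
            continue
        if not float(rec.age_years) > MIN_AGE_YEARS:
            continue
        endpoints = [float(rec.discharge_h)]
        if not pd.isna(rec.death_h):
            endpoints.append(float(rec.death_h))
        septic = bool(rec.septic) if not pd.isna(rec.septic) else False
        if septic and not pd.isna(rec.onset_h):
            endpoints.append(float(rec.onset_h))
        end_h = min(endpoints)
        start_h = max(0.0, end_h - float(MAX_EPISODE_WINDOWS))
        n_windows = max(1, int(math.ceil(end_h - start_h)))
        onset_rel = None
        if septic and not pd.isna(rec.onset_h) and float(rec.onset_h) >= start_h:
            # An onset exactly at the episode end falls in the last window.
            onset_rel = min(int(math.floor(float(rec.onset_h) - start_h)), n_windows - 1)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "start_h": start_h,
                "end_h": end_h,
                "n_windows": n_windows,
                "label": septic,
                "onset_window": onset_rel,
            }
        )
    cols = ["patient_id", "start_h", "end_h", "n_windows", "label", "onset_window"]
    return pd.DataFrame(rows, columns=cols)
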