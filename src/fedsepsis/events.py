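"""Long-format clinical event streams.

An event stream is a :class:`pandas.DataFrame` with one row per timestamped
observation and columns ``patient_id, time_h, kind, channel, value``.
``time_h`` is real-valued hours since admission (hour 0).  ``kind`` tags the
payload type: note events carry text, every other kind carries a real number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

COLUMNS = ["patient_id", "time_h", "kind", "channel", "value"]

KIND_VITAL = "vital"
KIND_LAB = "lab"
KIND_DEMOGRAPHIC = "demographic"
KIND_NOTE = "note"
KIND_ABX = "antimicrobial_dose"
KIND_CULTURE = "culture_order"
KIND_SOFA = "sofa_score"

KINDS = (
    KIND_VITAL,
    KIND_LAB,
    KIND_DEMOGRAPHIC,
    KIND_NOTE,
    KIND_ABX,
    KIND_CULTURE,
    KIND_SOFA,
)

NUMERIC_KINDS = tuple(k for k in KINDS if k != KIND_NOTE)


def empty_stream() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=object),
            "time_h": pd.Series(dtype=float),
            "kind": pd.Series(dtype=object),
            "channel": pd.Series(dtype=object),
            "value": pd.Series(dtype=object),
        }
    )


def validate_stream(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-stream contract; returns the frame sorted by (patient, time)."""
    missing = [c for c in COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event stream lacks columns: {missing}")
    if len(events) == 0:
        return events.copy()
    if (pd.to_numeric(events["time_h"], errors="coerce") < 0).any():
        raise ValueError("event times must be non-negative hours from admission")
    bad = set(events["kind"]) - set(KINDS)
    if bad:
        raise ValueError(f"unknown event kinds: {sorted(bad)}")
    return events.sort_values(["patient_id", "time_h"], kind="mergesort").reset_index(
        drop=True
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        events[COLUMNS].to_parquet(path, index=False)
    else:
        events[COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        events = pd.read_parquet(path)
    else:
        events = pd.read_csv(path)
    return validate_stream(events)
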