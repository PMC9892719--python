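"""Reading and writing event tables.

Event tables are plain CSV with one row per event and documented columns:

    time, fsc_a, fsc_h, ssc_a, cfse, violet, disc3, pi
    [+ optional synthetic-truth columns: is_sperm, is_doublet, is_dead,
       true_barcode, em_state, true_well]

``time`` is acquisition time in seconds; fluorescence and scatter are
linear arbitrary units.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("time", "fsc_a", "fsc_h", "ssc_a", "cfse", "violet", "disc3", "pi")
TRUTH_COLUMNS = ("is_sperm", "is_doublet", "is_dead", "true_barcode", "em_state")


def read_events_csv(path: str) -> pd.DataFrame:
    """Read an event table, validating the required channel columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns: {missing}")
    for col in ("true_barcode", "em_state", "true_well"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_events_csv(events: pd.DataFrame, path: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events.to_csv(path, index=False)
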