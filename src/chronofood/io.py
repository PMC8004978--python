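"""Reading and writing the package's tabular interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["read_event_log", "write_event_log"]


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read an ingestion-event log from JSONL or CSV.

    Expected fields: ``participant_id``, ``timestamp`` (ISO-8601 with
    timezone), ``text``; ``phase`` is optional.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        records = [json.loads(line) for line in path.read_text("utf-8").splitlines() if line.strip()]
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.read_csv(path)
    required = {"participant_id", "timestamp", "text"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"event log {path} lacks columns: {sorted(missing)}")
    frame["text"] = frame["text"].fillna("")
    return frame


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event log as JSONL or CSV depending on the file suffix."""
    path = Path(path)
    cols = [c for c in ("participant_id", "timestamp", "text", "phase") if c in events.columns]
    frame = events[cols]
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with path.open("w") as fh:
            for rec in frame.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        frame.to_csv(path, index=False)
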