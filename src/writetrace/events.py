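"""Editor-event and fixation records, and their delimited-text file formats.

The atom of a keystroke log is one timestamped editor action.  Logs are
tab-delimited text with a header row, one row per event, times in integer
milliseconds.  Columns::

    participant  language  t_ms  action  payload  cursor_before  cursor_after

``action`` is one of ``insert``, ``backspace``, ``delete_range``,
``cursor_move``, ``mouse_move``, ``shift``.  ``payload`` holds the inserted
character for ``insert`` and the half-open range ``start:end`` for
``delete_range``; it is empty otherwise.

Fixation streams use the columns::

    participant  language  t_start_ms  duration_ms  x_px  y_px  on_prompt
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ParseError

ACTIONS = ("insert", "backspace", "delete_range", "cursor_move", "mouse_move", "shift")

EVENT_COLUMNS = [
    "participant",
    "language",
    "t_ms",
    "action",
    "payload",
    "cursor_before",
    "cursor_after",
]

FIXATION_COLUMNS = [
    "participant",
    "language",
    "t_start_ms",
    "duration_ms",
    "x_px",
    "y_px",
    "on_prompt",
]


@dataclass(frozen=True)
class EditorEvent:
    """One timestamped editor action.

    ``cursor_before``/``cursor_after`` are 0-based character indices into the
    document as it was immediately before/after the action.
    """

    t_ms: int
    action: str
    payload: str = ""
    cursor_before: int = 0
    cursor_after: int = 0


def events_to_frame(events: Iterable[EditorEvent], participant: str, language: str) -> pd.DataFrame:
    rows = [
        (participant, language, e.t_ms, e.action, e.payload, e.cursor_before, e.cursor_after)
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(frame: pd.DataFrame) -> list[EditorEvent]:
    return [
        EditorEvent(int(r.t_ms), r.action, r.payload, int(r.cursor_before), int(r.cursor_after))
        for r in frame.itertuples()
    ]


def _check_payload(payload) -> str:
    payload = "" if payload is None or (isinstance(payload, float) and pd.isna(payload)) else str(payload)
    if "\t" in payload or "\n" in payload:
        raise ValueError("payload may not contain tab or newline characters")
    return payload


def write_event_log(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an event log as tab-delimited text (round-trip stable)."""
    out = frame.copy()
    out["payload"] = [_check_payload(p) for p in out["payload"]]
    for col in ("t_ms", "cursor_before", "cursor_after"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS, lineterminator="\n")


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read and validate an event log written by :func:`write_event_log`.

    Raises :class:`ParseError` with a 1-based line number for malformed rows
    or for timestamps that go backwards within a participant x language
    session.
    """
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            dtype={"participant": str, "language": str, "action": str},
            keep_default_na=False,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse event log: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", line=1)
    for i, row in enumerate(frame.itertuples(), start=2):
        if row.action not in ACTIONS:
            raise ParseError(f"unknown action {row.action!r}", line=i)
        try:
            int(row.t_ms), int(row.cursor_before), int(row.cursor_after)
        except (TypeError, ValueError):
            raise ParseError("non-integer time or cursor field", line=i) from None
    for col in ("t_ms", "cursor_before", "cursor_after"):
        frame[col] = frame[col].astype(int)
    last: dict[tuple[str, str], tuple[int, int]] = {}
    for i, row in enumerate(frame.itertuples(), start=2):
        key = (row.participant, row.language)
        if key in last and row.t_ms < last[key][0]:
            raise ParseError(
                f"timestamp {row.t_ms} before previous {last[key][0]} in session {key}", line=i
            )
        last[key] = (row.t_ms, i)
    return frame


def write_fixations(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out["on_prompt"] = out["on_prompt"].astype(int)
    for col in ("t_start_ms", "duration_ms"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, columns=FIXATION_COLUMNS, lineterminator="\n")


def read_fixations(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"participant": str, "language": str})
    missing = [c for c in FIXATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", line=1)
    frame["on_prompt"] = frame["on_prompt"].astype(bool)
    return frame
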