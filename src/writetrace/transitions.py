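"""Classify consecutive editor-event pairs into the typing-action taxonomy.

A *transition* is a pair of temporally consecutive editor events.  Its
location in the text (pre-sentence, pre-word, within-word) is read off the
replayed document state; whether it is a *writing* or an *editing* transition
depends on the second event.  Raw types:

======================  =====================================================
within-word             letter followed by letter
post-word               letter followed by space (reported merged into
                        within-word: the word-final/word-internal status of a
                        letter cannot be decided at edit time, so the merge
                        keeps writing and editing categories comparable)
pre-word                space then letter, mid-sentence
pre-sentence            space then letter, where the space follows
                        sentence-terminating punctuation
word->edit              letter followed by a deletion or cursor move
pre-word->edit          letter+space followed by a deletion or cursor move
pre-sentence->edit      terminator+space followed by a deletion or cursor move
other                   anything else (post-edit resumption, mouse noise);
                        excluded downstream
======================  =====================================================

Two timing quirks are honoured: an uppercase letter is produced by shift then
character, and the transition is timed to the shift keypress; and a run of
cursor moves that returns the cursor exactly to its prior position with no
intervening edit is treated as part of a non-editing transition (the writer
used the cursor to support lookback, not to edit).
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .errors import ConfigError
from .events import EditorEvent
from .replay import SENTENCE_TERMINATORS, DocState, DocumentTimeline

WRITING_RAW = ("within-word", "post-word", "pre-word", "pre-sentence")
EDIT_RAW = ("word->edit", "pre-word->edit", "pre-sentence->edit")

LOCATIONS = ("pre-sentence", "pre-word", "within-word")

_EDIT_ACTIONS = ("backspace", "delete_range")

TRANSITION_COLUMNS = [
    "participant",
    "language",
    "idx_first",
    "idx_second",
    "t_first",
    "t_second",
    "iki",
    "raw_type",
    "location",
    "mode",
]


def location_of(raw_type: str) -> str | None:
    """Map a raw transition type to its merged text location."""
    if raw_type in ("within-word", "post-word", "word->edit"):
        return "within-word"
    if raw_type in ("pre-word", "pre-word->edit"):
        return "pre-word"
    if raw_type in ("pre-sentence", "pre-sentence->edit"):
        return "pre-sentence"
    return None


def _char_before_space(state: DocState) -> str | None:
    """Character preceding the just-typed space, in the text at that time."""
    if state.poi >= 1 and state.poi < len(state.text):
        return state.text[state.poi - 1]
    return None


def _classify_writing(a: EditorEvent, next_char: str, state_after_a: DocState) -> str:
    prev_char = a.payload
    if not prev_char.isspace():
        return "within-word" if not next_char.isspace() else "post-word"
    if next_char.isspace():
        return "other"
    before = _char_before_space(state_after_a)
    if before is not None and before in SENTENCE_TERMINATORS:
        return "pre-sentence"
    if before is not None and not before.isspace():
        return "pre-word"
    return "other"


def _classify_edit(a: EditorEvent, state_after_a: DocState) -> str:
    if a.action != "insert":
        return "other"
    if not a.payload.isspace():
        return "word->edit"
    before = _char_before_space(state_after_a)
    if before is None or before.isspace():
        return "other"
    return "pre-sentence->edit" if before in SENTENCE_TERMINATORS else "pre-word->edit"


def classify_transitions(
    events: list[EditorEvent],
    timeline: DocumentTimeline,
    participant: str = "p0",
    language: str = "L1",
) -> pd.DataFrame:
    """Label every eligible consecutive event pair.

    ``timeline`` must be the replay of ``events``.  Returns one row per
    transition with the schema in :data:`TRANSITION_COLUMNS`.
    """
    if len(timeline.states) != len(events):
        raise ValueError("timeline does not match events (replay the same stream)")
    records: list[tuple] = []

    def emit(i: int, j: int, t2: int, raw: str) -> None:
        a = events[i]
        mode = "writing" if raw in WRITING_RAW else "editing" if raw in EDIT_RAW else "other"
        records.append(
            (
                participant,
                language,
                i,
                j,
                a.t_ms,
                t2,
                t2 - a.t_ms,
                "within-word" if raw == "post-word" else raw,
                location_of(raw),
                mode,
            )
        )

    n = len(events)
    i = 0
    while i < n - 1:
        a = events[i]
        state_a = timeline.states[i]
        if a.action == "mouse_move":
            i += 1
            continue
        b = events[i + 1]
        if b.action == "shift":
            if i + 2 < n and events[i + 2].action == "insert":
                raw = (
                    _classify_writing(a, events[i + 2].payload, state_a)
                    if a.action == "insert"
                    else "other"
                )
                emit(i, i + 1, b.t_ms, raw)
                i += 2
                continue
            emit(i, i + 1, b.t_ms, "other")
            i += 1
            continue
        if b.action in ("cursor_move", "mouse_move"):
            k = i + 1
            while k + 1 < n and events[k + 1].action in ("cursor_move", "mouse_move"):
                k += 1
            returned = timeline.states[k].cursor == b.cursor_before
            nxt = events[k + 1] if k + 1 < n else None
            if returned and nxt is not None and nxt.action in ("insert", "shift"):
                if nxt.action == "insert":
                    raw = (
                        _classify_writing(a, nxt.payload, state_a)
                        if a.action == "insert"
                        else "other"
                    )
                    emit(i, k + 1, nxt.t_ms, raw)
                    i = k + 1
                    continue
                if k + 2 < n and events[k + 2].action == "insert":
                    raw = (
                        _classify_writing(a, events[k + 2].payload, state_a)
                        if a.action == "insert"
                        else "other"
                    )
                    emit(i, k + 1, nxt.t_ms, raw)
                    i = k + 2
                    continue
            if b.action == "mouse_move":
                emit(i, i + 1, b.t_ms, "other")
            else:
                emit(i, i + 1, b.t_ms, _classify_edit(a, state_a))
            i += 1
            continue
        if b.action in _EDIT_ACTIONS:
            emit(i, i + 1, b.t_ms, _classify_edit(a, state_a))
            i += 1
            continue
        # b is an insert
        if a.action == "insert":
            emit(i, i + 1, b.t_ms, _classify_writing(a, b.payload, state_a))
        else:
            emit(i, i + 1, b.t_ms, "other")
        i += 1
    return pd.DataFrame(records, columns=TRANSITION_COLUMNS)


def production_sequences(
    events: list[EditorEvent], participant: str = "p0", language: str = "L1"
) -> pd.DataFrame:
    """Runs of writing keystrokes terminated by an editing action.

    Cursor runs that return to their origin and are followed by typing do not
    terminate a sequence (they are lookback-supporting, not editing).  The
    final unterminated run counts as a sequence; mean length per session
    indexes production fluency.
    """
    lengths: list[int] = []
    terminators: list[int | None] = []
    cur = 0
    n = len(events)
    cursor_pos = 0
    i = 0
    while i < n:
        ev = events[i]
        if ev.action == "insert":
            cur += 1
            cursor_pos = ev.cursor_before + 1
        elif ev.action in _EDIT_ACTIONS:
            if cur > 0:
                lengths.append(cur)
                terminators.append(i)
            cur = 0
            cursor_pos = ev.cursor_before - 1 if ev.action == "backspace" else int(
                ev.payload.split(":")[0]
            )
        elif ev.action == "cursor_move":
            k = i
            while k + 1 < n and events[k + 1].action in ("cursor_move", "mouse_move"):
                k += 1
            returned = events[k].cursor_after == ev.cursor_before
            nxt_typing = k + 1 < n and events[k + 1].action in ("insert", "shift")
            if not (returned and nxt_typing):
                if cur > 0:
                    lengths.append(cur)
                    terminators.append(i)
                cur = 0
            cursor_pos = events[k].cursor_after
            i = k + 1
            continue
        i += 1
    if cur > 0:
        lengths.append(cur)
        terminators.append(None)
    return pd.DataFrame(
        {
            "participant": participant,
            "language": language,
            "length": lengths,
            "terminating_event": terminators,
        }
    )


def filter_ikis(
    transitions: pd.DataFrame, min_iki_ms: float = 50.0, max_iki_ms: float = 30_000.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop implausibly short and very long transition durations.

    Durations <= ``min_iki_ms`` typically come from two keys pressed at once;
    durations >= ``max_iki_ms`` from off-task activity.  Returns the retained
    transitions and a per-participant exclusion report with percentages at
    both tails.
    """
    low = transitions["iki"] <= min_iki_ms
    high = transitions["iki"] >= max_iki_ms
    kept = transitions.loc[~(low | high)].copy()
    grp = transitions.assign(low=low, high=high).groupby("participant", observed=True)
    report = grp.agg(n=("iki", "size"), n_low=("low", "sum"), n_high=("high", "sum"))
    report["pct_low"] = 100.0 * report["n_low"] / report["n"]
    report["pct_high"] = 100.0 * report["n_high"] / report["n"]
    return kept, report.reset_index()


def subsample_cell(transitions: pd.DataFrame, cap: int = 200, seed: int = 0) -> pd.DataFrame:
    """Cap each participant x language x location x mode cell by seeded sampling.

    Cells larger than ``cap`` are reduced to exactly ``cap`` rows by uniform
    sampling without replacement; smaller cells pass through.  The selection
    depends only on the seed and the cell contents (rows are ordered by time
    before sampling), not on the row order of the input frame.
    """
    if cap < 1:
        raise ConfigError(f"cap must be >= 1, got {cap}")
    keys = ["participant", "language", "location", "mode"]
    pieces = []
    groups = transitions.groupby(keys, observed=True, dropna=False, sort=True)
    for key, grp in groups:
        grp = grp.sort_values(["t_first", "idx_first"], kind="mergesort")
        if len(grp) > cap:
            # seed from the cell key itself so that subsampling a single cell
            # in isolation gives the same rows as subsampling the full table
            key_int = int.from_bytes(
                hashlib.blake2s("\x1f".join(map(str, key)).encode()).digest()[:6], "big"
            )
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key_int,)))
            take = np.sort(rng.choice(len(grp), size=cap, replace=False))
            grp = grp.iloc[take]
        pieces.append(grp)
    if not pieces:
        return transitions.copy()
    return pd.concat(pieces, axis=0).sort_values(["participant", "language", "t_first"]).reset_index(
        drop=True
    )
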