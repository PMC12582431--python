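"""Replay editor events into a time-indexed document model.

During composition the on-screen text changes constantly, so fixations cannot
be mapped to words through static areas of interest.  Instead the keystroke
log is replayed into a :class:`DocumentTimeline` that can answer, for any
instant, what the text was, where the point of inscription (the last-typed
character) was, and how the text segmented into words, sentences and
paragraphs.  Fixations are then anchored against the text state at fixation
onset.

Conventions (documented, not configurable):

* character indices are 0-based; delete ranges are half-open ``[start, end)``;
* a sentence ends at a run of ``.``, ``?`` or ``!`` followed by whitespace
  (synthetic texts contain no abbreviations);
* the point of inscription after an insert is the index of the inserted
  character; after a deletion it is the character before the new cursor;
* the "current sentence" at an insertion point is the count of sentence
  boundaries completed at or before the point of inscription, so a writer who
  has just terminated sentence *k* and typed the following space is about to
  write sentence *k+1* and every existing fixation target is at sentence
  distance >= 1.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnchorError, ReplayError
from .events import EditorEvent

SENTENCE_TERMINATORS = ".?!"

_WORD_RE = re.compile(r"\S+")
_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s)")


@dataclass(frozen=True)
class LayoutModel:
    """Fixed-grid monospace stand-in for the editor's rendering.

    The text area starts below a prompt band of ``prompt_lines`` lines; text
    wraps at ``chars_per_line`` with no word wrap.  The grid is invertible, so
    screen-coordinate and text-anchored input paths agree exactly.
    """

    chars_per_line: int = 80
    px_per_char: float = 12.0
    px_per_line: float = 24.0
    prompt_lines: int = 4

    def char_to_px(self, index: int) -> tuple[float, float]:
        line, col = divmod(index, self.chars_per_line)
        x = (col + 0.5) * self.px_per_char
        y = (self.prompt_lines + line + 0.5) * self.px_per_line
        return x, y

    def px_to_char(self, x: float, y: float) -> int | None:
        """Return the character index under (x, y), or None for the prompt band."""
        line = int(y // self.px_per_line) - self.prompt_lines
        if line < 0:
            return None
        col = min(max(int(x // self.px_per_char), 0), self.chars_per_line - 1)
        return line * self.chars_per_line + col


@dataclass
class DocState:
    t_ms: int
    text: str
    cursor: int
    poi: int  # index of last-typed character; -1 before any keypress


@dataclass
class DocumentTimeline:
    """Snapshots of document state after every event, queryable by time."""

    states: list[DocState] = field(default_factory=list)

    @property
    def final_text(self) -> str:
        return self.states[-1].text if self.states else ""

    def state_at(self, t_ms: float) -> DocState:
        times = [s.t_ms for s in self.states]
        i = bisect.bisect_right(times, t_ms) - 1
        if i < 0:
            return DocState(int(t_ms), "", 0, -1)
        return self.states[i]

    def text_at(self, t_ms: float) -> str:
        return self.state_at(t_ms).text

    def poi_at(self, t_ms: float) -> int:
        return self.state_at(t_ms).poi


def replay(events: list[EditorEvent]) -> DocumentTimeline:
    """Apply editor events in order and record the state after each one.

    Raises :class:`ReplayError`, citing the offending event index, if an
    event refers to positions outside the current document.
    """
    text: list[str] = []
    cursor = 0
    poi = -1
    timeline = DocumentTimeline()
    for i, ev in enumerate(events):
        n = len(text)
        if ev.action == "insert":
            if not (0 <= ev.cursor_before <= n):
                raise ReplayError(f"event {i}: insert at {ev.cursor_before} outside [0, {n}]")
            if len(ev.payload) != 1:
                raise ReplayError(f"event {i}: insert payload must be a single character")
            text.insert(ev.cursor_before, ev.payload)
            cursor = ev.cursor_before + 1
            poi = ev.cursor_before
        elif ev.action == "backspace":
            if ev.cursor_before <= 0 or ev.cursor_before > n:
                raise ReplayError(f"event {i}: backspace at {ev.cursor_before} with length {n}")
            del text[ev.cursor_before - 1]
            cursor = ev.cursor_before - 1
            poi = cursor - 1
        elif ev.action == "delete_range":
            try:
                start, end = (int(v) for v in ev.payload.split(":"))
            except ValueError:
                raise ReplayError(f"event {i}: bad delete_range payload {ev.payload!r}") from None
            if not (0 <= start <= end <= n):
                raise ReplayError(f"event {i}: delete range {start}:{end} outside document")
            del text[start:end]
            cursor = start
            poi = start - 1
        elif ev.action == "cursor_move":
            if not (0 <= ev.cursor_after <= n):
                raise ReplayError(f"event {i}: cursor moved to {ev.cursor_after} outside [0, {n}]")
            cursor = ev.cursor_after
        elif ev.action in ("mouse_move", "shift"):
            pass
        else:
            raise ReplayError(f"event {i}: unknown action {ev.action!r}")
        timeline.states.append(DocState(ev.t_ms, "".join(text), cursor, poi))
    return timeline


# ---------------------------------------------------------------------------
# Segmentation


def word_spans(text: str) -> list[tuple[int, int]]:
    """Half-open spans of maximal non-whitespace runs."""
    return [m.span() for m in _WORD_RE.finditer(text)]


def sentence_boundaries(text: str) -> list[int]:
    """Indices of the whitespace character following each sentence terminator."""
    return [m.end() for m in _BOUNDARY_RE.finditer(text)]


def segment(text: str) -> tuple[list[tuple[int, int]], int, int]:
    """Return (word spans, sentence count, paragraph count).

    A trailing sentence fragment without terminator counts as a sentence;
    paragraphs are newline-separated non-empty blocks.
    """
    words = word_spans(text)
    bounds = sentence_boundaries(text)
    n_sent = len(bounds)
    if bounds:
        tail = text[bounds[-1] + 1 :] if bounds[-1] + 1 <= len(text) else ""
    else:
        tail = text
    if tail.strip():
        n_sent += 1
    paragraphs = [p for p in re.split(r"\n+", text) if p.strip()]
    return words, n_sent, len(paragraphs)


def sentence_ordinal_of_char(text: str, index: int) -> int:
    """0-based sentence index of the character at ``index``.

    A character strictly after *k* completed boundaries lies in sentence *k*.
    """
    return bisect.bisect_right(sentence_boundaries(text), index)


def current_sentence_ordinal(text: str, poi: int) -> int:
    """Sentence that the *next* typed character will join.

    Counts boundaries whose trailing whitespace lies at or before the point
    of inscription, so immediately after ``". "`` the writer is in the next,
    still-empty sentence.
    """
    return bisect.bisect_right(sentence_boundaries(text), poi + 1)


# ---------------------------------------------------------------------------
# Fixation anchoring

ANCHORED_COLUMNS = [
    "participant",
    "language",
    "t_start_ms",
    "duration_ms",
    "region",  # text | prompt | off
    "char_index",
    "word_index",
    "sentence_ord",
    "paragraph",
    "word_dist",
    "char_dist",
    "sent_dist",
    "ahead",
]


def _anchor_one(char_index: int, state: DocState) -> dict:
    text = state.text
    spans = word_spans(text)
    starts = [s for s, _ in spans]
    if char_index >= len(text):
        return {"region": "off"}
    wi = bisect.bisect_right(starts, char_index) - 1
    if wi < 0 or char_index >= spans[wi][1]:
        # whitespace between words: snap to the preceding word's last char
        if wi < 0:
            return {"region": "off"}
        char_index = spans[wi][1] - 1
    start, end = spans[wi]
    poi = state.poi
    poi_word = bisect.bisect_right(starts, poi) - 1 if poi >= 0 else -1
    if end - 1 <= poi:
        # word entirely behind the point of inscription: nearest edge is its
        # last character
        char_dist = poi - (end - 1)
        ahead = False
    elif start <= poi < end:
        char_dist = 0
        ahead = False
    else:
        char_dist = poi - start  # negative: ahead of the point of inscription
        ahead = True
    word_dist = poi_word - wi
    fix_ord = sentence_ordinal_of_char(text, start)
    cur_ord = current_sentence_ordinal(text, poi)
    return {
        "region": "text",
        "char_index": char_index,
        "word_index": wi,
        "sentence_ord": fix_ord,
        "paragraph": 0,
        "word_dist": word_dist,
        "char_dist": char_dist,
        "sent_dist": cur_ord - fix_ord,
        "ahead": ahead,
    }


def anchor_fixations(
    fixations: pd.DataFrame, timeline: DocumentTimeline, layout: LayoutModel
) -> pd.DataFrame:
    """Map fixations onto the text as it existed at fixation onset.

    Accepts the raw fixation format (screen coordinates plus ``on_prompt``
    flag).  Fixations whose ``on_prompt`` flag is set bypass the layout model
    and are anchored as prompt fixations with no word index.  Fixations whose
    onset falls outside the session timeline are skipped (counted in the
    ``skipped`` attribute of the returned frame).
    """
    if timeline.states:
        t_lo, t_hi = timeline.states[0].t_ms, timeline.states[-1].t_ms
    else:
        t_lo, t_hi = 0, -1
    rows = []
    skipped = 0
    for fx in fixations.itertuples():
        t = int(fx.t_start_ms)
        if t < t_lo or t > t_hi:
            skipped += 1
            continue
        base = {
            "participant": fx.participant,
            "language": fx.language,
            "t_start_ms": t,
            "duration_ms": int(fx.duration_ms),
            "region": "prompt",
            "char_index": np.nan,
            "word_index": np.nan,
            "sentence_ord": np.nan,
            "paragraph": np.nan,
            "word_dist": np.nan,
            "char_dist": np.nan,
            "sent_dist": np.nan,
            "ahead": False,
        }
        if not bool(fx.on_prompt):
            ci = layout.px_to_char(float(fx.x_px), float(fx.y_px))
            if ci is None:
                pass  # gaze in the prompt band
            else:
                state = timeline.state_at(t)
                base.update(_anchor_one(ci, state))
        rows.append(base)
    out = pd.DataFrame(rows, columns=ANCHORED_COLUMNS)
    out.attrs["skipped"] = skipped
    return out


def require_anchored(fixations: pd.DataFrame) -> None:
    if "region" not in fixations.columns:
        raise AnchorError("fixations must be anchored first (missing 'region' column)")
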