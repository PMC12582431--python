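"""Test utilities: a tiny keypress DSL and independent oracles.

The oracles here re-implement published definitions from scratch with plain
Python loops so that the package's vectorized implementations are checked
against an independent route.
"""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd

from writetrace.events import EditorEvent

# ---------------------------------------------------------------------------
# Keypress DSL: characters insert themselves; tuples are special actions.

BSP = ("bsp",)
LEFT = ("left",)
RIGHT = ("right",)
SHIFT = ("shift",)


def build_events(tokens, dt: int = 200, t0: int = 1000) -> list[EditorEvent]:
    """Build an event stream from a token list, tracking cursor and text."""
    events = []
    text: list[str] = []
    cursor = 0
    t = t0
    for tok in tokens:
        if tok == BSP:
            events.append(EditorEvent(t, "backspace", "", cursor, cursor - 1))
            del text[cursor - 1]
            cursor -= 1
        elif tok == LEFT:
            events.append(EditorEvent(t, "cursor_move", "", cursor, cursor - 1))
            cursor -= 1
        elif tok == RIGHT:
            events.append(EditorEvent(t, "cursor_move", "", cursor, cursor + 1))
            cursor += 1
        elif tok == SHIFT:
            events.append(EditorEvent(t, "shift", "", cursor, cursor))
        elif isinstance(tok, tuple) and tok[0] == "move":
            events.append(EditorEvent(t, "cursor_move", "", cursor, tok[1]))
            cursor = tok[1]
        else:
            events.append(EditorEvent(t, "insert", tok, cursor, cursor + 1))
            text.insert(cursor, tok)
            cursor += 1
        t += dt
    return events


def type_string(s: str):
    return list(s)


# ---------------------------------------------------------------------------
# Brute-force lookback oracle: literal loop-based evaluation of the four
# lookback criteria on an anchored fixation window.


def brute_force_lookback(window: pd.DataFrame, min_word=1.0, min_char=5.0,
                         behind_frac=0.8, prompt_frac=0.5) -> bool:
    rows = [r for _, r in window.sort_values("t_start_ms").iterrows()]
    if len(rows) < 2:
        return False
    text_rows = [r for r in rows if r["region"] == "text"]
    if not text_rows:
        return False
    # (a) median word and character distance behind the point of inscription
    if statistics.median([r["word_dist"] for r in text_rows]) < min_word:
        return False
    if statistics.median([r["char_dist"] for r in text_rows]) < min_char:
        return False
    # (b) share of fixations behind
    n_behind = 0
    for r in rows:
        if r["region"] == "text" and not r["ahead"] and r["word_dist"] >= 1:
            n_behind += 1
    if not n_behind / len(rows) > behind_frac:
        return False
    # (c) does not start on the prompt
    if rows[0]["region"] == "prompt":
        return False
    # (d) fewer than half the fixations on the prompt
    n_prompt = sum(1 for r in rows if r["region"] == "prompt")
    if not n_prompt / len(rows) < prompt_frac:
        return False
    return True


def random_anchored_window(rng: np.random.Generator, t_first=0, t_second=10_000,
                           max_fix=8) -> pd.DataFrame:
    """A random anchored-fixation window exercising all criterion branches."""
    n = int(rng.integers(0, max_fix + 1))
    rows = []
    t = t_first + 1
    for _ in range(n):
        t += int(rng.integers(1, max(2, (t_second - t_first) // (max_fix + 2))))
        kind = rng.choice(["text", "prompt"], p=[0.8, 0.2])
        if kind == "prompt":
            rows.append(
                {"t_start_ms": t, "duration_ms": int(rng.integers(40, 400)),
                 "region": "prompt", "char_index": np.nan, "word_index": np.nan,
                 "sentence_ord": np.nan, "paragraph": np.nan, "word_dist": np.nan,
                 "char_dist": np.nan, "sent_dist": np.nan, "ahead": False}
            )
        else:
            word_dist = int(rng.integers(-2, 6))
            if word_dist > 0:
                char_dist = int(rng.integers(1, 30))
                ahead = False
            elif word_dist == 0:
                char_dist = 0
                ahead = False
            else:
                char_dist = -int(rng.integers(1, 20))
                ahead = True
            rows.append(
                {"t_start_ms": t, "duration_ms": int(rng.integers(40, 400)),
                 "region": "text", "char_index": 100 - char_dist,
                 "word_index": 20 - word_dist, "sentence_ord": 2, "paragraph": 0,
                 "word_dist": word_dist, "char_dist": char_dist,
                 "sent_dist": int(rng.integers(0, 3)), "ahead": ahead}
            )
    from writetrace.replay import ANCHORED_COLUMNS

    df = pd.DataFrame(rows, columns=[c for c in ANCHORED_COLUMNS if c not in ("participant", "language")])
    df.insert(0, "participant", "p00")
    df.insert(1, "language", "L1")
    return df


def metric_window(specs) -> pd.DataFrame:
    """Anchored window from (t, duration, word_dist, sent_dist) tuples."""
    from writetrace.replay import ANCHORED_COLUMNS

    rows = []
    for t, dur, word_dist, sent_dist in specs:
        rows.append(
            {"t_start_ms": t, "duration_ms": dur, "region": "text",
             "char_index": 100 - 5 * word_dist, "word_index": 20 - word_dist,
             "sentence_ord": 3 - sent_dist, "paragraph": 0, "word_dist": word_dist,
             "char_dist": 5 * word_dist, "sent_dist": sent_dist, "ahead": False}
        )
    df = pd.DataFrame(rows, columns=[c for c in ANCHORED_COLUMNS if c not in ("participant", "language")])
    df.insert(0, "participant", "p00")
    df.insert(1, "language", "L1")
    return df


def rle_entry_count(word_sequence) -> int:
    """Independent run-length word-entry count (consecutive repeats collapse)."""
    count = 0
    prev = object()
    for w in word_sequence:
        if w != prev:
            count += 1
        prev = w
    return count
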