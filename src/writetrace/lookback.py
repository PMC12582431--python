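"""Lookback detection within writing transitions, and lookback metrics.

A *lookback* is the writer's gaze leaving the word currently being typed and
returning into the already-written text between two consecutive keypresses.
Operationally, the candidate sequence is the maximal run of fixations whose
onsets fall strictly between the two keyboard events of a writing transition,
and it qualifies as a lookback when all of the following hold:

(a) the fixations lie at a median distance of at least one word *and* at
    least five characters behind the point of inscription (both medians over
    the in-text fixations, distances to the fixated word's nearest edge);
(b) more than 80% of the fixations in the sequence are behind (not ahead of)
    the point of inscription;
(c) the sequence does not start with a fixation on the writing prompt;
(d) fewer than 50% of the fixations are on the prompt.

Prompt fixations count toward the sequence denominators in (b) and (d) but
carry no text distance.  Editing transitions are excluded by the caller:
looking back while editing is trivially expected (the eyes track the cursor
to the error) and carries no planning signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnchorError
from .replay import require_anchored

DEFAULT_THRESHOLDS = {
    "min_word_dist": 1.0,
    "min_char_dist": 5.0,
    "behind_frac": 0.8,
    "prompt_frac": 0.5,
}


@dataclass
class LookbackEvent:
    """A qualifying fixation sequence within one writing transition."""

    transition_id: int
    fixation_rows: list[int]
    n_fixations: int
    duration_ms: float
    words_fixated: int
    sentence_depth: int | None  # None on a modal-sentence tie
    location: str | None = None
    language: str | None = None
    participant: str | None = None


def window_fixations(fixations: pd.DataFrame, t_first: float, t_second: float) -> pd.DataFrame:
    """Fixations whose onset falls strictly inside the transition window."""
    m = (fixations["t_start_ms"] > t_first) & (fixations["t_start_ms"] < t_second)
    return fixations.loc[m].sort_values("t_start_ms", kind="mergesort")


def lookback_duration(window: pd.DataFrame) -> float:
    """Total lookback time: the sum of all member fixation durations."""
    return float(window["duration_ms"].sum())


def words_fixated(window: pd.DataFrame) -> int:
    """Number of word entries during the sequence.

    Consecutive fixations on the same word count once; leaving a word and
    returning to it later counts again.  Prompt fixations are transparent:
    they neither count nor break a run.
    """
    wi = window.loc[window["region"] == "text", "word_index"].to_numpy()
    if len(wi) == 0:
        return 0
    return int(1 + np.sum(wi[1:] != wi[:-1]))


def sentence_depth(window: pd.DataFrame) -> int | None:
    """Distance of the most-fixated sentence from the point of inscription.

    Same sentence = 0, previous sentence = 1, and so on; ``None`` when two or
    more sentences tie for the most fixations (such sequences are excluded
    from the depth analysis).
    """
    dists = window.loc[window["region"] == "text", "sent_dist"].astype(int)
    if dists.empty:
        return None
    counts = dists.value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        return None
    return int(counts.index[0])


def detect_lookback(
    transition: pd.Series,
    fixations: pd.DataFrame,
    thresholds: dict | None = None,
) -> LookbackEvent | None:
    """Apply criteria (a)-(d) to the fixations inside one writing transition.

    ``fixations`` must already be anchored (see
    :func:`writetrace.replay.anchor_fixations`); raises :class:`AnchorError`
    otherwise.  Returns a :class:`LookbackEvent` or ``None``.
    """
    require_anchored(fixations)
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    win = window_fixations(fixations, transition["t_first"], transition["t_second"])
    n = len(win)
    if n < 2:
        return None
    if win["region"].isna().any():
        raise AnchorError("window contains unanchored fixations")
    text = win[win["region"] == "text"]
    if text.empty:
        return None
    # (a) median distances behind the point of inscription
    if float(text["word_dist"].median()) < th["min_word_dist"]:
        return None
    if float(text["char_dist"].median()) < th["min_char_dist"]:
        return None
    # (b) share of fixations behind the point of inscription: in-text, not
    # ahead, and at least one word behind the word being typed
    behind = int(((win["region"] == "text") & (~win["ahead"]) & (win["word_dist"] >= 1)).sum())
    if behind / n <= th["behind_frac"]:
        return None
    # (c) must not start on the prompt
    if win.iloc[0]["region"] == "prompt":
        return None
    # (d) prompt share
    if (win["region"] == "prompt").sum() / n >= th["prompt_frac"]:
        return None
    return LookbackEvent(
        transition_id=int(transition.name) if transition.name is not None else -1,
        fixation_rows=list(win.index),
        n_fixations=n,
        duration_ms=lookback_duration(win),
        words_fixated=words_fixated(win),
        sentence_depth=sentence_depth(win),
        location=transition.get("location"),
        language=transition.get("language"),
        participant=transition.get("participant"),
    )


def detect_lookbacks(
    transitions: pd.DataFrame,
    fixations: pd.DataFrame,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Run the detector over all writing transitions; one row per event."""
    require_anchored(fixations)
    rows = []
    writing = transitions[transitions["mode"] == "writing"]
    for tid, tr in writing.iterrows():
        ev = detect_lookback(tr, fixations, thresholds)
        if ev is not None:
            rows.append(
                {
                    "transition_id": tid,
                    "participant": tr["participant"],
                    "language": tr["language"],
                    "location": tr["location"],
                    "t_first": tr["t_first"],
                    "t_second": tr["t_second"],
                    "n_fixations": ev.n_fixations,
                    "duration_ms": ev.duration_ms,
                    "words_fixated": ev.words_fixated,
                    "sentence_depth": ev.sentence_depth,
                }
            )
    cols = [
        "transition_id",
        "participant",
        "language",
        "location",
        "t_first",
        "t_second",
        "n_fixations",
        "duration_ms",
        "words_fixated",
        "sentence_depth",
    ]
    return pd.DataFrame(rows, columns=cols)
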