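"""Synthetic writing sessions with ground truth for every pipeline stage.

The generator emulates the statistical structure that the analysis assumes:

* inter-keystroke intervals drawn from a two-component lognormal mixture per
  text location (pre-sentence, pre-word, within-word) and language, with a
  shared fluent component and a location/language-specific hesitation
  component;
* editing subsequences (wrong character + backspace, or deletion and
  retyping of a just-typed space) inserted with per-location probability;
* lookback fixation sequences planted behind the point of inscription for a
  per-location fraction of writing transitions, constructed to satisfy the
  detector's criteria (a)-(d); non-lookback transitions receive fixations at
  the point of inscription or short prompt-contaminated sequences that
  violate the criteria;
* per-participant heterogeneity as normal random effects on the log-duration
  and logit-probability scales.

Text content comes from synthetic lexicons: a finite pool of random content
words per language (distinct letter inventories, configurable lengths) mixed
with that language's closed-class function words, so token-based measures
(lexical diversity, open/closed ratio) behave as they would on real text even
though content words carry no semantics.
Configured ms quantities are geometric means (medians) of the lognormal
components.  Defaults mirror the observed structure of adult L1/L2
composition: fluent keystrokes around 153 ms, hesitation components from
~270 ms within words up to ~1.9 s before L2 sentences, editing probabilities
of 5-24% and lookback probabilities from under 1% within words to ~40%
before sentences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError
from .events import EditorEvent, events_to_frame
from .replay import (
    LayoutModel,
    current_sentence_ordinal,
    sentence_ordinal_of_char,
    word_spans,
)

LOCATIONS = ("pre-sentence", "pre-word", "within-word")

_ALPHABETS = {
    "L1": "abcdefghijklmnopqrstuvwy",
    "L2": "abcdefghijlmnopqrstuvázéíñóú",
}


@dataclass(frozen=True)
class CellParams:
    """Generating parameters for one text-location x language cell."""

    fluent_mean_ms: float = 153.0
    fluent_sd: float = 0.25  # sd of log-IKI, fluent component
    hesitation_shift_ms: float = 280.0  # hesitation median = fluent + shift
    hesitation_sd: float = 0.55
    mixing_proportion: float = 0.5  # P(hesitation component)
    edit_prob: float = 0.07
    lookback_prob: float = 0.05
    lookback_dur_mean_ms: float = 1200.0
    words_fixated_mean: float = 4.0
    sentence_depth_mean: float = 0.8


@dataclass(frozen=True)
class ParticipantSD:
    """Between-participant random-effect SDs (log / logit scales)."""

    log_iki: float = 0.12
    logit_theta: float = 0.4
    logit_edit: float = 0.25
    logit_lookback: float = 0.3


@dataclass
class SessionConfig:
    """Full configuration of the synthetic study.

    ``cells`` maps (location, language) to :class:`CellParams`.  The same
    seed always reproduces byte-identical event and fixation streams.
    """

    n_participants: int = 39
    languages: tuple[str, ...] = ("L1", "L2")
    cells: dict = field(default_factory=dict)
    participant_sd: ParticipantSD = field(default_factory=ParticipantSD)
    words_per_sentence: float = 9.0
    sentences_per_text: int = 6
    mean_word_length: float = 5.0
    lexicon_size: int = 150  # distinct content words per language pool
    closed_class_rate: float = 0.35  # share of tokens drawn from function words
    layout: LayoutModel = field(default_factory=LayoutModel)
    cursor_return_prob: float = 0.03
    near_poi_fix_prob: float = 0.35
    prompt_start_prob: float = 0.05
    prompt_mix_prob: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not self.cells:
            self.cells = default_cells()
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for loc in LOCATIONS:
            for lang in self.languages:
                if (loc, lang) not in self.cells:
                    raise ConfigError(f"missing cell parameters for {(loc, lang)}")
                c = self.cells[(loc, lang)]
                for name in ("mixing_proportion", "edit_prob", "lookback_prob"):
                    v = getattr(c, name)
                    if not 0.0 <= v <= 1.0:
                        raise ConfigError(f"cell {(loc, lang)}: {name}={v} outside [0, 1]")
                for name in (
                    "fluent_mean_ms",
                    "hesitation_shift_ms",
                    "lookback_dur_mean_ms",
                    "fluent_sd",
                    "hesitation_sd",
                ):
                    v = getattr(c, name)
                    if not v > 0:
                        raise ConfigError(f"cell {(loc, lang)}: {name}={v} must be > 0")


def default_cells() -> dict:
    """Cell parameters emulating observed L1/L2 composition behaviour."""
    # (location, language): hesitation median, theta, edit prob, lookback
    # prob, lookback duration, words fixated, modal-sentence depth
    table = {
        ("pre-sentence", "L1"): (1366, 0.78, 0.15, 0.342, 1932, 8.67, 1.45),
        ("pre-sentence", "L2"): (1912, 0.94, 0.24, 0.396, 2711, 11.26, 1.68),
        ("pre-word", "L1"): (433, 0.53, 0.07, 0.041, 1153, 4.42, 0.54),
        ("pre-word", "L2"): (703, 0.88, 0.13, 0.108, 1423, 4.59, 0.80),
        ("within-word", "L1"): (271, 0.08, 0.05, 0.003, 795, 2.55, 0.46),
        ("within-word", "L2"): (370, 0.20, 0.07, 0.008, 1004, 2.60, 0.85),
    }
    fluent = 153.0
    cells = {}
    for key, (hes, theta, pe, pl, dur, wf, depth) in table.items():
        cells[key] = CellParams(
            fluent_mean_ms=fluent,
            hesitation_shift_ms=hes - fluent,
            mixing_proportion=theta,
            edit_prob=pe,
            lookback_prob=pl,
            lookback_dur_mean_ms=dur,
            words_fixated_mean=wf,
            sentence_depth_mean=depth,
        )
    return cells


@dataclass
class ParticipantEffects:
    u_log: float
    b_theta: float
    b_edit: float
    b_look: float


def participant_effects(config: SessionConfig, p: int) -> ParticipantEffects:
    """Random effects for one participant, shared across both languages."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(7, p)))
    sd = config.participant_sd
    return ParticipantEffects(
        u_log=rng.normal(0.0, sd.log_iki),
        b_theta=rng.normal(0.0, sd.logit_theta),
        b_edit=rng.normal(0.0, sd.logit_edit),
        b_look=rng.normal(0.0, sd.logit_lookback),
    )


GROUND_TRUTH_COLUMNS = [
    "idx_first",
    "idx_second",
    "t_first",
    "t_second",
    "iki",
    "raw_type",
    "location",
    "mode",
    "component",
    "lookback",
    "lb_duration_ms",
    "lb_words_fixated",
    "lb_sentence_depth",
    "lb_n_fixations",
]


class _SessionBuilder:
    """Stateful assembly of one participant x language session."""

    def __init__(self, config: SessionConfig, p: int, language: str):
        self.cfg = config
        self.language = language
        self.p = p
        self.pid = f"p{p:02d}"
        lang_idx = config.languages.index(language)
        self.rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(p, lang_idx + 1))
        )
        self.eff = participant_effects(config, p)
        self.events: list[EditorEvent] = []
        self.fixations: list[dict] = []
        self.gt: list[dict] = []
        self.text: list[str] = []
        self.t = 0
        self.min_iki = 60  # keep generated writing IKIs above the short-tail filter
        # finite token pools shared by all participants in a language, so
        # generated texts have realistic (finite) lexical diversity
        pool_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(23, lang_idx))
        )
        self.content_pool = tuple(
            self._random_word(pool_rng) for _ in range(config.lexicon_size)
        )
        from ._lexicon import CLOSED_CLASS

        self.closed_pool = tuple(sorted(CLOSED_CLASS.get(language, CLOSED_CLASS["L1"])))

    # -- parameter draws ---------------------------------------------------

    def _cell(self, location: str) -> CellParams:
        return self.cfg.cells[(location, self.language)]

    def _draw_iki(self, location: str) -> tuple[int, str]:
        c = self._cell(location)
        theta = expit(logit(np.clip(c.mixing_proportion, 1e-9, 1 - 1e-9)) + self.eff.b_theta)
        if self.rng.random() < theta:
            median, sd, comp = c.fluent_mean_ms + c.hesitation_shift_ms, c.hesitation_sd, "hesitation"
        else:
            median, sd, comp = c.fluent_mean_ms, c.fluent_sd, "fluent"
        iki = int(round(np.exp(self.rng.normal(np.log(median) + self.eff.u_log, sd))))
        return max(iki, self.min_iki), comp

    def _edit_iki(self) -> int:
        return max(int(round(np.exp(self.rng.normal(np.log(300.0), 0.4)))), self.min_iki)

    def _p(self, base: float, effect: float) -> float:
        if base <= 0.0:
            return 0.0
        if base >= 1.0:
            return 1.0
        return float(expit(logit(base) + effect))

    # -- event emission ----------------------------------------------------

    def _append(self, action: str, t: int, payload: str = "", cb: int | None = None, ca: int | None = None):
        cur = len(self.text)
        if action == "insert":
            cb = len(self.text) if cb is None else cb
            self.text.insert(cb, payload)
            ca = cb + 1
        elif action == "backspace":
            cb = len(self.text) if cb is None else cb
            del self.text[cb - 1]
            ca = cb - 1
        elif action == "cursor_move":
            pass
        else:
            cb = cur if cb is None else cb
            ca = cur if ca is None else ca
        self.events.append(EditorEvent(t, action, payload, int(cb), int(ca)))
        self.t = t

    def _gt_row(self, idx_first, idx_second, raw, location, mode, component=None, lookback=False, lb=None):
        e1, e2 = self.events[idx_first], self.events[idx_second]
        self.gt.append(
            {
                "idx_first": idx_first,
                "idx_second": idx_second,
                "t_first": e1.t_ms,
                "t_second": e2.t_ms,
                "iki": e2.t_ms - e1.t_ms,
                "raw_type": raw,
                "location": location,
                "mode": mode,
                "component": component,
                "lookback": lookback,
                "lb_duration_ms": lb["duration"] if lb else np.nan,
                "lb_words_fixated": lb["words"] if lb else np.nan,
                "lb_sentence_depth": lb["depth"] if lb else np.nan,
                "lb_n_fixations": lb["n_fix"] if lb else np.nan,
            }
        )

    # -- fixation planting -------------------------------------------------

    def _char_px(self, index: int) -> tuple[float, float]:
        return self.cfg.layout.char_to_px(index)

    def _prompt_px(self) -> tuple[float, float]:
        lay = self.cfg.layout
        return (lay.chars_per_line * lay.px_per_char * 0.4, lay.prompt_lines * lay.px_per_line * 0.5)

    def _add_fixation(self, t: int, dur: int, x: float, y: float, on_prompt: bool):
        self.fixations.append(
            {
                "participant": self.pid,
                "language": self.language,
                "t_start_ms": int(t),
                "duration_ms": int(dur),
                "x_px": round(float(x), 1),
                "y_px": round(float(y), 1),
                "on_prompt": bool(on_prompt),
            }
        )

    def _eligible_words(self, poi: int) -> dict[int, list[tuple[int, int, int]]]:
        """Map sentence distance -> [(word_idx, start, end)] of plantable targets."""
        text = "".join(self.text)
        spans = word_spans(text)
        starts = [s for s, _ in spans]
        poi_word = int(np.searchsorted(starts, poi, side="right")) - 1
        cur_ord = current_sentence_ordinal(text, poi)
        out: dict[int, list[tuple[int, int, int]]] = {}
        for wi, (s, e) in enumerate(spans):
            if wi >= poi_word:
                continue
            if poi - (e - 1) < 5:  # nearest edge at least 5 characters behind
                continue
            d = cur_ord - sentence_ordinal_of_char(text, s)
            out.setdefault(d, []).append((wi, s, e))
        return out

    def _plant_lookback(self, t1: int, t2: int, location: str) -> dict | None:
        """Build a criterion-conformant fixation sequence inside (t1, t2)."""
        c = self._cell(location)
        rng = self.rng
        window = t2 - t1
        if window < 220:
            return None
        # point of inscription: the character typed by the transition's
        # first event (the last insert so far)
        poi = None
        for ev in reversed(self.events):
            if ev.action == "insert":
                poi = ev.cursor_before
                break
        if poi is None:
            return None
        by_dist = self._eligible_words(poi)
        if not by_dist:
            return None
        min_d = 1 if location == "pre-sentence" else 0
        avail = sorted(d for d in by_dist if d >= min_d)
        if not avail:
            return None
        want = max(min_d, int(round(rng.normal(c.sentence_depth_mean, 0.6))))
        d = min(avail, key=lambda a: abs(a - want))
        modal = by_dist[d]
        others = [w for dd, ws in by_dist.items() if dd != d and dd >= min_d for w in ws]
        nw = max(1, int(rng.poisson(max(c.words_fixated_mean - 1, 0.0))) + 1)
        # cap entries by what the window can host at >=30 ms per fixation
        nw = min(nw, max(1, int(0.85 * window / 60) - 1))
        seq, entries = self._entry_sequence(rng, modal, others, nw)
        slots: list[tuple[str, tuple | None]] = [("word", w) for w in seq]
        # an occasional mid-sequence prompt fixation; only in sequences long
        # enough that the behind-share criterion (b) still holds (> 80%)
        if len(slots) >= 5 and rng.random() < self.cfg.prompt_mix_prob:
            pos = 1 + int(rng.integers(len(slots) - 1))
            slots.insert(pos, ("prompt", None))
        n_fix = len(slots)
        if (window - (n_fix + 1)) < n_fix * 30:
            return None
        total = np.exp(rng.normal(np.log(c.lookback_dur_mean_ms), 0.3))
        total = float(min(total, 0.85 * window))
        total = max(total, n_fix * 30.0)
        weights = rng.dirichlet(np.full(n_fix, 4.0))
        durs = np.maximum(30.0, weights * (total - 30.0 * n_fix) + 30.0)
        durs = np.floor(durs).astype(int)
        pad = (window - int(durs.sum())) / (n_fix + 1)
        if pad < 1:
            return None
        t = t1
        depth_counts: dict[int, int] = {}
        for (kind, w), dur in zip(slots, durs):
            t = t + int(pad)
            if kind == "prompt":
                x, y = self._prompt_px()
                self._add_fixation(t, dur, x, y, True)
            else:
                wi, s, e = w
                x, y = self._char_px((s + e - 1) // 2)
                self._add_fixation(t, dur, x, y, False)
            t += dur
        return {
            "duration": int(durs.sum()),
            "words": entries,
            "depth": d,
            "n_fix": n_fix,
        }

    @staticmethod
    def _entry_sequence(rng, modal, others, nw):
        """Word-entry sequence for a planted lookback.

        No consecutive duplicate words (so entries equal fixations), and the
        modal sentence receives strictly more fixations than any other, so
        the planted depth is the unique mode.
        """
        if nw == 1 or (len(modal) == 1 and not others):
            w = modal[int(rng.integers(len(modal)))]
            return [w, w], 1  # two consecutive fixations, one word entry
        n_other = 1 if (others and nw >= 3 and rng.random() < 0.5) else 0
        n_modal = nw - n_other
        if len(modal) == 1:
            # single eligible word in the modal sentence: alternate with
            # other-sentence words, keeping the modal count strictly larger
            n_modal = max(2, min(n_modal, 4))
            n_other = n_modal - 1
        order = ["m"] * n_modal
        for k in range(n_other):
            order.insert(1 + 2 * k, "o")
        seq: list[tuple[int, int, int]] = []
        prev = None
        for which in order:
            pool = modal if which == "m" else others
            cand = [w for w in pool if w != prev] or pool
            w = cand[int(rng.integers(len(cand)))]
            seq.append(w)
            prev = w
        entries = 1 + sum(1 for a, b in zip(seq, seq[1:]) if a != b)
        return seq, entries

    def _plant_negative(self, t1: int, t2: int) -> None:
        """Fixations that must not be detected as lookback."""
        rng = self.rng
        window = t2 - t1
        if window < 150:
            return
        poi = None
        for ev in reversed(self.events):
            if ev.action == "insert":
                poi = ev.cursor_before
                break
        if poi is None or poi < 0:
            return
        if rng.random() < self.cfg.prompt_start_prob and window >= 260:
            # starts on the prompt: violates criterion (c)
            x, y = self._prompt_px()
            d1 = int(min(120, window // 3))
            self._add_fixation(t1 + 10, d1, x, y, True)
            by_dist = self._eligible_words(poi)
            allw = [w for ws in by_dist.values() for w in ws]
            if allw:
                wi, s, e = allw[int(rng.integers(len(allw)))]
                x2, y2 = self._char_px((s + e - 1) // 2)
                self._add_fixation(t1 + 20 + d1, d1, x2, y2, False)
            return
        n = 1 + int(rng.integers(2))
        x, y = self._char_px(poi)
        t = t1 + 5
        for _ in range(n):
            dur = int(min(100, max(40, window // (n + 1) - 10)))
            if t + dur >= t2:
                break
            self._add_fixation(t, dur, x, y, False)
            t += dur + 10
        # fixating the word under production: word distance 0, fails (a)

    # -- typing ------------------------------------------------------------

    def _type_keypress(
        self, ch: str, location: str | None, raw: str, use_shift: bool = False
    ) -> None:
        """Append one writing keypress, its transition and any fixations."""
        prev_idx = len(self.events) - 1
        if prev_idx < 0:
            # very first keypress of the session: no transition
            if use_shift:
                self._append("shift", self.t + 100)
                self._append("insert", self.t + self._shift_gap(), ch)
                self._gt_row(0, 1, "other", None, "other")
            else:
                self._append("insert", self.t + 100, ch)
            return
        iki, comp = self._draw_iki(location)
        t1 = self.t
        t2 = t1 + iki
        c = self._cell(location)
        lb = None
        plant = self.rng.random() < self._p(c.lookback_prob, self.eff.b_look)
        cursor_block = (
            location == "pre-sentence"
            and iki >= 400
            and self.rng.random() < self.cfg.cursor_return_prob
        )
        if cursor_block:
            cur = len(self.text)
            away = max(0, cur - int(self.rng.integers(5, 30)))
            ta = t1 + max(1, iki // 3)
            tb = t1 + max(2, (2 * iki) // 3)
            self._append("cursor_move", ta, "", cur, away)
            self._append("cursor_move", tb, "", away, cur)
        if plant:
            lb = self._plant_lookback(t1, t2, location)
        if lb is None and self.rng.random() < self.cfg.near_poi_fix_prob:
            self._plant_negative(t1, t2)
        if use_shift:
            self._append("shift", t2)
            shift_idx = len(self.events) - 1
            self._append("insert", t2 + self._shift_gap(), ch)
            self._gt_row(prev_idx, shift_idx, raw, location, "writing", comp, lb is not None, lb)
        else:
            self._append("insert", t2, ch)
            self._gt_row(prev_idx, len(self.events) - 1, raw, location, "writing", comp, lb is not None, lb)

    def _shift_gap(self) -> int:
        return int(self.rng.integers(60, 140))

    def _plant_edit(self, location: str) -> None:
        """Editing subsequence appropriate to the upcoming location.

        For pre-word / pre-sentence the just-typed space is deleted and
        retyped; within a word a wrong character is typed and backspaced by
        the caller.
        """
        prev_idx = len(self.events) - 1
        t2 = self.t + self._edit_iki()
        raw = "pre-sentence->edit" if location == "pre-sentence" else "pre-word->edit"
        self._append("backspace", t2, "", len(self.text), None)
        self._gt_row(prev_idx, len(self.events) - 1, raw, location, "editing")
        # retype the space: a post-edit resumption pair, excluded downstream
        prev_idx = len(self.events) - 1
        self._append("insert", self.t + self._edit_iki(), " ")
        self._gt_row(prev_idx, len(self.events) - 1, "other", None, "other")

    def _type_word(self, word: str, sentence_initial: bool, first_of_text: bool) -> None:
        location = "pre-sentence" if sentence_initial else "pre-word"
        c = self._cell(location)
        if not first_of_text and self.rng.random() < self._p(c.edit_prob, self.eff.b_edit):
            self._plant_edit(location)
        chars = list(word)
        wc = self._cell("within-word")
        edit_at = None
        if len(chars) > 2 and self.rng.random() < self._p(wc.edit_prob, self.eff.b_edit):
            edit_at = 1 + int(self.rng.integers(len(chars) - 1))
        for i, ch in enumerate(chars):
            if i == 0:
                self._type_keypress(
                    ch.upper() if sentence_initial else ch,
                    None if first_of_text else location,
                    location,
                    use_shift=sentence_initial,
                )
                continue
            if i == edit_at:
                wrong = self._other_letter(ch)
                self._type_keypress(wrong, "within-word", "within-word")
                prev_idx = len(self.events) - 1
                self._append("backspace", self.t + self._edit_iki(), "", len(self.text), None)
                self._gt_row(prev_idx, len(self.events) - 1, "word->edit", "within-word", "editing")
                prev_idx = len(self.events) - 1
                self._append("insert", self.t + self._edit_iki(), ch)
                self._gt_row(prev_idx, len(self.events) - 1, "other", None, "other")
                continue
            self._type_keypress(ch, "within-word", "within-word")

    def _other_letter(self, ch: str) -> str:
        alpha = _ALPHABETS[self.language] if self.language in _ALPHABETS else _ALPHABETS["L1"]
        alt = alpha[int(self.rng.integers(len(alpha)))]
        while alt == ch:
            alt = alpha[int(self.rng.integers(len(alpha)))]
        return alt

    def _random_word(self, rng) -> str:
        alpha = _ALPHABETS[self.language] if self.language in _ALPHABETS else _ALPHABETS["L1"]
        n = max(2, 1 + int(rng.poisson(max(self.cfg.mean_word_length - 1, 1.0))))
        return "".join(alpha[int(i)] for i in rng.integers(len(alpha), size=n))

    def _make_word(self) -> str:
        if self.rng.random() < self.cfg.closed_class_rate:
            return self.closed_pool[int(self.rng.integers(len(self.closed_pool)))]
        return self.content_pool[int(self.rng.integers(len(self.content_pool)))]

    def build(self):
        cfg = self.cfg
        for s in range(cfg.sentences_per_text):
            n_words = max(3, int(self.rng.poisson(cfg.words_per_sentence)))
            for w in range(n_words):
                word = self._make_word()
                self._type_word(word, sentence_initial=(w == 0), first_of_text=(s == 0 and w == 0))
                # terminator and trailing space close the sentence; the space
                # after a mid-sentence word is the merged post-word transition
                if w == n_words - 1:
                    self._type_keypress(".", "within-word", "within-word")
                self._type_keypress(" ", "within-word", "within-word")
        ev_frame = events_to_frame(self.events, self.pid, self.language)
        fx_frame = pd.DataFrame(
            self.fixations,
            columns=["participant", "language", "t_start_ms", "duration_ms", "x_px", "y_px", "on_prompt"],
        ).sort_values("t_start_ms", kind="mergesort").reset_index(drop=True)
        gt_frame = pd.DataFrame(self.gt, columns=GROUND_TRUTH_COLUMNS)
        gt_frame.insert(0, "participant", self.pid)
        gt_frame.insert(1, "language", self.language)
        return ev_frame, fx_frame, gt_frame


def generate_session(config: SessionConfig, participant: int, language: str):
    """One participant x language session.

    Returns ``(events, fixations, ground_truth)`` DataFrames.  The event
    stream replays to a well-formed multi-sentence text; the ground-truth
    frame carries one row per consecutive-event transition exactly as the
    classifier will see them, with component labels and planted lookback
    metrics.
    """
    if language not in config.languages:
        raise ConfigError(f"unknown language {language!r}")
    return _SessionBuilder(config, participant, language).build()


def generate_study(config: SessionConfig):
    """All participants x languages; concatenated frames."""
    evs, fxs, gts = [], [], []
    for p in range(config.n_participants):
        for lang in config.languages:
            e, f, g = generate_session(config, p, lang)
            evs.append(e)
            fxs.append(f)
            gts.append(g)
    return (
        pd.concat(evs, ignore_index=True),
        pd.concat(fxs, ignore_index=True),
        pd.concat(gts, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Direct samplers for model-recovery work (no event stream, just responses)


def simulate_ikis(
    cells: dict,
    n_participants: int,
    n_per_cell: int,
    participant_sd: ParticipantSD | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """IKIs drawn straight from the per-cell two-component mixture.

    ``cells`` maps (location, language) to :class:`CellParams`.  Returns rows
    (participant, language, location, iki, component).
    """
    sd = participant_sd or ParticipantSD()
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sd.log_iki, size=n_participants)
    b = rng.normal(0.0, sd.logit_theta, size=n_participants)
    rows = []
    for (loc, lang), c in sorted(cells.items()):
        for p in range(n_participants):
            theta = expit(logit(np.clip(c.mixing_proportion, 1e-9, 1 - 1e-9)) + b[p])
            z = rng.random(n_per_cell) < theta
            med = np.where(z, c.fluent_mean_ms + c.hesitation_shift_ms, c.fluent_mean_ms)
            sds = np.where(z, c.hesitation_sd, c.fluent_sd)
            iki = np.exp(rng.normal(np.log(med) + u[p], sds))
            rows.append(
                pd.DataFrame(
                    {
                        "participant": f"p{p:02d}",
                        "language": lang,
                        "location": loc,
                        "iki": iki,
                        "component": np.where(z, "hesitation", "fluent"),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_binomial_cells(
    cell_probs: dict,
    trials: dict | int,
    n_participants: int,
    re_sd: float = 0.3,
    slope_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell success counts with participant intercepts and language slopes.

    ``cell_probs`` maps (location, language) to a probability; ``trials``
    is an int or a matching dict of per-cell trial counts.
    """
    rng = np.random.default_rng(seed)
    u0 = rng.normal(0.0, re_sd, n_participants)
    u1 = rng.normal(0.0, slope_sd, n_participants)
    rows = []
    for (loc, lang), prob in sorted(cell_probs.items()):
        n_tr = trials[(loc, lang)] if isinstance(trials, dict) else trials
        code = 0.5 if lang == "L1" else -0.5
        for p in range(n_participants):
            pr = expit(logit(prob) + u0[p] + code * u1[p])
            k = int(rng.binomial(n_tr, pr))
            rows.append((f"p{p:02d}", lang, loc, k, n_tr))
    return pd.DataFrame(rows, columns=["participant", "language", "location", "successes", "trials"])


def simulate_lognormal_cells(
    cell_medians: dict,
    n_per_cell: int,
    n_participants: int,
    sigma: float = 0.5,
    re_sd: float = 0.15,
    slope_sd: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Lognormal responses (e.g., lookback durations) per cell."""
    rng = np.random.default_rng(seed)
    u0 = rng.normal(0.0, re_sd, n_participants)
    u1 = rng.normal(0.0, slope_sd, n_participants)
    rows = []
    for (loc, lang), med in sorted(cell_medians.items()):
        code = 0.5 if lang == "L1" else -0.5
        for p in range(n_participants):
            y = np.exp(rng.normal(np.log(med) + u0[p] + code * u1[p], sigma, n_per_cell))
            rows.append(
                pd.DataFrame(
                    {"participant": f"p{p:02d}", "language": lang, "location": loc, "y": y}
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_negbinomial_cells(
    cell_means: dict,
    n_per_cell: int,
    n_participants: int,
    phi: float = 8.0,
    re_sd: float = 0.15,
    slope_sd: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial counts (e.g., words fixated) per cell."""
    rng = np.random.default_rng(seed)
    u0 = rng.normal(0.0, re_sd, n_participants)
    u1 = rng.normal(0.0, slope_sd, n_participants)
    rows = []
    for (loc, lang), mean in sorted(cell_means.items()):
        code = 0.5 if lang == "L1" else -0.5
        for p in range(n_participants):
            mu = np.exp(np.log(mean) + u0[p] + code * u1[p])
            y = rng.negative_binomial(phi, phi / (phi + mu), n_per_cell)
            rows.append(
                pd.DataFrame(
                    {"participant": f"p{p:02d}", "language": lang, "location": loc, "y": y}
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_measure_pairs(
    effect: float,
    n_participants: int,
    re_sd: float = 0.3,
    seed: int = 0,
    measure: str = "word_count",
) -> pd.DataFrame:
    """Standardized paired measures with a planted language effect.

    The standardized effect is the L1 - L2 difference in SD units of the
    (log-scaled) measure; negative values mean larger in L2.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, re_sd, n_participants)
    resid = np.sqrt(max(1.0 - re_sd**2, 0.05))
    rows = []
    for p in range(n_participants):
        for lang, code in (("L1", 0.5), ("L2", -0.5)):
            y = rng.normal(code * effect + u[p], resid)
            rows.append((f"p{p:02d}", lang, measure, y))
    return pd.DataFrame(rows, columns=["participant", "language", "measure", "value"])
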