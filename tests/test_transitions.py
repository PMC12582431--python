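import numpy as np
import pandas as pd
import pytest

from helpers import BSP, LEFT, RIGHT, SHIFT, build_events, type_string
from writetrace.errors import ConfigError
from writetrace.replay import replay
from writetrace.transitions import (
    classify_transitions,
    filter_ikis,
    production_sequences,
    subsample_cell,
)


def classify(tokens, dt=200):
    events = build_events(tokens, dt=dt)
    return events, classify_transitions(events, replay(events))


class TestTypingActionTaxonomy:
    """The full typing-actions classification on hand-built key sequences."""

    def test_within_and_post_word_merge(self):
        _, tr = classify(type_string("The dog"))
        # h<-e are within-word; e->space is post-word, reported merged
        raw = tr["raw_type"].tolist()
        assert raw == ["within-word", "within-word", "within-word", "pre-word",
                       "within-word", "within-word"]
        assert "post-word" not in set(tr["raw_type"])
        assert (tr["mode"] == "writing").all()

    def test_pre_word_mid_sentence(self):
        _, tr = classify(type_string("The dog"))
        row = tr.iloc[3]
        assert row["raw_type"] == "pre-word"
        assert row["location"] == "pre-word"

    def test_pre_sentence_with_shift_timing(self):
        # ". ", then shift+T: the transition is pre-sentence and its IKI
        # ends at the shift keypress, not at the character
        tokens = type_string("The dog barked. ") + [SHIFT] + type_string("That")
        events, tr = classify(tokens)
        shift_idx = next(i for i, e in enumerate(events) if e.action == "shift")
        row = tr[tr["idx_first"] == shift_idx - 1].iloc[0]
        assert row["raw_type"] == "pre-sentence"
        assert row["idx_second"] == shift_idx
        assert row["t_second"] == events[shift_idx].t_ms
        # the (shift, T) pair itself is absorbed, not a transition
        assert not (tr["idx_first"] == shift_idx).any()

    def test_word_edit(self):
        tokens = type_string("The dog barked. That") + [BSP, BSP] + type_string("en")
        events, tr = classify(tokens)
        t_idx = len(type_string("The dog barked. That")) - 1
        row = tr[tr["idx_first"] == t_idx].iloc[0]
        assert row["raw_type"] == "word->edit"
        assert row["mode"] == "editing"
        assert row["location"] == "within-word"
        # backspace -> letter resumption is unclassifiable, tagged other
        resume = tr[tr["raw_type"] == "other"]
        assert len(resume) >= 1

    def test_pre_word_edit(self):
        tokens = type_string("The dug ") + [LEFT, LEFT, BSP, "o", RIGHT, RIGHT]
        events, tr = classify(tokens)
        space_idx = len("The dug ") - 1
        row = tr[tr["idx_first"] == space_idx].iloc[0]
        assert row["raw_type"] == "pre-word->edit"
        assert row["location"] == "pre-word"
        assert replay(events).final_text == "The dog "

    def test_pre_sentence_edit(self):
        tokens = type_string("The dog barkid. ") + [LEFT, LEFT, LEFT, BSP, "e"]
        events, tr = classify(tokens)
        space_idx = len("The dog barkid. ") - 1
        row = tr[tr["idx_first"] == space_idx].iloc[0]
        assert row["raw_type"] == "pre-sentence->edit"
        assert row["location"] == "pre-sentence"
        assert replay(events).final_text == "The dog barked. "

    def test_cursor_round_trip_is_non_editing(self):
        # cursor away and back with no edit, then a letter: a writing
        # transition at the appropriate location spanning the whole interval
        prefix = type_string("The dog barked. Then it ")
        tokens = prefix + [("move", 4), ("move", len("The dog barked. Then it "))] + ["r"]
        events, tr = classify(tokens)
        first = len(prefix) - 1
        row = tr[tr["idx_first"] == first].iloc[0]
        assert row["raw_type"] == "pre-word"
        assert row["mode"] == "writing"
        assert row["idx_second"] == len(events) - 1
        assert row["iki"] == events[-1].t_ms - events[first].t_ms

    def test_classifier_matches_ground_truth_labels(self, small_study):
        from writetrace.events import frame_to_events

        events_f, _, gt = small_study
        for (pid, lang), grp in events_f.groupby(["participant", "language"]):
            session = frame_to_events(grp.reset_index(drop=True))
            tr = classify_transitions(session, replay(session), pid, lang)
            sub = gt[(gt["participant"] == pid) & (gt["language"] == lang)]
            merged = tr.merge(sub, on="idx_first", suffixes=("_c", "_g"))
            assert len(merged) == len(tr) == len(sub)
            assert (merged["raw_type_c"] == merged["raw_type_g"]).all()
            assert (merged["mode_c"] == merged["mode_g"]).all()
            assert (merged["iki_c"] == merged["iki_g"]).all()


class TestProductionSequences:
    def test_no_edits_is_one_sequence(self):
        events = build_events(type_string("abc def"))
        seq = production_sequences(events)
        assert seq["length"].tolist() == [7]

    def test_edit_after_every_keystroke(self):
        tokens = []
        for ch in "abc":
            tokens += [ch, "x", BSP]
        events = build_events(tokens)
        seq = production_sequences(events)
        # each backspace terminates the run of keystrokes before it
        assert (seq["length"] == 2).all()
        assert len(seq) == 3

    def test_planted_edit_positions(self):
        tokens = type_string("abcd") + [BSP] + type_string("xy") + [BSP] + type_string("z")
        seq = production_sequences(build_events(tokens))
        assert seq["length"].tolist() == [4, 2, 1]
        assert pd.isna(seq["terminating_event"].tolist()[-1])

    def test_lengths_partition_keystrokes(self, small_study):
        from writetrace.events import frame_to_events

        events_f, _, _ = small_study
        grp = events_f[(events_f["participant"] == "p01") & (events_f["language"] == "L2")]
        session = frame_to_events(grp.reset_index(drop=True))
        seq = production_sequences(session)
        n_inserts = sum(1 for e in session if e.action == "insert")
        assert seq["length"].sum() == n_inserts


class TestFilterAndSubsample:
    def _toy(self, ikis, participant="p00"):
        n = len(ikis)
        return pd.DataFrame(
            {
                "participant": participant,
                "language": "L1",
                "idx_first": range(n),
                "idx_second": range(1, n + 1),
                "t_first": np.arange(n) * 1000,
                "t_second": np.arange(n) * 1000 + ikis,
                "iki": ikis,
                "raw_type": "pre-word",
                "location": "pre-word",
                "mode": "writing",
            }
        )

    def test_filter_boundaries(self):
        df = self._toy(np.array([40, 50, 51, 500, 29_999, 30_000, 31_000]))
        kept, report = filter_ikis(df)
        assert kept["iki"].tolist() == [51, 500, 29_999]
        r = report.iloc[0]
        assert r["n_low"] == 2 and r["n_high"] == 2
        assert r["pct_low"] == pytest.approx(100 * 2 / 7)

    def test_subsample_caps_and_is_deterministic(self):
        df = self._toy(np.full(350, 500))
        out1 = subsample_cell(df, cap=200, seed=9)
        out2 = subsample_cell(df.sample(frac=1.0, random_state=4), cap=200, seed=9)
        assert len(out1) == 200
        assert sorted(out1["idx_first"]) == sorted(out2["idx_first"])
        small = self._toy(np.full(150, 500))
        assert len(subsample_cell(small, cap=200, seed=9)) == 150

    def test_subsample_commutes_with_cell_partition(self):
        df = pd.concat(
            [self._toy(np.full(350, 500), "p00"), self._toy(np.full(250, 600), "p01")],
            ignore_index=True,
        )
        whole = subsample_cell(df, cap=200, seed=3)
        parts = pd.concat(
            [
                subsample_cell(df[df["participant"] == p], cap=200, seed=3)
                for p in ("p00", "p01")
            ],
            ignore_index=True,
        )
        key = ["participant", "t_first", "idx_first"]
        pd.testing.assert_frame_equal(
            whole.sort_values(key).reset_index(drop=True),
            parts.sort_values(key).reset_index(drop=True),
        )

    def test_bad_cap_raises(self):
        with pytest.raises(ConfigError):
            subsample_cell(self._toy(np.full(5, 500)), cap=0)
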