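import numpy as np
import pandas as pd
import pytest

from helpers import brute_force_lookback, random_anchored_window, rle_entry_count
from writetrace.errors import AnchorError
from writetrace.lookback import (
    detect_lookback,
    detect_lookbacks,
    lookback_duration,
    sentence_depth,
    window_fixations,
    words_fixated,
)
from writetrace.replay import ANCHORED_COLUMNS


def make_window(rows):
    df = pd.DataFrame(rows, columns=[c for c in ANCHORED_COLUMNS if c not in ("participant", "language")])
    df.insert(0, "participant", "p00")
    df.insert(1, "language", "L1")
    return df


def text_fix(t, dur, word_dist, char_dist, sent_dist=1, ahead=False):
    return {
        "t_start_ms": t, "duration_ms": dur, "region": "text",
        "char_index": 50 - char_dist, "word_index": 10 - word_dist,
        "sentence_ord": 2 - sent_dist, "paragraph": 0,
        "word_dist": word_dist, "char_dist": char_dist,
        "sent_dist": sent_dist, "ahead": ahead,
    }


def prompt_fix(t, dur):
    return {
        "t_start_ms": t, "duration_ms": dur, "region": "prompt",
        "char_index": np.nan, "word_index": np.nan, "sentence_ord": np.nan,
        "paragraph": np.nan, "word_dist": np.nan, "char_dist": np.nan,
        "sent_dist": np.nan, "ahead": False,
    }


TRANSITION = pd.Series(
    {"t_first": 0, "t_second": 10_000, "mode": "writing", "location": "pre-word",
     "participant": "p00", "language": "L1"},
    name=7,
)


class TestCriteria:
    def test_single_fixation_is_not_lookback(self):
        win = make_window([text_fix(100, 300, 3, 12)])
        assert detect_lookback(TRANSITION, win) is None

    def test_five_fixations_behind_qualify(self):
        rows = [text_fix(100 * (i + 1), 200, 3, 12) for i in range(5)]
        ev = detect_lookback(TRANSITION, make_window(rows))
        assert ev is not None
        assert ev.n_fixations == 5
        assert ev.duration_ms == 1000

    def test_half_prompt_fixations_disqualify(self):
        rows = [text_fix(100, 200, 3, 12), prompt_fix(200, 200),
                text_fix(300, 200, 2, 8), prompt_fix(400, 200)]
        assert detect_lookback(TRANSITION, make_window(rows)) is None

    def test_prompt_start_disqualifies(self):
        rows = [prompt_fix(100, 200)] + [text_fix(200 + 100 * i, 200, 3, 12) for i in range(6)]
        assert detect_lookback(TRANSITION, make_window(rows)) is None

    def test_median_word_distance_below_one_disqualifies(self):
        rows = [text_fix(100, 200, 0, 0), text_fix(200, 200, 0, 0), text_fix(300, 200, 3, 12)]
        assert detect_lookback(TRANSITION, make_window(rows)) is None

    def test_median_char_distance_below_five_disqualifies(self):
        rows = [text_fix(100 * (i + 1), 200, 1, 3) for i in range(4)]
        assert detect_lookback(TRANSITION, make_window(rows)) is None

    def test_ahead_fixations_break_behind_share(self):
        rows = [text_fix(100, 200, 5, 20), text_fix(200, 200, 5, 20),
                text_fix(300, 200, -1, -4, ahead=True)]
        # 2/3 behind <= 80%
        assert detect_lookback(TRANSITION, make_window(rows)) is None

    def test_unanchored_window_raises(self):
        fx = pd.DataFrame({"t_start_ms": [100, 200], "duration_ms": [100, 100]})
        with pytest.raises(AnchorError):
            detect_lookback(TRANSITION, fx)

    def test_detector_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(2024)
        agree = 0
        n_windows = 300
        for _ in range(n_windows):
            win = random_anchored_window(rng)
            got = detect_lookback(TRANSITION, win) is not None
            want = brute_force_lookback(win)
            assert got == want
            agree += 1
        assert agree == n_windows


class TestMetrics:
    def test_duration_is_sum_of_fixations(self):
        rows = [text_fix(100, 200, 3, 12), text_fix(300, 300, 2, 8), text_fix(700, 250, 4, 15)]
        assert lookback_duration(make_window(rows)) == 750
        pair = [text_fix(100, 100, 3, 12), text_fix(300, 100, 2, 8)]
        assert lookback_duration(make_window(pair)) == 200

    def test_duration_invariant_under_retiming(self):
        rows = [text_fix(100, 200, 3, 12), text_fix(300, 300, 2, 8)]
        shifted = [text_fix(900, 200, 3, 12), text_fix(5000, 300, 2, 8)]
        assert lookback_duration(make_window(rows)) == lookback_duration(make_window(shifted))

    def test_word_reentry_counts_again(self):
        # w3, w5, w3: leaving and returning makes three entries
        rows = [text_fix(100, 200, 7, 30), text_fix(200, 200, 5, 20), text_fix(300, 200, 7, 30)]
        assert words_fixated(make_window(rows)) == 3
        same = [text_fix(100 * (i + 1), 200, 8, 33) for i in range(3)]
        assert words_fixated(make_window(same)) == 1

    def test_words_fixated_matches_rle_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            dists = rng.integers(1, 6, size=rng.integers(1, 12))
            rows = [text_fix(100 * (i + 1), 150, int(d), int(d) * 5) for i, d in enumerate(dists)]
            win = make_window(rows)
            word_ids = win[win["region"] == "text"]["word_index"].tolist()
            assert words_fixated(win) == rle_entry_count(word_ids)

    def test_modal_sentence_and_ties(self):
        rows = [text_fix(100, 200, 3, 12, sent_dist=1), text_fix(200, 200, 4, 16, sent_dist=1),
                text_fix(300, 200, 3, 12, sent_dist=1), text_fix(400, 200, 8, 33, sent_dist=2)]
        assert sentence_depth(make_window(rows)) == 1
        tie = [text_fix(100, 200, 3, 12, sent_dist=1), text_fix(200, 200, 8, 33, sent_dist=2),
               text_fix(300, 200, 3, 12, sent_dist=1), text_fix(400, 200, 9, 36, sent_dist=2)]
        assert sentence_depth(make_window(tie)) is None


class TestOnGeneratedSessions:
    def test_planted_lookbacks_recovered_exactly(self, small_config, small_study):
        from writetrace.events import frame_to_events
        from writetrace.replay import anchor_fixations, replay
        from writetrace.transitions import classify_transitions

        events_f, fix_f, gt = small_study
        n_planted = n_found = n_fp = 0
        for (pid, lang), grp in events_f.groupby(["participant", "language"]):
            session = frame_to_events(grp.reset_index(drop=True))
            tl = replay(session)
            tr = classify_transitions(session, tl, pid, lang)
            fx = fix_f[(fix_f["participant"] == pid) & (fix_f["language"] == lang)]
            anchored = anchor_fixations(fx, tl, small_config.layout)
            found = detect_lookbacks(tr, anchored)
            sub = gt[(gt["participant"] == pid) & (gt["language"] == lang)]
            planted = sub[sub["lookback"]]
            n_planted += len(planted)
            n_found += planted["t_first"].isin(found["t_first"]).sum()
            n_fp += (~found["t_first"].isin(planted["t_first"])).sum()
            merged = planted.merge(found, on="t_first")
            assert (merged["lb_duration_ms"] == merged["duration_ms"]).all()
            assert (merged["lb_words_fixated"] == merged["words_fixated"]).all()
            assert (
                merged["lb_sentence_depth"].fillna(-1) == merged["sentence_depth"].fillna(-1)
            ).all()
        assert n_planted > 10
        assert n_found == n_planted  # recall 1.0
        assert n_fp == 0  # false-positive rate 0

    def test_presentence_lookbacks_have_depth_at_least_one(self, small_config, small_study):
        from writetrace.events import frame_to_events
        from writetrace.replay import anchor_fixations, replay
        from writetrace.transitions import classify_transitions

        events_f, fix_f, _ = small_study
        depths = []
        for (pid, lang), grp in events_f.groupby(["participant", "language"]):
            session = frame_to_events(grp.reset_index(drop=True))
            tl = replay(session)
            tr = classify_transitions(session, tl, pid, lang)
            fx = fix_f[(fix_f["participant"] == pid) & (fix_f["language"] == lang)]
            found = detect_lookbacks(tr, anchor_fixations(fx, tl, small_config.layout))
            depths += found.loc[found["location"] == "pre-sentence", "sentence_depth"].dropna().tolist()
        assert depths and min(depths) >= 1
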