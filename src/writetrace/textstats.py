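"""Text-characteristic measures for completed texts.

Six measures summarise a final text: word count, mean word length, sentence
count, mean sentence length (in words), the ratio of open-class to
closed-class words, and MTLD lexical diversity.  Tokenization mirrors the
replay module's segmentation (maximal non-whitespace runs), followed by
case-folding and stripping of leading/trailing punctuation, so the same
string segments identically everywhere in the pipeline.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from ._lexicon import CLOSED_CLASS  # noqa: F401  (re-exported for callers)
from .replay import segment, word_spans

_STRIP = string.punctuation + "¿¡“”‘’«»"


@dataclass
class TextMeasures:
    word_count: int
    mean_word_length: float
    sentence_count: int
    mean_sentence_length: float
    open_closed_ratio: float  # NaN (flagged) when no closed-class token occurs
    mtld: float  # NaN (flagged) when undefined
    ratio_defined: bool = True
    mtld_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "word_count": self.word_count,
            "mean_word_length": self.mean_word_length,
            "sentence_count": self.sentence_count,
            "mean_sentence_length": self.mean_sentence_length,
            "open_closed_ratio": self.open_closed_ratio,
            "mtld": self.mtld,
        }


def tokenize(text: str) -> list[str]:
    """Case-folded tokens with surrounding punctuation stripped."""
    toks = []
    for s, e in word_spans(text):
        t = text[s:e].casefold().strip(_STRIP)
        if t:
            toks.append(t)
    return toks


def basic_measures(text: str, closed_class_lexicon: frozenset[str] | set[str]) -> TextMeasures:
    """Word/sentence counts, lengths and the open/closed-class ratio.

    Empty text yields zeros with the ratio flagged undefined.  The ratio is
    |tokens not in lexicon| / |tokens in lexicon|.
    """
    spans, n_sent, _ = segment(text)
    tokens = tokenize(text)
    n_words = len(spans)
    mean_wlen = float(np.mean([e - s for s, e in spans])) if spans else 0.0
    mean_slen = n_words / n_sent if n_sent else 0.0
    closed = sum(1 for t in tokens if t in closed_class_lexicon)
    open_ = len(tokens) - closed
    if closed == 0:
        ratio, defined = float("nan"), False
    else:
        ratio, defined = open_ / closed, True
    return TextMeasures(
        word_count=n_words,
        mean_word_length=mean_wlen,
        sentence_count=n_sent,
        mean_sentence_length=mean_slen,
        open_closed_ratio=ratio,
        mtld=float("nan"),
        ratio_defined=defined,
        mtld_defined=False,
    )


def _mtld_one_direction(tokens: list[str], threshold: float) -> float:
    """Factor count for a single pass of the MTLD algorithm.

    Walk the token sequence keeping a running type-token ratio; each time the
    TTR drops to or below the threshold a factor is complete and the counters
    reset.  The remainder contributes a partial factor
    (1 - TTR_end) / (1 - threshold).
    """
    factors = 0.0
    types: set[str] = set()
    count = 0
    ttr = 1.0
    for tok in tokens:
        count += 1
        types.add(tok)
        ttr = len(types) / count
        if ttr <= threshold:
            factors += 1.0
            types.clear()
            count = 0
            ttr = 1.0
    if count > 0 and ttr < 1.0:
        factors += (1.0 - ttr) / (1.0 - threshold)
    return factors


def mtld(tokens: list[str], ttr_threshold: float = 0.72) -> float:
    """Measure of Textual Lexical Diversity.

    Mean of the forward and reverse passes of N / factors.  Returns NaN when
    both passes complete zero factors (e.g., a short all-unique text, where
    the TTR never falls to the threshold).
    """
    if not tokens:
        raise ValueError("mtld requires at least one token")
    n = len(tokens)
    vals = []
    for seq in (tokens, tokens[::-1]):
        f = _mtld_one_direction(seq, ttr_threshold)
        if f > 0:
            vals.append(n / f)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def text_measures(
    text: str, closed_class_lexicon: frozenset[str] | set[str], ttr_threshold: float = 0.72
) -> TextMeasures:
    """All six measures for one final text."""
    m = basic_measures(text, closed_class_lexicon)
    tokens = tokenize(text)
    if tokens:
        val = mtld(tokens, ttr_threshold)
        m.mtld = val
        m.mtld_defined = not np.isnan(val)
    return m
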