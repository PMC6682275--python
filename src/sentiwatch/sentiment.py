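"""Dictionary-based dual-scale sentiment scoring.

Each text receives two independent integer scores: a positive strength and a
negative strength, both on a 1-5 scale where 1 is neutral.  A text is flagged
positive if its positive score is at least 2, and negative if its negative
score is at least 2; the two flags are independent, so a single text can carry
both positive and negative sentiment.

Scoring is a pure lexicon lookup: the score on each scale is the maximum
strength among the lexicon terms of that polarity present in the text, or 1
when none is present.  No boosters, negators, emoticons or spelling
correction are applied -- the pipeline's claims concern how scores aggregate
over cities and hours, not lexical nuance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: Valid term strengths.  1 is reserved for the neutral default.
STRENGTH_RANGE = (2, 5)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon term with its polarity and strength.

    Parameters
    ----------
    term : lowercase token.
    polarity : ``"positive"`` or ``"negative"``.
    strength : integer in [2, 5]; larger means stronger sentiment.
    """

    term: str
    polarity: str
    strength: int

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if not (STRENGTH_RANGE[0] <= self.strength <= STRENGTH_RANGE[1]):
            raise ValueError(f"strength must be in [2, 5], got {self.strength}")
        if self.term != self.term.lower():
            raise ValueError(f"lexicon terms must be lowercase, got {self.term!r}")


@dataclass(frozen=True)
class SentimentScore:
    """Dual-scale score for one text.

    ``pos`` and ``neg`` are each in [1, 5]; the flags apply the >=2 rule.
    """

    pos: int
    neg: int

    @property
    def is_positive(self) -> bool:
        return self.pos >= 2

    @property
    def is_negative(self) -> bool:
        return self.neg >= 2


class Lexicon:
    """An indexed sentiment lexicon supporting O(1) term lookup."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._pos: dict[str, int] = {}
        self._neg: dict[str, int] = {}
        for e in entries:
            table = self._pos if e.polarity == POSITIVE else self._neg
            if e.term in table:
                raise ValueError(f"duplicate lexicon entry for {e.term!r} ({e.polarity})")
            table[e.term] = e.strength
        if not self._pos and not self._neg:
            raise ValueError("lexicon is empty")

    @property
    def positive_terms(self) -> Mapping[str, int]:
        return self._pos

    @property
    def negative_terms(self) -> Mapping[str, int]:
        return self._neg

    def __len__(self) -> int:
        return len(self._pos) + len(self._neg)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Lexicon":
        """Build from a table with columns ``term, polarity, strength``."""
        entries = [
            LexiconEntry(str(r.term), str(r.polarity), int(r.strength))
            for r in frame.itertuples(index=False)
        ]
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, POSITIVE, s) for t, s in sorted(self._pos.items())]
        rows += [(t, NEGATIVE, s) for t, s in sorted(self._neg.items())]
        return pd.DataFrame(rows, columns=["term", "polarity", "strength"])


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


def score_text(text: str, lexicon: Lexicon) -> SentimentScore:
    """Score one text against the lexicon.

    The positive (negative) score is the maximum strength over positive
    (negative) lexicon terms present in the tokenized text, defaulting to the
    neutral value 1 when no term of that polarity occurs.
    """
    pos, neg = 1, 1
    ptab, ntab = lexicon.positive_terms, lexicon.negative_terms
    for tok in tokenize(text):
        s = ptab.get(tok)
        if s is not None and s > pos:
            pos = s
        s = ntab.get(tok)
        if s is not None and s > neg:
            neg = s
    return SentimentScore(pos=pos, neg=neg)


def classify_batch(tweets: pd.DataFrame, lexicon: Lexicon, text_col: str = "text") -> pd.DataFrame:
    """Score every row of a tweet table.

    Returns the input frame with four added columns: ``pos``, ``neg``,
    ``is_positive`` and ``is_negative``.  Rows with a missing text field are
    dropped with a logged count; order of surviving rows is preserved.
    """
    if tweets.empty:
        out = tweets.copy()
        out["pos"] = pd.Series(dtype=int)
        out["neg"] = pd.Series(dtype=int)
        out["is_positive"] = pd.Series(dtype=bool)
        out["is_negative"] = pd.Series(dtype=bool)
        return out
    if text_col not in tweets.columns:
        raise KeyError(f"tweet table has no {text_col!r} column")
    valid = tweets[text_col].notna()
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("classify_batch: skipped %d records with missing text", n_skipped)
    out = tweets.loc[valid].copy()
    scores = [score_text(t, lexicon) for t in out[text_col]]
    out["pos"] = [s.pos for s in scores]
    out["neg"] = [s.neg for s in scores]
    out["is_positive"] = [s.is_positive for s in scores]
    out["is_negative"] = [s.is_negative for s in scores]
    return out
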