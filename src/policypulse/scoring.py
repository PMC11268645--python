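"""Comment sentiment scoring and the daily attitude series.

A comment's raw score is a sum over its sentiment words::

    E = P * sum_j (-1)^(N_j) * W_j * prod(L over adverbs in scope of j)

where ``W_j`` is the signed lexicon weight of the j-th sentiment word,
``N_j`` the number of negator words in its scope, ``L`` the intensity
multipliers of the degree adverbs in its scope, and ``P`` the terminal
punctuation intensity of the whole comment.  The *scope* of a sentiment word
runs from just after the previous sentiment word (or the comment start) up
to the word itself, so every modifier attaches to exactly one sentiment
word.  Comments are classified positive (E > 0), neutral (E = 0) or
negative (E < 0).

Daily aggregation averages the raw scores of non-neutral comments per day
(neutral comments are treated as objective statements and excluded), imputes
empty days with the pre-normalization series mean, and min–max normalizes
the result into [0, 1].
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import SentimentLexicon

__all__ = [
    "ClassificationReport",
    "CommentScore",
    "DailyAttitudeSeries",
    "EmbeddingTable",
    "TokenizedComment",
    "build_daily_series",
    "evaluate_classifier",
    "read_comments_csv",
    "read_comments_jsonl",
    "score_comment",
    "score_comments",
    "scores_to_frame",
    "semantic_shift_flag",
    "whitespace_tokenize",
    "write_comments_jsonl",
]

POSITIVE = "positive"
NEUTRAL = "neutral"
NEGATIVE = "negative"


def _as_date(value) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class TokenizedComment:
    """One pre-tokenized comment: the unit the scoring rule applies to."""

    comment_id: str
    timestamp: date
    topic_id: str
    tokens: tuple[str, ...]
    terminal_punct: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "timestamp", _as_date(self.timestamp))


@dataclass(frozen=True)
class CommentScore:
    """Raw score E, the derived label, and the comment's timestamp."""

    comment_id: str
    raw_score: float
    label: str
    shift_flagged: bool = False
    timestamp: date | None = None


def whitespace_tokenize(text: str) -> tuple[str, ...]:
    """Default tokenizer: whitespace splitting (segmentation is pluggable)."""
    return tuple(text.split())


def _label_for(score: float) -> str:
    if score > 0:
        return POSITIVE
    if score < 0:
        return NEGATIVE
    return NEUTRAL


def score_comment(
    comment: TokenizedComment,
    lex: SentimentLexicon,
    embeddings: "EmbeddingTable | None" = None,
    invert_on_shift: bool = False,
) -> CommentScore:
    """Score one comment under the lexicon's composition rules.

    Unknown tokens are neutral.  When ``embeddings`` is given, the comment is
    split at its token midpoint into two semantic chunks and
    :func:`semantic_shift_flag` is evaluated; if it fires and
    ``invert_on_shift`` is set, the second chunk's contribution has its sign
    inverted (the shift is always reported via ``shift_flagged``).
    """
    weights = lex.sentiment_weights
    negators = lex.negators
    adverbs = lex.adverb_intensity

    total = 0.0
    second_chunk = 0.0
    split = len(comment.tokens) // 2 if embeddings is not None else None
    n_neg = 0
    adv_prod = 1.0
    for pos, token in enumerate(comment.tokens):
        w = weights.get(token)
        if w is not None:
            term = (-1.0) ** n_neg * w * adv_prod
            total += term
            if split is not None and pos >= split:
                second_chunk += term
            n_neg = 0
            adv_prod = 1.0
        elif token in negators:
            n_neg += 1
        else:
            mult = adverbs.get(token)
            if mult is not None:
                adv_prod *= mult

    flagged = False
    if embeddings is not None and split is not None:
        flagged = semantic_shift_flag(
            comment.tokens[:split], comment.tokens[split:], embeddings, lex
        )
        if flagged and invert_on_shift:
            total -= 2.0 * second_chunk

    total *= lex.punctuation_intensity(comment.terminal_punct)
    return CommentScore(
        comment_id=comment.comment_id,
        raw_score=total,
        label=_label_for(total),
        shift_flagged=flagged,
        timestamp=comment.timestamp,
    )


def score_comments(
    comments: Iterable[TokenizedComment],
    lex: SentimentLexicon,
    embeddings: "EmbeddingTable | None" = None,
    invert_on_shift: bool = False,
) -> list[CommentScore]:
    """Score a stream of comments (see :func:`score_comment`)."""
    return [score_comment(c, lex, embeddings, invert_on_shift) for c in comments]


# -- semantic shift ---------------------------------------------------------

class EmbeddingTable:
    """Word → dense vector map with a fixed dimension (no zero vectors)."""

    def __init__(self, vectors: Mapping[str, Sequence[float]]):
        self._vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        for word, vec in vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"vector for {word!r} is not one-dimensional")
            if dim is None:
                dim = arr.shape[0]
            elif arr.shape[0] != dim:
                raise ValueError(
                    f"vector for {word!r} has dimension {arr.shape[0]}, expected {dim}"
                )
            if not np.any(arr):
                raise ValueError(f"vector for {word!r} is all zeros")
            self._vectors[word] = arr
        self.dim = dim or 0

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def __len__(self) -> int:
        return len(self._vectors)

    def mean_vector(self, words: Iterable[str]) -> np.ndarray | None:
        """Mean embedding of the words present in the table, else None."""
        vecs = [self._vectors[w] for w in words if w in self._vectors]
        if not vecs:
            return None
        return np.mean(vecs, axis=0)

    @classmethod
    def from_word2vec_text(cls, path: str | Path) -> "EmbeddingTable":
        """Read the word2vec *text* format (optional ``count dim`` header)."""
        vectors: dict[str, list[float]] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split(" ")
                if lineno == 1 and len(parts) == 2:
                    continue  # header line
                if len(parts) < 2:
                    continue
                vectors[parts[0]] = [float(x) for x in parts[1:] if x]
        return cls(vectors)


def semantic_shift_flag(
    chunk_a: Sequence[str],
    chunk_b: Sequence[str],
    embeddings: EmbeddingTable,
    lex: SentimentLexicon,
) -> bool:
    """True iff the mean sentiment-word embeddings of the two chunks point in
    opposite hemispheres (cosine similarity < 0, i.e. angle > 90 degrees).

    False when either chunk has no embedded sentiment word, or at the exact
    90-degree boundary (cosine = 0).
    """
    sent = lex.sentiment_weights
    va = embeddings.mean_vector(w for w in chunk_a if w in sent)
    vb = embeddings.mean_vector(w for w in chunk_b if w in sent)
    if va is None or vb is None:
        return False
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return False
    return float(np.dot(va, vb) / (na * nb)) < 0.0


# -- validation harness -----------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """Accuracy and per-class recall of predicted sentiment labels."""

    accuracy: float
    recall: Mapping[str, float]
    n: int

    def min_recall(self) -> float:
        return min(self.recall.values())


def evaluate_classifier(
    predictions: Sequence[str], truth: Sequence[str]
) -> ClassificationReport:
    """Accuracy = matches/total; recall(c) = correctly-predicted-c / true-c."""
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    if not truth:
        raise ValueError("empty label lists")
    matches = sum(p == t for p, t in zip(predictions, truth))
    recall: dict[str, float] = {}
    for cls in sorted(set(truth)):
        idx = [i for i, t in enumerate(truth) if t == cls]
        recall[cls] = sum(predictions[i] == cls for i in idx) / len(idx)
    return ClassificationReport(matches / len(truth), recall, len(truth))


# -- daily attitude series --------------------------------------------------

@dataclass
class DailyAttitudeSeries:
    """Gap-free daily attitude values in [0, 1] with contributing counts.

    ``norm_offset`` / ``norm_scale`` record the affine min–max transform
    applied to the raw daily means (value = (mean − offset)/scale), so raw
    quantities can be mapped onto the normalized scale; ``imputed`` marks
    days that had no non-neutral comments and carry the series mean.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    n_comments: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]
    norm_offset: float = 0.0
    norm_scale: float = 1.0

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.n_comments = np.asarray(self.n_comments, dtype=int)
        if self.imputed is None:
            self.imputed = np.zeros(len(self.values), dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        n = len(self.dates)
        if not (len(self.values) == len(self.n_comments) == len(self.imputed) == n):
            raise ValueError("dates, values, n_comments and imputed must align")
        if n >= 2:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise ValueError("dates must be strictly increasing with daily spacing")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("attitude values must lie in [0, 1]")
        if np.any(self.n_comments < 0):
            raise ValueError("comment counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "value": self.values,
                "n_comments": self.n_comments,
                "imputed": self.imputed,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DailyAttitudeSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(
            dates=pd.DatetimeIndex(df["date"]),
            values=df["value"].to_numpy(float),
            n_comments=df.get("n_comments", pd.Series(np.zeros(len(df)))).to_numpy(int),
            imputed=df.get("imputed", pd.Series(np.zeros(len(df), dtype=bool))).to_numpy(bool),
        )


def build_daily_series(
    scores: Sequence[CommentScore],
    window: tuple[date | str, date | str] | None = None,
) -> DailyAttitudeSeries:
    """Aggregate comment scores into the normalized daily attitude series.

    Per day, the mean raw score of non-neutral comments; days without any
    non-neutral comment receive the pre-normalization series mean (flagged
    in ``imputed``); the series is then min–max normalized into [0, 1]
    (a constant series maps to all 0.5).

    ``window`` is an inclusive (start, end) date pair; by default the span
    of the scored comments.
    """
    nonneutral = [s for s in scores if s.label != NEUTRAL]
    if not nonneutral:
        raise ValueError("empty series: all comments are neutral")
    for s in nonneutral:
        if s.timestamp is None:
            raise ValueError(f"score {s.comment_id!r} has no timestamp")
    stamps = pd.DatetimeIndex([pd.Timestamp(s.timestamp) for s in nonneutral])
    if window is None:
        start, end = stamps.min(), stamps.max()
    else:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    dates = pd.date_range(start, end, freq="D")
    if len(dates) < 2:
        raise ValueError("window must span at least two days")

    df = pd.DataFrame({"date": stamps.normalize(), "score": [s.raw_score for s in nonneutral]})
    df = df[(df["date"] >= start.normalize()) & (df["date"] <= end.normalize())]
    if df.empty:
        raise ValueError("empty series: no non-neutral comments inside the window")
    grouped = df.groupby("date")["score"].agg(["mean", "size"]).reindex(dates)
    observed_days = int(grouped["mean"].notna().sum())
    if observed_days < 2:
        raise ValueError("need non-neutral comments on at least two days")

    n_comments = grouped["size"].fillna(0).to_numpy(int)
    imputed = grouped["mean"].isna().to_numpy()
    means = grouped["mean"].to_numpy(float)
    series_mean = float(np.nanmean(means))
    means = np.where(imputed, series_mean, means)

    lo, hi = float(means.min()), float(means.max())
    if hi > lo:
        values = (means - lo) / (hi - lo)
        offset, scale = lo, hi - lo
    else:
        values = np.full_like(means, 0.5)
        offset, scale = lo - 0.5, 1.0  # degenerate constant series
    return DailyAttitudeSeries(dates, values, n_comments, imputed, offset, scale)


# -- comment I/O ------------------------------------------------------------

def read_comments_jsonl(path: str | Path) -> list[TokenizedComment]:
    """Read comments from JSONL records with keys comment_id, timestamp
    (ISO-8601), topic_id, tokens (array), terminal_punct."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(
                TokenizedComment(
                    comment_id=str(rec["comment_id"]),
                    timestamp=rec["timestamp"],
                    topic_id=str(rec.get("topic_id", "")),
                    tokens=tuple(rec["tokens"]),
                    terminal_punct=rec.get("terminal_punct", ""),
                )
            )
    return out


def write_comments_jsonl(comments: Iterable[TokenizedComment], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(
                json.dumps(
                    {
                        "comment_id": c.comment_id,
                        "timestamp": c.timestamp.isoformat(),
                        "topic_id": c.topic_id,
                        "tokens": list(c.tokens),
                        "terminal_punct": c.terminal_punct,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_comments_csv(
    path: str | Path, token_delimiter: str = " "
) -> list[TokenizedComment]:
    """Read comments from CSV with columns comment_id, timestamp, topic_id,
    text, terminal_punct; ``text`` is split on ``token_delimiter``."""
    out = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(
                TokenizedComment(
                    comment_id=str(rec["comment_id"]),
                    timestamp=rec["timestamp"],
                    topic_id=str(rec.get("topic_id", "")),
                    tokens=tuple(t for t in rec["text"].split(token_delimiter) if t),
                    terminal_punct=rec.get("terminal_punct", "") or "",
                )
            )
    return out


def scores_to_frame(scores: Sequence[CommentScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "comment_id": [s.comment_id for s in scores],
            "timestamp": [s.timestamp for s in scores],
            "raw_score": [s.raw_score for s in scores],
            "label": [s.label for s in scores],
            "shift_flagged": [s.shift_flagged for s in scores],
        }
    )
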