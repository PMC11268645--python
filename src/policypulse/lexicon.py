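"""Composite sentiment lexicon: signed word weights, negators, degree
adverbs and terminal-punctuation intensity rules.

The lexicon is the measurement instrument for comment scoring: each
sentiment word carries a signed weight ``W``; negators flip the sign of the
sentiment word in whose scope they occur; degree adverbs multiply it by a
class intensity (large 2.0, medium 1.5, small 0.5); a terminal run of
repeated punctuation rescales the whole comment (``!``→1.5×n, ``?``→
1.2×(n−1) for runs of ≥2, ``~``→0.8×n).

File formats are plain UTF-8 TSV with ``#`` comment lines; see
:func:`load_lexicon`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ADVERB_CLASSES",
    "DEFAULT_PUNCTUATION_RULES",
    "LexiconError",
    "LexiconParseError",
    "PunctuationRule",
    "SentimentLexicon",
    "load_lexicon",
    "save_lexicon",
]

logger = logging.getLogger(__name__)

#: Degree-adverb class labels and their intensity multipliers.
ADVERB_CLASSES: Mapping[str, float] = {"large": 2.0, "medium": 1.5, "small": 0.5}


class LexiconError(ValueError):
    """Invalid lexicon content (role overlap, zero weight, bad multiplier)."""


class LexiconParseError(LexiconError):
    """Malformed lexicon file; message carries file name and line number."""


@dataclass(frozen=True)
class PunctuationRule:
    """Intensity rule for a terminal run of one repeated punctuation symbol.

    ``kind`` is ``"linear_in_n"`` (intensity = coefficient × n) or
    ``"linear_in_n_minus_1"`` (intensity = coefficient × (n − 1)), where n is
    the run length.  Runs shorter than ``min_run`` are neutral (1.0).
    """

    symbol: str
    coefficient: float
    min_run: int = 1
    kind: str = "linear_in_n"

    def __post_init__(self) -> None:
        if len(self.symbol) != 1:
            raise LexiconError(f"punctuation symbol must be a single character, got {self.symbol!r}")
        if self.coefficient <= 0:
            raise LexiconError(f"punctuation coefficient must be > 0, got {self.coefficient}")
        if self.min_run < 1:
            raise LexiconError(f"min_run must be >= 1, got {self.min_run}")
        if self.kind not in ("linear_in_n", "linear_in_n_minus_1"):
            raise LexiconError(f"unknown punctuation rule kind {self.kind!r}")

    def intensity(self, n: int) -> float:
        """Intensity of a run of length ``n``; 1.0 below ``min_run``."""
        if n < self.min_run:
            return 1.0
        if self.kind == "linear_in_n":
            return self.coefficient * n
        return self.coefficient * (n - 1)


#: Built-in terminal punctuation rules: '!'→1.5×n (n≥1), '?'→1.2×(n−1) (n≥2),
#: '~'→0.8×n (n≥1).
DEFAULT_PUNCTUATION_RULES: tuple[PunctuationRule, ...] = (
    PunctuationRule("!", 1.5, 1, "linear_in_n"),
    PunctuationRule("?", 1.2, 2, "linear_in_n_minus_1"),
    PunctuationRule("~", 0.8, 1, "linear_in_n"),
)


@dataclass(frozen=True)
class SentimentLexicon:
    """Sentiment word weights plus negator / adverb / punctuation rule tables.

    Invariants enforced at construction: all sentiment weights are nonzero;
    adverb multipliers are positive; no word plays more than one role.
    """

    sentiment_weights: Mapping[str, float]
    negators: frozenset[str] = frozenset()
    adverb_intensity: Mapping[str, float] = field(default_factory=dict)
    punctuation_rules: tuple[PunctuationRule, ...] = DEFAULT_PUNCTUATION_RULES

    def __post_init__(self) -> None:
        object.__setattr__(self, "sentiment_weights", dict(self.sentiment_weights))
        object.__setattr__(self, "negators", frozenset(self.negators))
        object.__setattr__(self, "adverb_intensity", dict(self.adverb_intensity))
        object.__setattr__(self, "punctuation_rules", tuple(self.punctuation_rules))
        for word, w in self.sentiment_weights.items():
            if w == 0:
                raise LexiconError(f"sentiment weight for {word!r} is zero")
        for word, m in self.adverb_intensity.items():
            if not m > 0:
                raise LexiconError(f"adverb multiplier for {word!r} must be > 0, got {m}")
        roles = {
            "sentiment": set(self.sentiment_weights),
            "negator": set(self.negators),
            "adverb": set(self.adverb_intensity),
        }
        names = list(roles)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlap = roles[a] & roles[b]
                if overlap:
                    word = sorted(overlap)[0]
                    raise LexiconError(f"word {word!r} appears in both {a} and {b} tables")
        symbols = [r.symbol for r in self.punctuation_rules]
        if len(symbols) != len(set(symbols)):
            raise LexiconError("duplicate punctuation symbol in rules")

    # -- rule lookups -------------------------------------------------------

    def classify_adverb(self, word: str) -> float:
        """Degree-adverb multiplier for ``word``; 1.0 for non-adverbs."""
        return self.adverb_intensity.get(word, 1.0)

    def punctuation_intensity(self, run: str) -> float:
        """Intensity of a terminal punctuation run.

        Neutral (1.0) when the run is empty, mixes symbols, has no matching
        rule, or is shorter than the rule's minimum run length.
        """
        if not run or len(set(run)) != 1:
            return 1.0
        for rule in self.punctuation_rules:
            if rule.symbol == run[0]:
                return rule.intensity(len(run))
        return 1.0


# -- generic rule-module functions (mirror the methods) ---------------------

def classify_adverb(word: str, lex: SentimentLexicon) -> float:
    """Degree-adverb multiplier of ``word`` under ``lex`` (1.0 otherwise)."""
    return lex.classify_adverb(word)


def punctuation_intensity(run: str, lex: SentimentLexicon) -> float:
    """Terminal punctuation intensity of ``run`` under ``lex``."""
    return lex.punctuation_intensity(run)


# -- file I/O ---------------------------------------------------------------

def _read_rows(path: Path, n_min: int, n_max: int) -> Iterable[tuple[int, list[str]]]:
    """Yield (line number, fields) from a TSV file.

    Fields are tab-separated; as a convenience a single trailing
    whitespace-separated field is also accepted (so ``a little bit\t0.5`` and
    ``good 1`` both parse), since adverbs may be multiword phrases.
    """
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            fields = [f.strip() for f in line.split("\t")]
        elif n_max == 1:
            fields = [line]
        else:
            fields = line.rsplit(None, n_max - 1)
        if not n_min <= len(fields) <= n_max:
            raise LexiconParseError(
                f"{path}:{lineno}: expected {n_min}-{n_max} columns, got {len(fields)}"
            )
        yield lineno, fields


def _load_weights(paths: Sequence[Path], sign: int | None = None) -> dict[str, float]:
    weights: dict[str, float] = {}
    for path in paths:
        seen: dict[str, float] = {}
        for lineno, fields in _read_rows(path, 2, 2):
            word, raw = fields
            try:
                w = float(raw)
            except ValueError as exc:
                raise LexiconParseError(f"{path}:{lineno}: non-numeric weight {raw!r}") from exc
            if sign is not None:
                w = sign * abs(w)
            if word in seen:
                logger.warning("%s:%d: duplicate word %r, last entry wins", path, lineno, word)
            seen[word] = w
        for word, w in seen.items():
            if word in weights and (weights[word] > 0) != (w > 0):
                raise LexiconError(
                    f"word {word!r} has conflicting polarity across sentiment files"
                )
            weights[word] = w
    return weights


def load_lexicon(
    sentiment: str | Path | Sequence[str | Path],
    negators: str | Path | None = None,
    adverbs: str | Path | None = None,
    punctuation: str | Path | None = None,
) -> SentimentLexicon:
    """Load a :class:`SentimentLexicon` from TSV files.

    Parameters
    ----------
    sentiment
        One file or a list of files with columns (word, signed weight).
        Within one file a duplicated word keeps its last entry (logged);
        across files a polarity conflict is a :class:`LexiconError`.
    negators
        Optional file, one negator word per line.
    adverbs
        Optional file with columns (word, class-or-multiplier) where class is
        one of ``large`` / ``medium`` / ``small`` or an explicit positive
        number.
    punctuation
        Optional file with columns (symbol, coefficient, min_run, kind);
        when omitted the built-in rules are used.
    """
    if isinstance(sentiment, (str, Path)):
        sentiment = [sentiment]
    weights = _load_weights([Path(p) for p in sentiment])

    neg: set[str] = set()
    if negators is not None:
        for _, (word,) in _read_rows(Path(negators), 1, 1):
            neg.add(word)

    adv: dict[str, float] = {}
    if adverbs is not None:
        path = Path(adverbs)
        for lineno, (word, raw) in _read_rows(path, 2, 2):
            if raw in ADVERB_CLASSES:
                mult = ADVERB_CLASSES[raw]
            else:
                try:
                    mult = float(raw)
                except ValueError as exc:
                    raise LexiconParseError(
                        f"{path}:{lineno}: adverb class {raw!r} is neither "
                        f"large/medium/small nor numeric"
                    ) from exc
            if word in adv:
                logger.warning("%s:%d: duplicate adverb %r, last entry wins", path, lineno, word)
            adv[word] = mult

    rules: tuple[PunctuationRule, ...] = DEFAULT_PUNCTUATION_RULES
    if punctuation is not None:
        path = Path(punctuation)
        parsed = []
        for lineno, fields in _read_rows(path, 4, 4):
            symbol, coef, min_run, kind = fields
            try:
                parsed.append(PunctuationRule(symbol, float(coef), int(min_run), kind))
            except (ValueError, LexiconError) as exc:
                raise LexiconParseError(f"{path}:{lineno}: {exc}") from exc
        rules = tuple(parsed)

    return SentimentLexicon(weights, frozenset(neg), adv, rules)


def save_lexicon(lex: SentimentLexicon, directory: str | Path) -> dict[str, Path]:
    """Write the four TSV files for ``lex`` under ``directory``.

    Returns the mapping of role name to file path, suitable for
    :func:`load_lexicon` (load → save → load round-trips).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sentiment": directory / "sentiment.tsv",
        "negators": directory / "negators.tsv",
        "adverbs": directory / "adverbs.tsv",
        "punctuation": directory / "punctuation.tsv",
    }
    with paths["sentiment"].open("w", encoding="utf-8") as fh:
        for word in sorted(lex.sentiment_weights):
            fh.write(f"{word}\t{lex.sentiment_weights[word]!r}\n")
    with paths["negators"].open("w", encoding="utf-8") as fh:
        for word in sorted(lex.negators):
            fh.write(f"{word}\n")
    with paths["adverbs"].open("w", encoding="utf-8") as fh:
        for word in sorted(lex.adverb_intensity):
            fh.write(f"{word}\t{lex.adverb_intensity[word]!r}\n")
    with paths["punctuation"].open("w", encoding="utf-8") as fh:
        for r in lex.punctuation_rules:
            fh.write(f"{r.symbol}\t{r.coefficient!r}\t{r.min_run}\t{r.kind}\n")
    return paths
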