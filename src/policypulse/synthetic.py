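"""Synthetic inputs with known ground truth for every pipeline stage.

Real comment streams come from web platforms and cannot ship with the
package, so every experiment here runs on generated data: a synthetic
lexicon, comment streams whose compositional structure (negators, degree
adverbs, terminal punctuation) matches what the scoring rule assumes and
whose true labels are known, coder assignments with a controlled agreement
rate, and daily attitude series generated from the segmented-regression
model itself with AR(1) noise and optional Fourier seasonality.

All generators are deterministic under a fixed seed and return their truth
records alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CodedCorpus
from .lexicon import ADVERB_CLASSES, DEFAULT_PUNCTUATION_RULES, SentimentLexicon
from .scoring import DailyAttitudeSeries, TokenizedComment

__all__ = [
    "CommentGenConfig",
    "CommentTruth",
    "ITSGenConfig",
    "ITSTruth",
    "gen_codings",
    "gen_comments",
    "gen_its_series",
    "gen_lexicon",
]


@dataclass(frozen=True)
class CommentGenConfig:
    """Conditions for the synthetic comment stream.

    ``daily_volume`` is either a flat per-day count or a per-topic map
    (volumes are matched exactly).  ``label_noise`` is the probability that
    a comment's tokens contradict its assigned label.  The daily probability
    of a positive label is ``base_positive_prob`` plus
    ``positive_trend_per_day`` times the day index plus the cumulative
    ``polarity_drift`` shifts at or before that day.
    """

    start: date = date(2021, 6, 1)
    end: date = date(2021, 6, 30)
    daily_volume: int | Mapping[str, int] = 100
    n_pos: int = 50
    n_neg: int = 50
    n_neutral: int = 100
    n_negators: int = 5
    n_adverbs: int = 9
    negation_rate: float = 0.3
    adverb_rate: float = 0.3
    punctuation_rate: float = 0.2
    filler_rate: float = 0.3
    label_noise: float = 0.2
    base_positive_prob: float = 0.5
    positive_trend_per_day: float = 0.0
    polarity_drift: Mapping[date, float] = field(default_factory=dict)
    words_per_comment: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "negation_rate",
            "adverb_rate",
            "punctuation_rate",
            "filler_rate",
            "label_noise",
            "base_positive_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if isinstance(self.daily_volume, int):
            if self.daily_volume < 0:
                raise ValueError("daily_volume must be >= 0")
        elif any(v < 0 for v in self.daily_volume.values()):
            raise ValueError("per-topic volumes must be >= 0")
        if self.start > self.end:
            raise ValueError("start must not be after end")
        lo, hi = self.words_per_comment
        if not 1 <= lo <= hi:
            raise ValueError("words_per_comment must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class CommentTruth:
    """Ground truth emitted with a generated comment stream."""

    labels: Mapping[str, str]
    daily_positive_prob: Mapping[date, float]
    expected_level_shift_raw: float | None
    config: CommentGenConfig


def gen_lexicon(cfg: CommentGenConfig) -> SentimentLexicon:
    """Synthetic lexicon: pos####/neg#### words with weights +1/-1, negators,
    and degree adverbs cycling through the three class intensities."""
    if cfg.n_pos < 1 or cfg.n_neg < 1:
        raise ValueError("need at least one positive and one negative word")
    weights: dict[str, float] = {}
    for i in range(cfg.n_pos):
        weights[f"pos{i:04d}"] = 1.0
    for i in range(cfg.n_neg):
        weights[f"neg{i:04d}"] = -1.0
    negators = frozenset(f"not{i:02d}" for i in range(cfg.n_negators))
    classes = list(ADVERB_CLASSES.values())
    adverbs = {f"adv{i:02d}": classes[i % len(classes)] for i in range(cfg.n_adverbs)}
    return SentimentLexicon(weights, negators, adverbs, DEFAULT_PUNCTUATION_RULES)


def _positive_prob_schedule(cfg: CommentGenConfig, dates: Sequence[date]) -> list[float]:
    drift_dates = sorted(cfg.polarity_drift)
    out = []
    for t, day in enumerate(dates):
        p = cfg.base_positive_prob + cfg.positive_trend_per_day * t
        p += sum(cfg.polarity_drift[d] for d in drift_dates if d <= day)
        out.append(min(max(p, 0.01), 0.99))
    return out


def gen_comments(
    cfg: CommentGenConfig, lex: SentimentLexicon
) -> tuple[list[TokenizedComment], CommentTruth]:
    """Generate a labeled comment stream whose scored sign matches the
    assigned label with probability 1 - label_noise.

    Each comment carries 1..k sentiment terms that all share the comment's
    intended sign: a term either uses a word of that sign directly, a word
    of that sign wrapped in a *pair* of negators (sign preserved), or a word
    of the opposite sign behind a *single* negator (sign flipped).  Degree
    adverbs and terminal punctuation only rescale magnitudes, never signs,
    so the construction is exact.  Label noise builds the comment with the
    opposite sign instead.
    """
    rng = np.random.default_rng(cfg.seed)
    days = [cfg.start + timedelta(days=i) for i in range((cfg.end - cfg.start).days + 1)]
    schedule = _positive_prob_schedule(cfg, days)
    if isinstance(cfg.daily_volume, int):
        volumes = {"topic0": cfg.daily_volume}
    else:
        volumes = dict(cfg.daily_volume)

    pos_words = [w for w, v in lex.sentiment_weights.items() if v > 0]
    neg_words = [w for w, v in lex.sentiment_weights.items() if v < 0]
    fillers = [f"neut{i:04d}" for i in range(cfg.n_neutral)]
    negators = sorted(lex.negators)
    adverbs = sorted(lex.adverb_intensity)
    rules = lex.punctuation_rules
    kmin, kmax = cfg.words_per_comment

    comments: list[TokenizedComment] = []
    labels: dict[str, str] = {}
    counter = 0
    for day, p_pos in zip(days, schedule):
        for topic, volume in volumes.items():
            if volume == 0:
                continue
            is_pos = rng.random(volume) < p_pos
            flip = rng.random(volume) < cfg.label_noise
            ks = rng.integers(kmin, kmax + 1, volume)
            neg_draw = rng.random((volume, kmax))
            adv_draw = rng.random((volume, kmax))
            fill_draw = rng.random((volume, kmax))
            word_idx = rng.integers(0, 1 << 30, (volume, kmax))
            adv_idx = rng.integers(0, max(len(adverbs), 1), (volume, kmax))
            fill_idx = rng.integers(0, max(len(fillers), 1), (volume, kmax))
            neg_pair = rng.random((volume, kmax)) < 0.5
            punct_draw = rng.random(volume)
            rule_idx = rng.integers(0, len(rules), volume)
            run_extra = rng.integers(0, 3, volume)
            for i in range(volume):
                label = "positive" if is_pos[i] else "negative"
                sign = 1 if is_pos[i] else -1
                built = -sign if flip[i] else sign
                tokens: list[str] = []
                for j in range(ks[i]):
                    if fillers and fill_draw[i, j] < cfg.filler_rate:
                        tokens.append(fillers[fill_idx[i, j]])
                    use_neg = negators and neg_draw[i, j] < cfg.negation_rate
                    if use_neg and not neg_pair[i, j]:
                        # single negator flips a word of the opposite sign
                        pool = neg_words if built > 0 else pos_words
                        tokens.append(negators[word_idx[i, j] % len(negators)])
                    else:
                        pool = pos_words if built > 0 else neg_words
                        if use_neg:
                            neg_a = negators[word_idx[i, j] % len(negators)]
                            tokens.extend([neg_a, neg_a])
                    if adverbs and adv_draw[i, j] < cfg.adverb_rate:
                        tokens.append(adverbs[adv_idx[i, j]])
                    tokens.append(pool[word_idx[i, j] % len(pool)])
                punct = ""
                if punct_draw[i] < cfg.punctuation_rate:
                    rule = rules[rule_idx[i]]
                    punct = rule.symbol * (rule.min_run + int(run_extra[i]))
                cid = f"c{counter:07d}"
                counter += 1
                comments.append(
                    TokenizedComment(
                        comment_id=cid,
                        timestamp=day,
                        topic_id=topic,
                        tokens=tuple(tokens),
                        terminal_punct=punct,
                    )
                )
                labels[cid] = label

    shift_raw: float | None = None
    if (
        cfg.polarity_drift
        and cfg.words_per_comment == (1, 1)
        and cfg.adverb_rate == 0.0
        and cfg.punctuation_rate == 0.0
        and all(abs(w) == 1.0 for w in lex.sentiment_weights.values())
    ):
        # with unit magnitudes the daily mean raw score is
        # (2p - 1) * (1 - 2*label_noise), so a drift delta in the positive
        # probability shifts it by 2 * delta * (1 - 2*label_noise)
        shift_raw = (
            2.0 * sum(cfg.polarity_drift.values()) * (1.0 - 2.0 * cfg.label_noise)
        )
    truth = CommentTruth(
        labels=labels,
        daily_positive_prob=dict(zip(days, schedule)),
        expected_level_shift_raw=shift_raw,
        config=cfg,
    )
    return comments, truth


@dataclass(frozen=True)
class ITSGenConfig:
    """Generative mirror of the segmented-regression model."""

    beta0: float = 0.5
    beta1: float = 0.001
    beta2: float = 0.15
    beta3: float = -0.005
    sigma: float = 0.05
    phi: float = 0.0
    fourier_amplitudes: tuple[tuple[float, float], ...] = ()
    period: float = 365.25
    n_pre: int = 90
    n_post: int = 90
    start: date = date(2021, 6, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must be in (-1, 1)")
        if self.n_pre < 3 or self.n_post < 3:
            raise ValueError("need at least 3 observations on each side")


@dataclass(frozen=True)
class ITSTruth:
    """Parameters and noise actually used to generate an attitude series."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    sigma: float
    phi: float
    event_date: date
    event_index: int
    noise: np.ndarray
    n_clipped: int


def gen_its_series(cfg: ITSGenConfig) -> tuple[DailyAttitudeSeries, ITSTruth]:
    """Generate y_t = b0 + b1*t + b2*level + b3*trend + seasonality + e_t.

    ``e_t`` is AR(1) with coefficient ``phi`` and innovation sd ``sigma``
    (initialized from the stationary distribution).  Values are clipped into
    [0, 1] only at emission; the clip count is reported in the truth record
    so recovery experiments can check clipping stayed rare.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pre + cfg.n_post
    t = np.arange(n, dtype=float)
    level = (t >= cfg.n_pre).astype(float)
    trend = np.where(level > 0, t - cfg.n_pre, 0.0)
    y = cfg.beta0 + cfg.beta1 * t + cfg.beta2 * level + cfg.beta3 * trend
    for k, (a_k, b_k) in enumerate(cfg.fourier_amplitudes, start=1):
        y = y + a_k * np.sin(2 * np.pi * k * t / cfg.period) + b_k * np.cos(
            2 * np.pi * k * t / cfg.period
        )
    noise = np.zeros(n)
    if cfg.sigma > 0:
        innov = rng.normal(0.0, cfg.sigma, n)
        if cfg.phi != 0.0:
            noise[0] = rng.normal(0.0, cfg.sigma / np.sqrt(1.0 - cfg.phi**2))
            for i in range(1, n):
                noise[i] = cfg.phi * noise[i - 1] + innov[i]
        else:
            noise = innov
    y = y + noise
    clipped = int(np.sum((y < 0) | (y > 1)))
    y = np.clip(y, 0.0, 1.0)
    dates = pd.date_range(cfg.start, periods=n, freq="D")
    series = DailyAttitudeSeries(
        dates=dates,
        values=y,
        n_comments=np.zeros(n, dtype=int),
        imputed=np.zeros(n, dtype=bool),
    )
    truth = ITSTruth(
        beta0=cfg.beta0,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        beta3=cfg.beta3,
        sigma=cfg.sigma,
        phi=cfg.phi,
        event_date=(cfg.start + timedelta(days=cfg.n_pre)),
        event_index=cfg.n_pre,
        noise=noise,
        n_clipped=clipped,
    )
    return series, truth


def gen_codings(
    n_comments: int,
    raters: int = 2,
    agreement: float = 0.9,
    categories: Sequence[str] = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8"),
    seed: int = 0,
    category_prob: float = 0.25,
) -> tuple[CodedCorpus, dict[str, frozenset[str]]]:
    """Reference coding plus per-rater copies matching it with probability
    ``agreement`` independently per comment.

    A disagreeing copy toggles one category, so it never equals the
    reference.  Returns the corpus and the reference coding.
    """
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    if raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(seed)
    cats = list(categories)
    ids = [f"c{i:05d}" for i in range(n_comments)]
    member = rng.random((n_comments, len(cats))) < category_prob
    reference = {
        cid: frozenset(c for c, m in zip(cats, member[i]) if m) for i, cid in enumerate(ids)
    }
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    for r in range(raters):
        match = rng.random(n_comments) < agreement
        toggle = rng.integers(0, len(cats), n_comments)
        coded: dict[str, frozenset[str]] = {}
        for i, cid in enumerate(ids):
            ref = reference[cid]
            if match[i]:
                coded[cid] = ref
            else:
                coded[cid] = ref ^ {cats[toggle[i]]}
        assignments[f"rater{r + 1}"] = coded
    corpus = CodedCorpus(assignments, {c: c for c in cats})
    return corpus, reference
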