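"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (explicit
scope enumeration, normal equations, hand-rolled kernel sums) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from policypulse.lexicon import SentimentLexicon

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_lexicon() -> SentimentLexicon:
    """Hand-built lexicon with one word per role class."""
    return SentimentLexicon(
        sentiment_weights={"good": 1.0, "great": 2.0, "bad": -1.0, "awful": -2.0},
        negators=frozenset({"not", "never"}),
        adverb_intensity={"very": 2.0, "too": 1.5, "slightly": 0.5},
    )


@pytest.fixture
def a_day() -> date:
    return date(2021, 6, 1)


# -- oracle: comment scoring ------------------------------------------------

def brute_force_score(tokens, terminal_punct, lex: SentimentLexicon) -> float:
    """Score a comment by explicitly enumerating sentiment-word scopes.

    Independently re-derives the composition rule: for the j-th sentiment
    word, its scope is the token span after the previous sentiment word;
    the term is (-1)^(#negators in scope) * weight * product of adverb
    multipliers in scope; the sum is scaled by the terminal punctuation
    intensity.
    """
    sentiment_positions = [i for i, t in enumerate(tokens) if t in lex.sentiment_weights]
    total = 0.0
    prev = -1
    for j in sentiment_positions:
        scope = tokens[prev + 1 : j]
        n_neg = sum(1 for t in scope if t in lex.negators)
        adv = 1.0
        for t in scope:
            if t in lex.adverb_intensity:
                adv *= lex.adverb_intensity[t]
        total += ((-1.0) ** n_neg) * lex.sentiment_weights[tokens[j]] * adv
        prev = j
    return total * brute_force_punct(terminal_punct)


def brute_force_punct(run: str) -> float:
    """Built-in punctuation table applied literally."""
    if not run or len(set(run)) != 1:
        return 1.0
    n = len(run)
    sym = run[0]
    if sym == "!":
        return 1.5 * n
    if sym == "?":
        return 1.2 * (n - 1) if n >= 2 else 1.0
    if sym == "~":
        return 0.8 * n
    return 1.0


def random_comment_tokens(rng: np.random.Generator, lex: SentimentLexicon, max_len: int = 12):
    """Random token list mixing all roles plus unknown words."""
    vocab = (
        list(lex.sentiment_weights)
        + list(lex.negators)
        + list(lex.adverb_intensity)
        + ["filler1", "filler2", "xyzzy"]
    )
    length = int(rng.integers(0, max_len + 1))
    tokens = tuple(vocab[i] for i in rng.integers(0, len(vocab), length))
    punct = rng.choice(["", "!", "!!", "?", "??", "???", "~", "~~", "!?", "."])
    return tokens, str(punct)


# -- oracle: least squares --------------------------------------------------

def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve the normal equations (X'X) b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def bartlett_hac_se(X: np.ndarray, u: np.ndarray, lag: int) -> np.ndarray:
    """Hand-rolled Newey-West sandwich with Bartlett weights 1 - l/(lag+1)."""
    n, p = X.shape
    g = X * u[:, None]
    S = g.T @ g
    for ell in range(1, lag + 1):
        w = 1.0 - ell / (lag + 1.0)
        gamma = g[ell:].T @ g[:-ell]
        S += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X)
    return np.sqrt(np.diag(bread @ S @ bread))
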