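"""From a synthetic comment stream to the daily attitude series.

Generates 20 days of labeled comments with a mild upward drift in positive
sentiment, scores them, and aggregates per-day means of the non-neutral
scores into the min-max normalized [0, 1] attitude series.
"""

from datetime import date

from policypulse import (
    CommentGenConfig,
    build_daily_series,
    gen_comments,
    gen_lexicon,
    score_comments,
)

cfg = CommentGenConfig(
    start=date(2021, 6, 1),
    end=date(2021, 6, 20),
    daily_volume=80,
    base_positive_prob=0.45,
    positive_trend_per_day=0.01,
    seed=3,
)
lex = gen_lexicon(cfg)
comments, truth = gen_comments(cfg, lex)
scores = score_comments(comments, lex)
series = build_daily_series(scores)

print(series.to_frame().head(8).to_string(index=False))
print("...")
print(
    f"{len(series)} days; values span [{series.values.min():.2f}, "
    f"{series.values.max():.2f}] by construction of the min-max normalization."
)
print(
    "value is the normalized mean sentiment of that day's non-neutral "
    "comments; n_comments counts them; imputed marks days filled with the "
    "series mean."
)
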