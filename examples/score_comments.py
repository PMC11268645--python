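"""Score a handful of comments with the composition rules.

Builds a four-word lexicon, scores comments that exercise negation, degree
adverbs and terminal punctuation, and prints the raw score and label for
each.  A negator flips the sign of the sentiment word in its scope, an
adverb multiplies it, and a terminal '!' run rescales the whole comment.
"""

from datetime import date

from policypulse import SentimentLexicon, TokenizedComment, score_comment

lex = SentimentLexicon(
    sentiment_weights={"good": 1.0, "bad": -1.0},
    negators=frozenset({"not"}),
    adverb_intensity={"very": 2.0, "slightly": 0.5},
)

examples = [
    (("good",), ""),
    (("very", "good"), ""),
    (("not", "very", "good"), "!"),
    (("bad", "not", "good"), ""),
    (("slightly", "bad"), "~~"),
    (("nothing", "relevant"), ""),
]

for i, (tokens, punct) in enumerate(examples):
    c = TokenizedComment(f"c{i}", date(2021, 6, 1), "demo", tokens, punct)
    s = score_comment(c, lex)
    text = " ".join(tokens) + punct
    print(f"{text:28s} -> score {s.raw_score:+.2f}  ({s.label})")

print()
print("A positive score means a supportive comment, negative an opposed one;")
print("magnitude reflects intensity (adverbs, repeated punctuation).")
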