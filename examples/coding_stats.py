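"""Support statistics for manual content coding.

Simulates two raters who match a reference coding 90% of the time,
reports their percent agreement (expected near 0.9^2 = 0.81 by
independence), tabulates monthly category percentages, and ranks keywords
of a tiny policy-text corpus by TF-IDF.
"""

from datetime import date, timedelta

from policypulse import (
    category_percentages,
    extract_keywords,
    gen_codings,
    interrater_reliability,
)

corpus, reference = gen_codings(2000, raters=2, agreement=0.9, seed=5)
r = interrater_reliability(corpus, "rater1", "rater2")
print(f"pairwise intercoder reliability: {r:.3f}  (expected ~0.81 = 0.9^2;")
print("the 0.9 threshold applies to each rater against the adjudicated reference)")

stamps = {
    cid: date(2021, 6, 1) + timedelta(days=(i * 7) % 60)
    for i, cid in enumerate(corpus.comment_ids)
}
table = category_percentages(reference, stamps)
print("\nmonthly % of comments carrying each category (multi-label):")
print(table.to_string())

docs = [
    "maternity insurance covers three child birth cost".split(),
    "housing subsidy for families with three children".split(),
    "maternity leave extension and employment protection".split(),
]
print("\ntop TF-IDF keywords of the policy corpus:")
for word, score in extract_keywords(docs, top_k=5, stopwords={"for", "with", "and"}):
    print(f"  {word:12s} {score:.3f}")
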