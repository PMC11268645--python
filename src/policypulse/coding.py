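"""Support statistics for manual (grounded-theory style) content coding.

The coding itself is human work done outside the package; this module
computes the quantities that make it auditable: percent intercoder
agreement, TF-IDF keyword rankings of a policy-text corpus, and monthly
multi-label category percentage tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CodedCorpus",
    "category_percentages",
    "extract_keywords",
    "interrater_reliability",
    "read_codings_csv",
    "write_category_table_csv",
]


@dataclass
class CodedCorpus:
    """Multi-label category assignments per rater.

    ``assignments`` maps rater id → {comment_id → frozenset of category
    ids}.  Every rater must code every comment (the empty set counts as a
    coding), and every assigned category must be in the catalogue.
    """

    assignments: Mapping[str, Mapping[str, frozenset[str]]]
    catalogue: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {
            rater: {cid: frozenset(labels) for cid, labels in coded.items()}
            for rater, coded in self.assignments.items()
        }
        if not self.assignments:
            raise ValueError("corpus has no raters")
        comment_sets = [set(coded) for coded in self.assignments.values()]
        base = comment_sets[0]
        for rater, cs in zip(self.assignments, comment_sets):
            if cs != base:
                raise ValueError(f"rater {rater!r} coded a different comment set")
        if self.catalogue:
            known = set(self.catalogue)
            for rater, coded in self.assignments.items():
                for cid, labels in coded.items():
                    unknown = labels - known
                    if unknown:
                        raise ValueError(
                            f"rater {rater!r}, comment {cid!r}: categories "
                            f"{sorted(unknown)} not in catalogue"
                        )

    @property
    def raters(self) -> list[str]:
        return list(self.assignments)

    @property
    def comment_ids(self) -> list[str]:
        return list(next(iter(self.assignments.values())))


def interrater_reliability(
    corpus: CodedCorpus,
    rater_a: str,
    rater_b: str,
    method: str = "exact",
) -> float:
    """Fraction of comments coded identically by the two raters.

    ``method="exact"`` (default) requires exact label-set equality, the
    strictest reading of "same coding result"; ``method="jaccard"`` averages
    the Jaccard overlap of the two label sets per comment (two empty sets
    count as full agreement) for sensitivity analysis.
    """
    try:
        a = corpus.assignments[rater_a]
        b = corpus.assignments[rater_b]
    except KeyError as exc:
        raise KeyError(f"unknown rater {exc.args[0]!r}") from exc
    common = set(a) & set(b)
    if not common:
        raise ValueError("raters share no coded comments")
    if method == "exact":
        return sum(a[cid] == b[cid] for cid in common) / len(common)
    if method == "jaccard":
        total = 0.0
        for cid in common:
            sa, sb = a[cid], b[cid]
            union = sa | sb
            total += 1.0 if not union else len(sa & sb) / len(union)
        return total / len(common)
    raise ValueError(f"unknown method {method!r}")


def all_agree_fraction(corpus: CodedCorpus) -> float:
    """Fraction of comments on which *all* raters agree exactly (>2 raters)."""
    raters = corpus.raters
    ids = corpus.comment_ids
    if not ids:
        raise ValueError("corpus has no comments")
    first = corpus.assignments[raters[0]]
    agree = 0
    for cid in ids:
        ref = first[cid]
        if all(corpus.assignments[r][cid] == ref for r in raters[1:]):
            agree += 1
    return agree / len(ids)


def extract_keywords(
    corpus: Sequence[Sequence[str]],
    top_k: int,
    stopwords: Iterable[str] = (),
) -> list[tuple[str, float]]:
    """Rank corpus words by max-over-documents TF-IDF.

    tf = count / document length, idf = ln(D / df) without smoothing; the
    stop-list is removed before counting.  Ties break lexicographically.
    Returns at most ``top_k`` (word, score) pairs; a ``top_k`` larger than
    the vocabulary returns the full ranking.
    """
    if top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    if len(corpus) < 2:
        raise ValueError("TF-IDF needs at least two documents")
    stop = set(stopwords)
    docs = [[w for w in doc if w not in stop] for doc in corpus]
    n_docs = len(docs)
    df_counts: dict[str, int] = {}
    for doc in docs:
        for w in set(doc):
            df_counts[w] = df_counts.get(w, 0) + 1
    scores: dict[str, float] = {}
    for doc in docs:
        if not doc:
            continue
        length = len(doc)
        counts: dict[str, int] = {}
        for w in doc:
            counts[w] = counts.get(w, 0) + 1
        for w, c in counts.items():
            tfidf = (c / length) * math.log(n_docs / df_counts[w])
            if tfidf > scores.get(w, -1.0):
                scores[w] = tfidf
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def category_percentages(
    consensus: Mapping[str, Iterable[str]],
    timestamps: Mapping[str, date | str],
    categories: Sequence[str] | None = None,
    denominator: str = "all",
) -> pd.DataFrame:
    """Monthly percentage of comments carrying each category.

    ``consensus`` is the post-adjudication coding (comment_id → categories);
    a multi-label comment contributes to every category it carries.  Cells
    are 100 × carriers / comments-in-month, rounded to 2 decimals; months in
    the covered range with zero comments are NaN (missing, not 0).  With
    ``denominator="coded"`` only comments with a nonempty label set count in
    the denominator.
    """
    if denominator not in ("all", "coded"):
        raise ValueError(f"unknown denominator {denominator!r}")
    missing = set(consensus) - set(timestamps)
    if missing:
        raise ValueError(f"no timestamp for comments {sorted(missing)[:3]}")
    labels = {cid: frozenset(v) for cid, v in consensus.items()}
    if categories is None:
        categories = sorted(set().union(*labels.values())) if labels else []
    months = {cid: pd.Period(pd.Timestamp(timestamps[cid]), freq="M") for cid in labels}
    if not months:
        raise ValueError("empty consensus coding")
    all_months = pd.period_range(min(months.values()), max(months.values()), freq="M")

    table = pd.DataFrame(index=list(categories), columns=all_months.astype(str), dtype=float)
    for month in all_months:
        ids = [cid for cid, m in months.items() if m == month]
        if denominator == "coded":
            denom_ids = [cid for cid in ids if labels[cid]]
        else:
            denom_ids = ids
        col = str(month)
        if not denom_ids:
            continue  # month stays NaN: missing, not 0
        for cat in categories:
            carriers = sum(cat in labels[cid] for cid in denom_ids)
            table.loc[cat, col] = round(100.0 * carriers / len(denom_ids), 2)
    table.index.name = "category"
    return table


# -- I/O --------------------------------------------------------------------

def read_codings_csv(
    path: str | Path, catalogue: Mapping[str, str] | None = None
) -> CodedCorpus:
    """Read long-format codings CSV (comment_id, rater_id, category_id).

    An empty ``category_id`` records that the rater saw the comment but
    assigned no category.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    assignments: dict[str, dict[str, set[str]]] = {}
    for _, row in df.iterrows():
        coded = assignments.setdefault(row["rater_id"], {})
        labels = coded.setdefault(row["comment_id"], set())
        if row["category_id"]:
            labels.add(row["category_id"])
    frozen = {
        rater: {cid: frozenset(v) for cid, v in coded.items()}
        for rater, coded in assignments.items()
    }
    return CodedCorpus(frozen, catalogue or {})


def write_category_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)
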