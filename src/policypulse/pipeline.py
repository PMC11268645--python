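"""End-to-end orchestration: comments + lexicon + events in, reports out.

Stages: load lexicon → read comments → preprocess (exact-duplicate removal
and a pluggable "meaningless" filter) → score → daily attitude series →
per-event segmented regressions → optional coding statistics.  Every run
writes a JSON manifest with the seedable configuration hash and per-stage
record counts so runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from . import __version__
from .coding import category_percentages, interrater_reliability, read_codings_csv
from .itsa import read_events_csv, run_policy_panel
from .lexicon import load_lexicon
from .scoring import (
    TokenizedComment,
    build_daily_series,
    read_comments_csv,
    read_comments_jsonl,
    score_comments,
    scores_to_frame,
)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration for :func:`run_full_pipeline`."""

    # inputs
    comments: str = ""
    sentiment_lexicon: list[str] = field(default_factory=list)
    negator_lexicon: str | None = None
    adverb_lexicon: str | None = None
    punctuation_lexicon: str | None = None
    events: str | None = None
    codings: str | None = None
    output_dir: str = "policypulse_out"
    # scoring options
    token_delimiter: str = " "
    invert_on_shift: bool = False
    min_tokens: int = 1
    drop_duplicates: bool = True
    # series options
    window_start: str | None = None
    window_end: str | None = None
    # itsa options
    fourier_k: int = 0
    period: float = 365.25
    dw_lower: float = 1.5
    dw_upper: float = 2.5
    hac_lag: int | None = None
    window_days: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _default_meaningless(comment: TokenizedComment, min_tokens: int) -> bool:
    """Default "meaningless" predicate: empty or below the token threshold."""
    return len(comment.tokens) < min_tokens


def run_full_pipeline(
    config: PipelineConfig,
    meaningless: Callable[[TokenizedComment], bool] | None = None,
) -> dict:
    """Run the full analysis and write CSV reports plus a JSON manifest.

    Returns the manifest dict.  On a stage failure all partial outputs are
    removed and a :class:`PipelineStageError` naming the stage is raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "package": "policypulse",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": {},
        "outputs": {},
        "complete": False,
    }

    def emit(name: str, writer: Callable[[Path], None]) -> None:
        path = outdir / name
        writer(path)
        written.append(path)
        manifest["outputs"][name.split(".")[0]] = str(path)

    try:
        stage = "lexicon"
        if not config.sentiment_lexicon:
            raise PipelineStageError(stage, "no sentiment lexicon files configured")
        lex = load_lexicon(
            sentiment=config.sentiment_lexicon,
            negators=config.negator_lexicon,
            adverbs=config.adverb_lexicon,
            punctuation=config.punctuation_lexicon,
        )
        manifest["counts"]["lexicon_words"] = len(lex.sentiment_weights)

        stage = "read_comments"
        path = Path(config.comments)
        if not path.exists():
            raise PipelineStageError(stage, f"missing comments file {path}")
        if path.suffix.lower() == ".csv":
            comments = read_comments_csv(path, config.token_delimiter)
        else:
            comments = read_comments_jsonl(path)
        manifest["counts"]["comments_in"] = len(comments)

        stage = "preprocess"
        n_in = len(comments)
        if config.drop_duplicates:
            seen: set[tuple] = set()
            unique = []
            # a duplicate is the same text posted on the same day
            for c in comments:
                key = (c.timestamp, c.tokens, c.terminal_punct)
                if key in seen:
                    continue
                seen.add(key)
                unique.append(c)
            comments = unique
        n_dup = n_in - len(comments)
        pred = meaningless or (lambda c: _default_meaningless(c, config.min_tokens))
        kept = [c for c in comments if not pred(c)]
        n_meaningless = len(comments) - len(kept)
        comments = kept
        manifest["counts"]["duplicates_removed"] = n_dup
        manifest["counts"]["duplicate_fraction"] = round(n_dup / n_in, 4) if n_in else 0.0
        manifest["counts"]["meaningless_removed"] = n_meaningless
        manifest["counts"]["comments_kept"] = len(comments)
        if not comments:
            raise PipelineStageError(stage, "no comments left after preprocessing")

        stage = "score"
        scores = score_comments(comments, lex, invert_on_shift=config.invert_on_shift)
        manifest["counts"]["scored"] = len(scores)
        emit("scores.csv", lambda p: scores_to_frame(scores).to_csv(p, index=False))

        stage = "series"
        window = None
        if config.window_start and config.window_end:
            window = (config.window_start, config.window_end)
        series = build_daily_series(scores, window=window)
        manifest["counts"]["series_days"] = len(series)
        manifest["counts"]["imputed_days"] = int(series.imputed.sum())
        emit("series.csv", series.to_csv)

        if config.events:
            stage = "itsa"
            events_path = Path(config.events)
            if not events_path.exists():
                raise PipelineStageError(stage, f"missing events file {events_path}")
            events = read_events_csv(events_path)
            report, _ = run_policy_panel(
                series,
                events,
                window_days=config.window_days,
                fourier_k=config.fourier_k,
                period=config.period,
                dw_lower=config.dw_lower,
                dw_upper=config.dw_upper,
                hac_lag=config.hac_lag,
            )
            manifest["counts"]["events_in"] = len(events)
            manifest["counts"]["events_fit"] = len(report)
            emit("itsa_report.csv", lambda p: report.to_csv(p, index=False))

        if config.codings:
            stage = "coding"
            corpus = read_codings_csv(config.codings)
            raters = corpus.raters
            if len(raters) >= 2:
                manifest["counts"]["interrater_reliability"] = round(
                    interrater_reliability(corpus, raters[0], raters[1]), 4
                )
            consensus = corpus.assignments[raters[0]]
            stamps = {c.comment_id: c.timestamp for c in comments}
            coded_ids = set(consensus) & set(stamps)
            if coded_ids:
                table = category_percentages(
                    {cid: consensus[cid] for cid in coded_ids},
                    {cid: stamps[cid] for cid in coded_ids},
                )
                emit("category_table.csv", lambda p: table.to_csv(p))
                manifest["counts"]["coded_comments"] = len(coded_ids)

        stage = "manifest"
        manifest["complete"] = True
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc
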