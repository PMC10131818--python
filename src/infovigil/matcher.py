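"""Count daily key-phrase mentions and daily total post volume in a stream.

Posts arrive as JSON Lines (Twitter v1-style ``created_at`` + ``text`` /
``full_text``, or an ISO-8601 ``timestamp``).  Text is normalized, matched
against the lexicon with word-boundary substring rules, and binned by UTC
calendar date.  A post counts at most once per phrase no matter how many
times the phrase or its variants occur; variant hits are grouped under the
canonical phrase.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from dateutil import parser as dtparser

from .lexicon import KeyPhraseSet

__all__ = [
    "PostRecord",
    "DailyCounts",
    "normalize_text",
    "PhraseMatcher",
    "match_post",
    "read_jsonl_posts",
    "count_stream",
    "write_counts_csv",
    "read_counts_csv",
]

logger = logging.getLogger(__name__)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_WS_RE = re.compile(r"\s+")
_TWITTER_FMT = "%a %b %d %H:%M:%S %z %Y"


@dataclass(frozen=True)
class PostRecord:
    """One post: opaque id, UTC timestamp (None if unparseable), free text."""

    post_id: str
    timestamp: datetime | None
    text: str


def normalize_text(raw: str) -> str:
    """Lowercase, NFC, URLs replaced by a space, whitespace collapsed."""
    text = unicodedata.normalize("NFC", raw).lower()
    text = _URL_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


class PhraseMatcher:
    """Compiled word-boundary matcher over a key-phrase set.

    A phrase (canonical or variant) matches when it occurs as a contiguous
    substring delimited by the string edges or non-alphanumeric characters,
    so the single-token variant ``chlorinedioxide`` matches inside a
    sentence while ``supersilver`` alone never fires the longer phrase
    ``supersilver whitening toothpaste``, and ``supersilverware`` fires
    nothing.
    """

    def __init__(self, keyphrases: KeyPhraseSet):
        self.keyphrases = keyphrases
        self._patterns: list[tuple[str, re.Pattern[str]]] = []
        for kp in keyphrases:
            alts = sorted(set(kp.all_forms), key=len, reverse=True)
            body = "|".join(re.escape(form) for form in alts)
            pat = re.compile(rf"(?<![a-z0-9])(?:{body})(?![a-z0-9])")
            self._patterns.append((kp.canonical_phrase, pat))

    def match(self, normalized_text: str) -> set[str]:
        """Canonical phrase ids mentioned in already-normalized text."""
        return {
            phrase
            for phrase, pat in self._patterns
            if pat.search(normalized_text) is not None
        }


def match_post(text: str, keyphrases: KeyPhraseSet) -> set[str]:
    """One-shot convenience wrapper around :class:`PhraseMatcher`."""
    return PhraseMatcher(keyphrases).match(text)


@dataclass
class DailyCounts:
    """Per-phrase daily mention counts plus daily total post volume.

    ``counts`` is indexed by a contiguous daily DatetimeIndex with one
    integer column per canonical phrase; ``totals`` shares that index.
    ``c_t <= X_t`` holds for every phrase and day.
    """

    counts: pd.DataFrame
    totals: pd.Series
    skipped_records: int = 0
    burst_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.totals.index):
            raise ValueError("counts and totals must share one date axis")
        idx = self.counts.index
        if len(idx) and not (idx.to_series().diff().dropna() == pd.Timedelta(days=1)).all():
            raise ValueError("date axis must be contiguous daily")
        if (self.counts.to_numpy() > self.totals.to_numpy()[:, None]).any():
            raise ValueError("phrase count exceeds daily total")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.counts.index

    @property
    def phrases(self) -> list[str]:
        return list(self.counts.columns)

    def total_mentions(self) -> pd.Series:
        """Whole-period mention totals per phrase (variants already grouped)."""
        return self.counts.sum(axis=0)


def _parse_timestamp(raw: str) -> datetime:
    try:
        ts = datetime.strptime(raw, _TWITTER_FMT)
    except ValueError:
        ts = dtparser.isoparse(raw)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def read_jsonl_posts(source: str | Path | IO[str]) -> Iterator[PostRecord]:
    """Yield PostRecords from a JSON Lines file or open text handle.

    Timestamp comes from ``created_at`` (Twitter v1 format) or ``timestamp``
    (ISO-8601); text from ``full_text`` falling back to ``text``.  A record
    whose timestamp cannot be parsed is yielded with ``timestamp=None`` so
    that count_stream can skip and tally it.
    """
    if hasattr(source, "read"):
        yield from _iter_handle(source)  # type: ignore[arg-type]
    else:
        with Path(source).open(encoding="utf-8") as fh:
            yield from _iter_handle(fh)


def _iter_handle(fh: Iterable[str]) -> Iterator[PostRecord]:
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        raw_ts = obj.get("created_at") or obj.get("timestamp")
        text = obj.get("full_text")
        if text is None:
            text = obj.get("text", "")
        post_id = str(obj.get("id", obj.get("post_id", lineno)))
        try:
            ts = _parse_timestamp(str(raw_ts))
        except (ValueError, TypeError, OverflowError):
            ts = None  # type: ignore[assignment]
        yield PostRecord(post_id=post_id, timestamp=ts, text=text)


def count_stream(
    posts: Iterable[PostRecord],
    keyphrases: KeyPhraseSet,
    date_range: tuple[date, date],
) -> DailyCounts:
    """Single-pass daily counting of a (possibly unordered) post stream.

    X_t counts *every* in-range post with a parseable timestamp, matched or
    not; c_t counts posts mentioning the phrase or any variant.  Days with no
    posts appear with X_t = 0.  Records with unparseable timestamps are
    skipped and tallied.
    """
    start, end = date_range
    if end < start:
        raise ValueError("date_range end precedes start")
    idx = pd.date_range(start, end, freq="D")
    day_pos = {d.date(): i for i, d in enumerate(idx)}
    phrases = list(keyphrases.phrases)
    col_pos = {p: j for j, p in enumerate(phrases)}
    counts = np.zeros((len(idx), len(phrases)), dtype=np.int64)
    totals = np.zeros(len(idx), dtype=np.int64)
    matcher = PhraseMatcher(keyphrases)
    skipped = 0
    for post in posts:
        if post.timestamp is None:
            skipped += 1
            continue
        pos = day_pos.get(post.timestamp.astimezone(timezone.utc).date())
        if pos is None:
            continue
        totals[pos] += 1
        for phrase in matcher.match(normalize_text(post.text)):
            counts[pos, col_pos[phrase]] += 1
    if skipped:
        logger.warning("count_stream skipped %d records with bad timestamps", skipped)
    return DailyCounts(
        counts=pd.DataFrame(counts, index=idx, columns=phrases),
        totals=pd.Series(totals, index=idx, name="daily_total"),
        skipped_records=skipped,
    )


def write_counts_csv(counts: DailyCounts, path: str | Path) -> None:
    """Write the ``date,phrase,count,daily_total`` long-format dialect."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "phrase", "count", "daily_total"])
        for day, total in counts.totals.items():
            d = day.date().isoformat()
            for phrase in counts.phrases:
                writer.writerow([d, phrase, int(counts.counts.at[day, phrase]), int(total)])


def read_counts_csv(path: str | Path) -> DailyCounts:
    """Read the counts CSV dialect back into a DailyCounts."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "phrase", "count", "daily_total"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    wide = df.pivot_table(index="date", columns="phrase", values="count", fill_value=0)
    totals = df.groupby("date")["daily_total"].first()
    idx = pd.date_range(wide.index.min(), wide.index.max(), freq="D")
    wide = wide.reindex(idx, fill_value=0).astype(np.int64)
    totals = totals.reindex(idx, fill_value=0).astype(np.int64)
    totals.name = "daily_total"
    wide.columns.name = None
    return DailyCounts(counts=wide, totals=totals)
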