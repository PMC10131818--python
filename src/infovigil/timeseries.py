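"""Relative-frequency series and the inclusion filters.

Daily phrase counts are normalized by the total number of posts collected
the same day and expressed as mentions per 1000 posts — the scale the
anomaly detector operates on.  Phrases mentioned fewer than 10 times over
the whole window (variants included) are excluded from analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matcher import DailyCounts

__all__ = [
    "RateSeries",
    "relative_frequency",
    "apply_min_mentions_filter",
    "read_rates_csv",
    "write_rates_csv",
]

PER_1000 = 1000.0


@dataclass(frozen=True)
class RateSeries:
    """Daily relative frequency x_i (mentions per 1000 posts) for one phrase.

    ``gap_mask`` marks days with zero total volume (collection downtime),
    where x is reported as 0 rather than missing so the detector keeps a
    dense calendar axis.
    """

    phrase: str
    dates: pd.DatetimeIndex
    x: np.ndarray
    gap_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.dates) == len(self.x) == len(self.gap_mask)):
            raise ValueError("dates, x and gap_mask must have equal length")
        if (self.x < 0).any():
            raise ValueError("relative frequencies must be non-negative")

    def __len__(self) -> int:
        return len(self.x)


def relative_frequency(counts: DailyCounts, phrase: str) -> RateSeries:
    """x_i = 1000 * c_i / X_i; zero-volume days give x_i = 0 with a gap flag."""
    if phrase not in counts.counts.columns:
        raise KeyError(f"phrase {phrase!r} not present in counts")
    c = counts.counts[phrase].to_numpy(dtype=float)
    total = counts.totals.to_numpy(dtype=float)
    gap = total == 0
    x = np.zeros_like(c)
    np.divide(PER_1000 * c, total, out=x, where=~gap)
    return RateSeries(phrase=phrase, dates=counts.dates, x=x, gap_mask=gap)


def apply_min_mentions_filter(
    total_mentions: Mapping[str, int] | pd.Series,
    threshold: int = 10,
) -> tuple[list[str], list[tuple[str, int]]]:
    """Split phrases into retained (total >= threshold) and excluded lists.

    Totals are whole-period sums including variant mentions.  The boundary
    follows the strict rule "fewer than ``threshold`` mentions excluded":
    a phrase with exactly ``threshold`` mentions is retained.  The excluded
    list carries the observed totals for reporting.
    """
    items = (
        total_mentions.items()
        if isinstance(total_mentions, Mapping)
        else total_mentions.to_dict().items()
    )
    retained: list[str] = []
    excluded: list[tuple[str, int]] = []
    for phrase, total in items:
        if total >= threshold:
            retained.append(phrase)
        else:
            excluded.append((phrase, int(total)))
    return retained, excluded


def write_rates_csv(series: list[RateSeries], path: str | Path) -> None:
    """Write precomputed rates in the ``date,phrase,rel_freq`` dialect."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "phrase", "rel_freq"])
        for rs in series:
            for day, val in zip(rs.dates, rs.x):
                writer.writerow([day.date().isoformat(), rs.phrase, repr(float(val))])


def read_rates_csv(path: str | Path, value_column: str | None = None) -> list[RateSeries]:
    """Ingest a precomputed daily table, bypassing raw posts.

    Accepts either relative frequencies (``rel_freq`` column) or raw counts
    plus totals (``count`` + ``daily_total`` columns, converted to per-1000
    rates here); ``value_column`` forces the choice when both exist.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    if value_column is None:
        value_column = "rel_freq" if "rel_freq" in df.columns else "count"
    if value_column == "count":
        if "daily_total" not in df.columns:
            raise ValueError("count ingestion requires a daily_total column")
        totals = df["daily_total"].to_numpy(dtype=float)
        df = df.assign(
            rel_freq=np.divide(
                PER_1000 * df["count"].to_numpy(dtype=float),
                totals,
                out=np.zeros(len(df)),
                where=totals > 0,
            )
        )
    elif value_column != "rel_freq":
        raise ValueError(f"unknown value column {value_column!r}")
    out: list[RateSeries] = []
    for phrase, grp in df.groupby("phrase", sort=True):
        grp = grp.sort_values("date")
        idx = pd.date_range(grp["date"].min(), grp["date"].max(), freq="D")
        vals = grp.set_index("date")["rel_freq"].reindex(idx, fill_value=0.0)
        gap = np.zeros(len(idx), dtype=bool)
        if "daily_total" in grp.columns:
            tot = grp.set_index("date")["daily_total"].reindex(idx, fill_value=0)
            gap = tot.to_numpy(dtype=float) == 0
        out.append(
            RateSeries(
                phrase=str(phrase), dates=idx, x=vals.to_numpy(dtype=float), gap_mask=gap
            )
        )
    return out
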