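"""Score first-signal dates against regulator warning-letter dates.

A phrase is an *early* detection when its first anomaly signal strictly
precedes the first FDA letter date for the product; *within_week* when the
signal falls on the letter date through seven days after it (both ends
inclusive); *late* beyond that; *none* when the detector never fired.
Aggregate accuracy is #early / #total.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

from .lexicon import KeyPhraseSet

__all__ = [
    "CATEGORIES",
    "SignalEvaluation",
    "EvaluationReport",
    "classify_signal",
    "evaluate_all",
    "write_report_csv",
]

CATEGORIES = ("early", "within_week", "late", "none")


@dataclass(frozen=True)
class SignalEvaluation:
    phrase: str
    letter_date: date
    first_signal_date: date | None
    category: str
    # letter_date - first_signal_date; positive = signal preceded the letter
    lead_days: int | None


@dataclass(frozen=True)
class EvaluationReport:
    evaluations: tuple[SignalEvaluation, ...]
    counts: dict[str, int]
    accuracy: float

    @property
    def n_total(self) -> int:
        return len(self.evaluations)


def classify_signal(
    first_signal: date | None,
    letter: date,
    within_week_days: int = 7,
) -> str:
    """Categorize one first-signal date relative to the letter date.

    The within-week band is [letter, letter + within_week_days], inclusive
    at both ends; the width is configurable but defaults to 7 days.
    """
    if first_signal is None:
        return "none"
    if first_signal < letter:
        return "early"
    if first_signal <= letter + timedelta(days=within_week_days):
        return "within_week"
    return "late"


def evaluate_all(
    signals: Mapping[str, date | None],
    keyphrases: KeyPhraseSet,
    within_week_days: int = 7,
) -> EvaluationReport:
    """Classify every phrase and compute aggregate early-detection accuracy.

    ``signals`` maps canonical phrase -> first-signal date (None = never
    fired).  Each phrase is scored against its deduplicated *first* letter
    date — the conservative convention when a product appears in several
    letters.
    """
    if not signals:
        raise ValueError("no phrases to evaluate; accuracy is undefined")
    evals = []
    for phrase in signals:
        if phrase not in keyphrases:
            raise KeyError(f"phrase {phrase!r} has no letter date in the lexicon")
    for phrase, first_signal in signals.items():
        letter = keyphrases[phrase].first_letter_date
        category = classify_signal(first_signal, letter, within_week_days)
        lead = (letter - first_signal).days if first_signal is not None else None
        evals.append(
            SignalEvaluation(
                phrase=phrase,
                letter_date=letter,
                first_signal_date=first_signal,
                category=category,
                lead_days=lead,
            )
        )
    counts = {cat: 0 for cat in CATEGORIES}
    for ev in evals:
        counts[ev.category] += 1
    return EvaluationReport(
        evaluations=tuple(evals),
        counts=counts,
        accuracy=counts["early"] / len(evals),
    )


def write_report_csv(report: EvaluationReport, path: str | Path) -> None:
    """Per-phrase rows plus a one-line aggregate summary footer file pair."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["phrase", "letter_date", "first_signal_date", "category", "lead_days"]
        )
        for ev in report.evaluations:
            writer.writerow(
                [
                    ev.phrase,
                    ev.letter_date.isoformat(),
                    ev.first_signal_date.isoformat() if ev.first_signal_date else "",
                    ev.category,
                    ev.lead_days if ev.lead_days is not None else "",
                ]
            )
    summary = path.with_name(path.stem + "_summary" + path.suffix)
    with summary.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["n_total", "n_early", "n_within_week", "n_late", "n_none", "accuracy_pct"]
        )
        writer.writerow(
            [
                report.n_total,
                report.counts["early"],
                report.counts["within_week"],
                report.counts["late"],
                report.counts["none"],
                f"{100 * report.accuracy:.1f}",
            ]
        )
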