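"""Curated key-phrase lexicon: loading, validation, deduplication, filtering.

The matching vocabulary is a set of canonical product/entity phrases, each
carrying the date of the first regulator warning letter that mentioned it and
an optional list of lexical variants (misspellings and alternative spellings)
whose mentions are grouped with the canonical phrase.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field, replace
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "PRODUCT_TYPES",
    "KeyPhrase",
    "KeyPhraseSet",
    "LexiconError",
    "normalize_phrase",
    "load_lexicon",
    "write_lexicon",
    "dedupe_first_occurrence",
    "filter_by_date_window",
    "naive_variant_expansion",
    "packaged_lexicon",
]

PRODUCT_TYPES = frozenset({"treatment", "test_kit", "entity"})


class LexiconError(ValueError):
    """Raised for malformed or internally inconsistent lexicon data."""


def normalize_phrase(raw: str) -> str:
    """Canonical phrase form: NFC, lowercase, whitespace collapsed to one space.

    Must match the matcher's text normalization so that lexicon entries and
    post text live in the same space.
    """
    text = unicodedata.normalize("NFC", raw).lower()
    return " ".join(text.split())


@dataclass(frozen=True)
class KeyPhrase:
    """A canonical phrase with its variants, type and first letter date."""

    canonical_phrase: str
    product_type: str
    first_letter_date: date
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.canonical_phrase:
            raise LexiconError("canonical_phrase must be non-empty")
        if self.product_type not in PRODUCT_TYPES:
            raise LexiconError(
                f"unknown product type {self.product_type!r} for "
                f"{self.canonical_phrase!r}; expected one of {sorted(PRODUCT_TYPES)}"
            )
        if len(set(self.variants)) != len(self.variants):
            raise LexiconError(f"duplicate variants for {self.canonical_phrase!r}")
        if self.canonical_phrase in self.variants:
            raise LexiconError(
                f"variant equals canonical phrase for {self.canonical_phrase!r}"
            )

    @property
    def all_forms(self) -> tuple[str, ...]:
        """Canonical phrase followed by its variants."""
        return (self.canonical_phrase, *self.variants)


@dataclass(frozen=True)
class KeyPhraseSet:
    """A validated collection of key phrases.

    Invariants enforced at construction: canonical phrases pairwise distinct,
    and no variant claimed by two different canonical phrases (counts must be
    attributable to exactly one phrase).
    """

    entries: tuple[KeyPhrase, ...]
    provenance: str = ""
    _by_phrase: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_phrase: dict[str, KeyPhrase] = {}
        owner: dict[str, str] = {}
        for kp in self.entries:
            if kp.canonical_phrase in by_phrase:
                raise LexiconError(
                    f"duplicate canonical phrase {kp.canonical_phrase!r}"
                )
            by_phrase[kp.canonical_phrase] = kp
            for form in kp.all_forms:
                if form in owner and owner[form] != kp.canonical_phrase:
                    raise LexiconError(
                        f"variant {form!r} is claimed by both "
                        f"{owner[form]!r} and {kp.canonical_phrase!r}"
                    )
                owner[form] = kp.canonical_phrase
        object.__setattr__(self, "_by_phrase", by_phrase)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[KeyPhrase]:
        return iter(self.entries)

    def __contains__(self, phrase: str) -> bool:
        return phrase in self._by_phrase

    def __getitem__(self, phrase: str) -> KeyPhrase:
        return self._by_phrase[phrase]

    @property
    def phrases(self) -> tuple[str, ...]:
        return tuple(kp.canonical_phrase for kp in self.entries)


def _parse_date(text: str, row: int) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError as exc:
        raise LexiconError(f"row {row}: malformed date {text!r}") from exc


def load_lexicon(path: str | Path, strict: bool = True) -> KeyPhraseSet:
    """Load a lexicon CSV (``phrase,type,first_letter_date,variants``).

    Variants are ``|``-separated and may be empty.  All phrases are
    normalized (lowercase, NFC, whitespace-collapsed).  In strict mode a
    repeated canonical phrase is an error; in lax mode repeats are merged by
    :func:`dedupe_first_occurrence`.
    """
    path = Path(path)
    records: list[KeyPhrase] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"phrase", "type", "first_letter_date", "variants"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LexiconError(
                f"{path}: expected header columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            phrase = normalize_phrase(row["phrase"])
            variants = tuple(
                dict.fromkeys(
                    v
                    for v in (normalize_phrase(p) for p in row["variants"].split("|"))
                    if v and v != phrase
                )
            )
            records.append(
                KeyPhrase(
                    canonical_phrase=phrase,
                    product_type=row["type"].strip().lower(),
                    first_letter_date=_parse_date(row["first_letter_date"], i),
                    variants=variants,
                )
            )
    if not records:
        raise LexiconError(f"{path}: empty lexicon file")
    if strict:
        return KeyPhraseSet(entries=tuple(records), provenance=str(path))
    merged = dedupe_first_occurrence(records)
    return replace(merged, provenance=str(path))


def write_lexicon(kps: KeyPhraseSet, path: str | Path) -> None:
    """Write a KeyPhraseSet back to the lexicon CSV dialect (round-trips)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phrase", "type", "first_letter_date", "variants"])
        for kp in kps:
            writer.writerow(
                [
                    kp.canonical_phrase,
                    kp.product_type,
                    kp.first_letter_date.isoformat(),
                    "|".join(kp.variants),
                ]
            )


def dedupe_first_occurrence(records: Iterable[KeyPhrase]) -> KeyPhraseSet:
    """Collapse repeated canonical phrases to one entry each.

    A product mentioned in several warning letters keeps the *earliest*
    letter date; variant lists are unioned (order of first appearance).
    Idempotent.
    """
    merged: dict[str, KeyPhrase] = {}
    for kp in records:
        prior = merged.get(kp.canonical_phrase)
        if prior is None:
            merged[kp.canonical_phrase] = kp
        else:
            variants = tuple(dict.fromkeys((*prior.variants, *kp.variants)))
            merged[kp.canonical_phrase] = replace(
                prior,
                first_letter_date=min(prior.first_letter_date, kp.first_letter_date),
                variants=variants,
            )
    return KeyPhraseSet(entries=tuple(merged.values()))


def filter_by_date_window(kps: KeyPhraseSet, latest_allowed: date) -> KeyPhraseSet:
    """Retain entries with first_letter_date on or before ``latest_allowed``."""
    kept = tuple(kp for kp in kps if kp.first_letter_date <= latest_allowed)
    return KeyPhraseSet(entries=kept, provenance=kps.provenance)


def naive_variant_expansion(phrase: str, max_edits: int = 1) -> list[str]:
    """Deterministic fallback variant generator (OFF by default in pipelines).

    Produces whitespace-joined/removed forms plus, for each token longer than
    4 characters, single-character deletions and adjacent transpositions.
    This is simple plumbing for when no curated variant list exists; shipped
    fixtures carry curated variants and do not use this.  The input itself is
    never returned; output is sorted and duplicate-free.
    """
    phrase = normalize_phrase(phrase)
    if not phrase:
        raise LexiconError("phrase must be non-empty")
    tokens = phrase.split()
    out: set[str] = {"".join(tokens), " ".join(tokens)}
    for ti, tok in enumerate(tokens):
        if len(tok) <= 4:
            continue
        edited: list[str] = []
        for j in range(len(tok)):
            edited.append(tok[:j] + tok[j + 1 :])  # deletion
        for j in range(len(tok) - 1):
            edited.append(tok[:j] + tok[j + 1] + tok[j] + tok[j + 2 :])
        for e in edited:
            out.add(" ".join([*tokens[:ti], e, *tokens[ti + 1 :]]))
    out.discard(phrase)
    return sorted(out)


def packaged_lexicon() -> KeyPhraseSet:
    """Load the key-phrase fixture shipped with the package (44 entries)."""
    ref = resources.files("infovigil.data") / "table1_keyphrases.csv"
    with resources.as_file(ref) as path:
        kps = load_lexicon(path, strict=True)
    return replace(kps, provenance="packaged table1_keyphrases.csv")
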