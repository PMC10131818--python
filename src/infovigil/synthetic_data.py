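"""Synthetic post streams and count tables with known ground truth.

The generator emulates the statistical structure the detector assumes:
heavy-tailed daily total post volumes (lognormal, millions per day at full
scale), sparse count-valued per-phrase mentions (Poisson around a small
per-1000 baseline rate, with optional negative-binomial overdispersion),
and promotion bursts — abrupt multiplicative increases in a phrase's
mention rate starting at a known onset day.  Everything is reproducible
from a single seed, so matching, detection and evaluation are testable
without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta, timezone, datetime
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .detector import DetectorConfig, detect_anomalies
from .lexicon import KeyPhraseSet
from .matcher import DailyCounts, PhraseMatcher
from .timeseries import relative_frequency

__all__ = [
    "BurstSpec",
    "SimulationConfig",
    "simulate_counts",
    "simulate_stream",
    "benchmark_detector",
]

# Nonsense filler vocabulary: no token appears in any real product name, so
# filler text alone can never fire the matcher (verified at emission time).
_FILLER_WORDS = (
    "zorply", "quindle", "vexthorn", "blippet", "crandle", "snorfle",
    "grubbin", "plimsy", "thwackle", "drossit", "fimble", "yarrup",
)


@dataclass(frozen=True)
class BurstSpec:
    """A promotion burst: the phrase's rate is multiplied by fold_change.

    ``shape='step'`` applies the full fold for the whole duration;
    ``'linear_ramp'`` ramps the multiplier linearly from 1 at onset to
    fold_change at the last burst day.
    """

    phrase: str
    onset_day: int
    duration: int
    fold_change: float
    shape: str = "step"

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("burst duration must be >= 1 day")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.shape not in ("step", "linear_ramp"):
            raise ValueError(f"unknown burst shape {self.shape!r}")

    def multiplier(self, n_days: int) -> np.ndarray:
        """Per-day rate multiplier over a series of length n_days."""
        if self.onset_day < 0 or self.onset_day + self.duration > n_days:
            raise ValueError("burst must lie within the simulated range")
        m = np.ones(n_days)
        span = np.arange(self.duration)
        if self.shape == "step":
            m[self.onset_day : self.onset_day + self.duration] = self.fold_change
        else:
            frac = span / max(self.duration - 1, 1)
            m[self.onset_day : self.onset_day + self.duration] = (
                1.0 + (self.fold_change - 1.0) * frac
            )
        return m


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: ~317 days of ~2M posts/day, sparse baselines.

    ``daily_total_mean`` is the arithmetic mean of the lognormal daily
    volume; ``daily_total_dispersion`` is the SD of log-volume (0.2 gives
    mild heavy-tailed day-to-day variation).  ``baseline_rates`` maps each
    phrase to its quiet-period mention rate in mentions per 1000 posts;
    0.5/1000 is a typical chattered-about product.  ``overdispersion``
    switches mention counts from Poisson to negative binomial with that
    Gamma shape (smaller = burstier); None keeps pure Poisson.
    """

    n_days: int = 317
    start_date: date = date(2020, 2, 19)
    daily_total_mean: float = 2_000_000.0
    daily_total_dispersion: float = 0.2
    baseline_rates: Mapping[str, float] = field(default_factory=dict)
    bursts: tuple[BurstSpec, ...] = ()
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if any(r < 0 for r in self.baseline_rates.values()):
            raise ValueError("baseline rates must be >= 0")
        for b in self.bursts:
            if b.phrase not in self.baseline_rates:
                raise ValueError(f"burst phrase {b.phrase!r} has no baseline rate")
            b.multiplier(self.n_days)  # validates the span


def simulate_counts(cfg: SimulationConfig) -> DailyCounts:
    """Draw daily totals and per-phrase mention counts with burst labels.

    X_t ~ lognormal with mean daily_total_mean; c_t ~ Poisson (or negative
    binomial) with mean X_t * rate_t / 1000, where rate_t carries the burst
    multipliers.  The returned DailyCounts records, per phrase, a boolean
    ground-truth mask of burst days in ``burst_labels``.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.daily_total_dispersion
    mu_log = np.log(cfg.daily_total_mean) - 0.5 * s * s
    totals = np.maximum(
        np.rint(rng.lognormal(mean=mu_log, sigma=s, size=cfg.n_days)), 1
    ).astype(np.int64)

    idx = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
    phrases = list(cfg.baseline_rates)
    counts = np.zeros((cfg.n_days, len(phrases)), dtype=np.int64)
    labels: dict[str, np.ndarray] = {}
    for j, phrase in enumerate(phrases):
        mult = np.ones(cfg.n_days)
        mask = np.zeros(cfg.n_days, dtype=bool)
        for b in cfg.bursts:
            if b.phrase == phrase:
                mult *= b.multiplier(cfg.n_days)
                mask[b.onset_day : b.onset_day + b.duration] = True
        mean = totals * cfg.baseline_rates[phrase] * mult / 1000.0
        if cfg.overdispersion is None:
            c = rng.poisson(mean)
        else:
            # NB as Gamma-Poisson mixture: shape r, mean preserved
            r = cfg.overdispersion
            lam = rng.gamma(shape=r, scale=np.where(mean > 0, mean / r, 0.0))
            c = rng.poisson(lam)
        counts[:, j] = np.minimum(c, totals)
        labels[phrase] = mask
    return DailyCounts(
        counts=pd.DataFrame(counts, index=idx, columns=phrases),
        totals=pd.Series(totals, index=idx, name="daily_total"),
        burst_labels=labels,
    )


def simulate_stream(
    counts: DailyCounts,
    keyphrases: KeyPhraseSet,
    out: str | Path | IO[str],
    seed: int = 0,
    variant_fraction: float = 0.5,
) -> int:
    """Emit a JSONL post stream that reproduces ``counts`` exactly on re-count.

    Exactly X_t posts per day; for each phrase, exactly c_t of them embed the
    canonical phrase or (with probability ``variant_fraction``) one of its
    variants, surrounded by nonsense filler that matches nothing.  The
    matcher round trip (count_stream over the emitted stream) recovers the
    input counts exactly.  Returns the number of posts written.  Byte-
    identical output under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    matcher = PhraseMatcher(keyphrases)
    for w in _FILLER_WORDS:
        if matcher.match(w):
            raise ValueError(f"filler word {w!r} collides with the lexicon")
    for phrase in counts.phrases:
        if phrase not in keyphrases:
            raise ValueError(f"counts phrase {phrase!r} missing from lexicon")

    def _emit(fh: IO[str]) -> int:
        written = 0
        for i, (day, total) in enumerate(counts.totals.items()):
            total = int(total)
            # phrase assignments: per phrase, c_t distinct post slots
            slots: list[list[str]] = [[] for _ in range(total)]
            for j, phrase in enumerate(counts.phrases):
                c = int(counts.counts.iat[i, j])
                if c > total:
                    raise ValueError(
                        f"c={c} exceeds X={total} for {phrase!r} on {day.date()}"
                    )
                if c == 0:
                    continue
                for slot in rng.choice(total, size=c, replace=False):
                    kp = keyphrases[phrase]
                    use_variant = kp.variants and rng.random() < variant_fraction
                    form = (
                        kp.variants[rng.integers(len(kp.variants))]
                        if use_variant
                        else phrase
                    )
                    slots[slot].append(form)
            ts = datetime(
                day.year, day.month, day.day, tzinfo=timezone.utc
            ) + timedelta(seconds=1)
            created = ts.strftime("%a %b %d %H:%M:%S +0000 %Y")
            for slot, forms in enumerate(slots):
                words = list(rng.choice(_FILLER_WORDS, size=3))
                for form in forms:
                    words.append(form)
                    words.append(str(rng.choice(_FILLER_WORDS)))
                fh.write(
                    json.dumps(
                        {
                            "id": f"{day.date().isoformat()}-{slot}",
                            "created_at": created,
                            "text": " ".join(words),
                        }
                    )
                    + "\n"
                )
                written += 1
        return written

    if hasattr(out, "write"):
        return _emit(out)  # type: ignore[arg-type]
    with Path(out).open("w", encoding="utf-8") as fh:
        return _emit(fh)


def benchmark_detector(
    detector_cfgs: Sequence[DetectorConfig],
    sim_cfg: SimulationConfig,
    n_reps: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo power study of the detector on paired simulated streams.

    For each replicate one count table is drawn and every detector config is
    run on the *same* data (paired seeds), giving per config:

    * sensitivity — fraction of burst phrases flagged at or after their
      first burst onset;
    * median detection delay in days from onset to first at/after-onset flag
      (NaN if no burst phrase was ever detected);
    * false-alarm day rate — flagged-day fraction across null phrases.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    burst_phrases = {b.phrase for b in sim_cfg.bursts}
    onsets = {
        p: min(b.onset_day for b in sim_cfg.bursts if b.phrase == p)
        for p in burst_phrases
    }
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    stats = {
        id(cfg): {"hits": 0, "bursts": 0, "delays": [], "fa_days": 0, "null_days": 0}
        for cfg in detector_cfgs
    }
    for rep_seed in rep_seeds:
        counts = simulate_counts(replace(sim_cfg, seed=int(rep_seed)))
        for phrase in counts.phrases:
            rates = relative_frequency(counts, phrase)
            for cfg in detector_cfgs:
                res = detect_anomalies(rates, cfg)
                st = stats[id(cfg)]
                if phrase in burst_phrases:
                    st["bursts"] += 1
                    onset = onsets[phrase]
                    post = np.flatnonzero(res.flags[onset:])
                    if post.size:
                        st["hits"] += 1
                        st["delays"].append(int(post[0]))
                else:
                    st["fa_days"] += int(res.flags.sum())
                    st["null_days"] += len(res.flags)
    rows = []
    for cfg in detector_cfgs:
        st = stats[id(cfg)]
        rows.append(
            {
                "window": cfg.window,
                "k": cfg.k,
                "day1_bias": cfg.day1_bias_enabled,
                "sensitivity": st["hits"] / st["bursts"] if st["bursts"] else np.nan,
                "median_delay_days": (
                    float(np.median(st["delays"])) if st["delays"] else np.nan
                ),
                "false_alarm_rate": (
                    st["fa_days"] / st["null_days"] if st["null_days"] else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
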