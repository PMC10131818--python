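from datetime import date

import numpy as np
import pandas as pd
import pytest

from infovigil.lexicon import KeyPhrase, KeyPhraseSet, packaged_lexicon
from infovigil.timeseries import RateSeries


@pytest.fixture(scope="session")
def table1_lexicon() -> KeyPhraseSet:
    """The packaged 44-phrase product lexicon."""
    return packaged_lexicon()


@pytest.fixture()
def small_lexicon() -> KeyPhraseSet:
    """A three-phrase lexicon with variants, for matcher/stream tests."""
    return KeyPhraseSet(
        entries=(
            KeyPhrase(
                "chlorine dioxide",
                "treatment",
                date(2020, 4, 8),
                ("chlorinedioxide", "clorine dioxide"),
            ),
            KeyPhrase("kratom", "treatment", date(2020, 5, 15)),
            KeyPhrase(
                "supersilver whitening toothpaste",
                "treatment",
                date(2020, 4, 9),
                ("supersilver whitening toothpast",),
            ),
        ),
        provenance="test fixture",
    )


def make_rate_series(
    x, phrase: str = "test", start: str = "2020-02-19", gaps=None
) -> RateSeries:
    x = np.asarray(x, dtype=float)
    return RateSeries(
        phrase=phrase,
        dates=pd.date_range(start, periods=len(x), freq="D"),
        x=x,
        gap_mask=np.zeros(len(x), dtype=bool) if gaps is None else np.asarray(gaps, bool),
    )


@pytest.fixture()
def rate_series_factory():
    return make_rate_series
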