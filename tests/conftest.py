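import warnings

import numpy as np
import pytest

from phonotrf.lexicon import FeatureLexicon, Interval, PhonemeAnnotation

# statsmodels mixed models emit convergence chatter on boundary fits
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def german_lexicon() -> FeatureLexicon:
    return FeatureLexicon.german()


@pytest.fixture(scope="session")
def toy_lexicon() -> FeatureLexicon:
    """Four phonemes over the full 17-feature inventory.

    a: voiced+syllabic+sonorant+continuant; b: voiced+consonantal+labial;
    s: strident+consonantal+coronal+anterior+continuant; l: voiced+lateral+
    consonantal+sonorant+coronal+anterior+continuant.
    """
    from phonotrf.lexicon import FEATURES

    def vec(*on):
        return np.array([1 if f in on else 0 for f in FEATURES], dtype=int)

    table = {
        "a": vec("voiced", "syllabic", "sonorant", "continuant"),
        "b": vec("voiced", "consonantal", "labial"),
        "s": vec("strident", "consonantal", "coronal", "anterior", "continuant"),
        "l": vec("voiced", "lateral", "consonantal", "sonorant", "coronal",
                 "anterior", "continuant"),
    }
    return FeatureLexicon(features=FEATURES, table=table)


def make_annotation(rows, total=None) -> PhonemeAnnotation:
    intervals = [Interval(lab, on, off) for lab, on, off in rows]
    if total is None:
        total = max((off for _, _, off in rows), default=0.0)
    return PhonemeAnnotation(intervals=intervals, total_duration=total)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
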