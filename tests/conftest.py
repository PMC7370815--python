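import numpy as np
import pytest

from contraspect import (
    Condition,
    ContrastResult,
    LuminanceField,
    load_fixture_catalog,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fixture_catalog():
    return load_fixture_catalog()


@pytest.fixture
def random_field(rng):
    def make(h=16, w=16):
        return LuminanceField(values=rng.random((h, w)))

    return make


def make_contrast_results(records, rng=None):
    """One deterministic-but-arbitrary ContrastResult per catalog record."""
    rng = rng or np.random.default_rng(0)
    out = []
    for rec in records:
        var = float(rng.uniform(0.0, 0.25))
        out.append(
            ContrastResult(
                variance_contrast=var,
                rms_contrast=float(np.sqrt(var)),
                image_id=rec.image_id,
            )
        )
    return out


HIGH_RANKS = {9, 10, 11, 12, 21, 22, 23, 27, 28}


def split_counts(records):
    low = sum(1 for r in records if r.condition is Condition.LOW)
    high = sum(1 for r in records if r.condition is Condition.HIGH)
    return low, high
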