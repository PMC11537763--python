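import numpy as np
import pandas as pd
import pytest

from sharedtaste import SyntheticConfig, generate_ratings


@pytest.fixture
def fixture_matrix() -> pd.DataFrame:
    """3 raters x 4 items with hand-derived agreement values.

    MM1 ~ 0.8317 (per-rater r = 0.8944, 0.8944, 0.6), Kendall's W =
    444/540, ICC(2,1) = 0.7857, interval Krippendorff alpha = 0.7556,
    Cronbach alpha = 33/37.
    """
    return pd.DataFrame(
        [[1, 2, 3, 4], [1, 2, 3, 4], [2, 1, 4, 3]],
        index=["r1", "r2", "r3"],
        columns=["i1", "i2", "i3", "i4"],
    )


@pytest.fixture(scope="session")
def study_table():
    """Default-configuration synthetic dataset at study size (seed 11)."""
    table, truth = generate_ratings(SyntheticConfig(seed=11))
    return table, truth


@pytest.fixture
def small_config() -> SyntheticConfig:
    """A fast, reduced design for structure-level tests."""
    return SyntheticConfig(
        n_raters=8, n_singers=4, n_melodies=2, styles=("lullaby", "pop"), seed=5
    )
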