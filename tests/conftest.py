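import numpy as np
import pandas as pd
import pytest

from disturbsamp.survey import (HEARD_COLUMNS, OBSERVATION_COLUMNS,
                                TRANSECT_COLUMNS, SurveyDataset)


def make_dataset(transects, observations=(), heard=()):
    """Build a SurveyDataset from row tuples (see survey column layouts)."""
    return SurveyDataset(
        pd.DataFrame(list(transects), columns=TRANSECT_COLUMNS),
        pd.DataFrame(list(observations), columns=OBSERVATION_COLUMNS),
        pd.DataFrame(list(heard), columns=HEARD_COLUMNS),
    )


@pytest.fixture
def tiny_dataset():
    """Two transects, a few observations including one poly-specific group."""
    transects = [
        ("A", 1, 1.0, "morning", 0.0), ("A", 2, 1.0, "afternoon", 0.0),
        ("A", 3, 1.0, "morning", 1.0), ("A", 4, 1.0, "morning", 5.0),
        ("B", 1, 0.8, "morning", 0.0), ("B", 2, 0.8, "afternoon", 0.0),
        ("B", 3, 0.8, "morning", 1.0),
    ]
    observations = [
        ("A", 2, "g1", "sp1", 1500.0, 4, 6.0),
        ("A", 3, "g2", "sp1", 2500.0, 3, 3.0),
        ("A", 3, "g2", "sp2", 2500.0, 2, 4.0),  # poly-specific partner row
        ("B", 3, "g3", "sp2", 500.0, 5, 8.0),
        ("A", 4, "g4", "sp1", 3000.0, 6, 9.0),
    ]
    heard = [
        ("A", 2, "sp1", "close"), ("A", 2, "sp2", "far"),
        ("B", 3, "sp1", "very_far"), ("A", 4, "sp2", "far"),
    ]
    return make_dataset(transects, observations, heard)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


def hn_sample(n, sigma, w, rng):
    """Distances from a uniform x half-normal sighting process."""
    out = np.empty(0)
    while len(out) < n:
        x = rng.uniform(0.0, w, size=4 * n)
        keep = rng.random(4 * n) < np.exp(-0.5 * (x / sigma) ** 2)
        out = np.concatenate([out, x[keep]])
    return out[:n]
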