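import numpy as np
import pandas as pd
import pytest

from commocc.camtrap_data import DetectionMatrix
from commocc.synthetic_data import paper_like_scenario, simulate_survey


@pytest.fixture(scope="session")
def paper_like_bundle():
    """One study-scale synthetic survey shared across tests (seed-fixed)."""
    return simulate_survey(paper_like_scenario("covariate"), seed=42)


@pytest.fixture(scope="session")
def null_bundle():
    """Study-scale survey without covariate effects."""
    return simulate_survey(paper_like_scenario("null"), seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix():
    """2 species x 3 sites x 2 occasions with one zero-effort cell."""
    y = np.array(
        [
            [[1, 0], [0, 0], [0, 1]],
            [[0, 0], [1, 0], [0, 0]],
        ],
        dtype=np.int8,
    )
    effort = np.array([[14.0, 14.0], [14.0, 0.0], [14.0, 8.0]])
    y[:, effort == 0] = 0
    return DetectionMatrix(
        y=y, species_ids=["fox", "boar"], site_ids=["A", "B", "C"], effort_days=effort
    )


def make_events(rows):
    """Helper: build an event table from (site, species, timestamp, n_images)."""
    return pd.DataFrame(rows, columns=["site_id", "species_id", "timestamp", "n_images"])
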