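"""Shared fixtures: tiny synthetic bundles and the published summary tables
used as inputs to the selection machinery."""

import numpy as np
import pandas as pd
import pytest

from dxopt import DSM4_CRITERIA, enumerate_rules
from dxopt.simulate import GeneratorConfig, generate, make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    """N=20, K=3 preset used by hand-checkable oracle tests."""
    bundle, truth, config = make_fixture("tiny")
    return bundle


@pytest.fixture(scope="session")
def k4_bundle():
    """Small K=4 panel for brute-force oracle comparisons (32 rules)."""
    config = GeneratorConfig(
        n_subjects=400,
        n_criteria=4,
        difficulties=(0.30, 0.25, 0.20, 0.15),
        informative_set=(0, 1),
        criterion_names=DSM4_CRITERIA[:4],
        seed=44,
    )
    bundle, _ = generate(config)
    return bundle


@pytest.fixture(scope="session")
def lattice11():
    return enumerate_rules(11)


# Published Votes row: proportion of the 55 fold-by-alpha solutions containing
# each criterion, in canonical order (Tolerance ... Fight/Trouble).
PRINTED_VOTES = np.array([0.51, 0.67, 0.49, 0.29, 0.62, 0.75, 0.98, 0.82, 0.29, 0.15, 0.60])


@pytest.fixture
def printed_votes():
    return PRINTED_VOTES.copy()


def _cv_rows():
    # (discovery fold, alpha range, D1..D5 percentiles, published row max)
    return [
        (1, "1.0 - .7", [None, 24.1, 38.8, 9.6, 3.4], 38.8),
        (1, ".6 - .3", [None, 21.6, 35.5, 8.5, 12.5], 35.5),
        (1, ".2 - .0", [None, 20.9, 31.6, 10.1, 11.1], 31.6),
        (2, "1.0 - .8", [15.8, None, 14.0, 9.1, 4.4], 15.8),
        (2, ".7", [19.8, None, 51.2, 24.9, 28.4], 51.2),
        (2, ".6 - .5", [31.0, None, 39.6, 14.1, 1.6], 39.6),
        (2, ".4 - .3", [32.2, None, 35.6, 12.6, 1.6], 35.6),
        (2, ".2 - .0", [32.7, None, 19.5, 30.7, 41.0], 41.0),
        (3, "1.0 - .6", [28.6, 38.5, None, 58.6, 28.3], 58.6),
        (3, ".5", [43.0, 13.0, None, 32.3, 24.8], 43.0),
        (3, ".4", [19.7, 17.7, None, 10.7, 17.6], 19.7),
        (3, ".3 - .0", [18.4, 19.7, None, 10.9, 16.4], 19.7),
        (4, "1.0 - .8", [20.0, 27.2, 10.7, None, 7.6], 27.2),
        (4, ".7 - .0", [9.6, 13.4, 25.9, None, 6.8], 25.9),
        (5, "1.0", [29.3, 32.4, 13.0, 14.0, None], 32.4),
        (5, ".9 - .5", [27.9, 7.0, 43.9, 14.1, None], 43.9),
        (5, ".0 - .4", [39.0, 18.8, 64.3, 21.2, None], 64.3),
    ]


@pytest.fixture
def printed_cv_matrix():
    """The published rule-by-fold percentile matrix as a DataFrame.

    One row per discovered rule (17 rows), columns D1..D5 with NaN on the
    discovery fold, plus the published maximum for checking.
    """
    rows = _cv_rows()
    df = pd.DataFrame(
        [
            {
                "fold": fold,
                "alpha_range": rng,
                **{f"D{i + 1}": (np.nan if v is None else v) for i, v in enumerate(cells)},
            }
            for fold, rng, cells, _ in rows
        ]
    )
    df["published_max"] = [m for *_, m in rows]
    return df
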