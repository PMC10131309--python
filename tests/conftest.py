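"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sasmote.data import validate_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_dataset(X, y, minority_label=None, label_name="y"):
    """Build a validated dataset from raw arrays."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df[label_name] = np.asarray(y)
    return validate_dataset(df, label_name, minority_label=minority_label)


def naive_visible_sets(anchors, neighbor_lists, points):
    """Triple-loop reference for the visibility definition.

    For each anchor x and each neighbor y in its list, y is visible iff
    (x - z) . (y - z) >= 0 for every z in the list.  Written with plain
    Python loops and scalar accumulation, independent of the package's
    vectorized implementation.
    """
    result = []
    for a, nbrs in zip(anchors, neighbor_lists):
        x = points[a]
        vis = []
        for y_idx in nbrs:
            y = points[y_idx]
            ok = True
            for z_idx in nbrs:
                z = points[z_idx]
                dot = 0.0
                for d in range(len(x)):
                    dot += (x[d] - z[d]) * (y[d] - z[d])
                if dot < 0.0:
                    ok = False
                    break
            if ok:
                vis.append(y_idx)
        result.append(np.array(vis, dtype=int))
    return result


def small_forest_factory(seed):
    """10-tree inspector for fast unit tests."""
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(n_estimators=10, random_state=seed)


@pytest.fixture
def crescent():
    """Default nonconvex crescent: 50 minority / 500 majority, seed 0."""
    from sasmote.datasets import SyntheticSpec, generate

    return generate(SyntheticSpec("nonconvex_crescent", 50, 500, seed=0))


@pytest.fixture
def blobs_separated():
    from sasmote.datasets import SyntheticSpec, generate

    return generate(SyntheticSpec("gaussian_blobs", 30, 120, seed=3))
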