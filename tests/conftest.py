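"""Shared fixtures: small hand-written datasets and seeded simulations.

Session-scoped simulation fixtures are shared across test modules so the
expensive fits (EM, forward selection) run once.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

import markernet as mn


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture()
def tiny_dataset() -> mn.ExpressionDataset:
    """3 genes x 6 samples, two classes, one clean marker per class."""
    matrix = pd.DataFrame(
        {
            "a1": [5.0, 1.0, 3.0],
            "a2": [5.2, 1.1, 3.1],
            "a3": [4.8, 0.9, 2.9],
            "b1": [1.0, 5.0, 3.0],
            "b2": [1.2, 5.1, 3.2],
            "b3": [0.8, 4.9, 2.8],
        },
        index=["gA", "gB", "gNeutral"],
    )
    labels = {s: ("A" if s.startswith("a") else "B") for s in matrix.columns}
    return mn.ExpressionDataset(matrix, labels)


@pytest.fixture(scope="session")
def planted():
    """Default planted simulation (4-sigma effects, blocks, quad pairs)."""
    return mn.generate(seed=7)


@pytest.fixture(scope="session")
def planted_ranker(planted):
    dataset, _ = planted
    X, y = dataset.to_xy()
    return mn.EmpiricalBayesRanker().fit(X, y)


@pytest.fixture(scope="session")
def separable():
    """Fully separable 5-class simulation (disjoint class envelopes)."""
    from markernet.synthetic import separable_dataset

    return separable_dataset(seed=11)


@pytest.fixture(scope="session")
def separable_pipeline(separable):
    dataset, _ = separable
    X, y = dataset.to_xy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mn.MarkerPipelineClassifier(
            config=mn.RunConfig(seed=11)
        ).fit(X, y)


@pytest.fixture(scope="session")
def network_sim():
    """Simulation whose per-class gene lists fit inside a top-30 network."""
    return mn.generate(
        n_classes=3, n_per_class=12, n_genes=600, de_per_class=25,
        block_size=5, seed=4,
    )


@pytest.fixture(scope="session")
def network_sim_ranking(network_sim):
    dataset, _ = network_sim
    X, y = dataset.to_xy()
    return mn.EmpiricalBayesRanker().fit(X, y).ranking_


def assert_frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> None:
    pd.testing.assert_frame_equal(a, b)
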