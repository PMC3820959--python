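"""Shared fixtures and toy-data builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ethotrack import featurize, simulate
from ethotrack.featurize import DEFAULT_MANIFEST, FeatureDataset
from ethotrack.sensor_io import CATEGORIES, BehaviorCategory, InertialRecording


FEATURE_NAMES = tuple(s.name for s in DEFAULT_MANIFEST)


def toy_dataset(
    counts: dict[BehaviorCategory, int],
    seed: int = 0,
    separation: float = 6.0,
    group: str | None = None,
    dog_id: str = "T01",
    breed: str = "Malinois",
    session_index: int = 1,
) -> FeatureDataset:
    """A synthetic feature dataset with linearly separable categories.

    Each category's windows are standard-normal noise shifted by a
    category-specific offset.  With *group* set, only that sensor group's
    columns carry the offset (so the classes are separable under that mask
    only); otherwise all columns do.
    """
    rng = np.random.default_rng(seed)
    if group is None:
        cols = np.arange(len(DEFAULT_MANIFEST))
    else:
        cols = np.array(
            [i for i, s in enumerate(DEFAULT_MANIFEST) if s.group == group]
        )
    blocks, labels = [], []
    for k, (cat, n) in enumerate(sorted(counts.items(), key=lambda kv: kv[0].value)):
        X = rng.normal(size=(n, len(DEFAULT_MANIFEST)))
        X[:, cols] += (k + 1) * separation
        blocks.append(X)
        labels.extend([cat] * n)
    X = np.vstack(blocks)
    n_total = len(X)
    prov = pd.DataFrame(
        {
            "dog_id": [dog_id] * n_total,
            "breed": [breed] * n_total,
            "session_index": [session_index] * n_total,
        }
    )
    return FeatureDataset(
        X, np.array(labels, dtype=object), np.arange(n_total, dtype=float),
        prov, FEATURE_NAMES,
    )


def featurized_study(
    n_per_breed: int,
    sessions: int,
    seed: int,
    sigma_ind: float = 0.15,
    seconds_per_item: float = 8.0,
    stride: int = 20,
    templates=None,
):
    """Generate and featurize a compact synthetic study."""
    pop = simulate.make_population(n_per_breed, sigma_ind, seed)
    meas = simulate.generate_study(
        pop, simulate.short_script(seconds_per_item), sessions,
        seed=seed + 1000, templates=templates,
    )
    return [
        featurize.featurize_session(m.recording, m.track, stride=stride)
        for m in meas
    ]


@pytest.fixture(scope="session")
def small_study_datasets():
    """3 dogs per breed, 2 compact sessions each, featurized at stride 20."""
    return featurized_study(n_per_breed=3, sessions=2, seed=11)


@pytest.fixture(scope="session")
def one_measurement():
    """A single labelled session of one default dog."""
    pop = simulate.make_population(1, 0.15, seed=5)
    return simulate.generate_session(pop[0], simulate.short_script(8.0), seed=6)
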