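"""Shared fixtures: small seeded synthetic datasets and trained models.

All fixtures are generated programmatically — no data files. Sizes are kept
small; the statistical structure (class effects, noise, hierarchy) matches
the package defaults so small runs are faithful miniatures of default runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sersnet import (
    ModelConfig,
    SpectraDataset,
    SplitSpec,
    SyntheticConfig,
    TrainConfig,
    build_model,
    generate_dataset,
    make_axis,
    minmax_normalize,
    split_dataset,
    train,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A miniature of the default generator: same effects, fewer cells."""
    return SyntheticConfig(n_cells=(24, 26), spectra_per_cell=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SpectraDataset:
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_dataset) -> SpectraDataset:
    return minmax_normalize(small_dataset)


@pytest.fixture(scope="session")
def trained_cnn(small_normalized):
    """A CNN trained briefly on the small synthetic dataset (separable)."""
    tr, va, te = split_dataset(small_normalized, SplitSpec(seed=3))
    net, _ = build_model("cnn", ModelConfig(), small_normalized.n_points, seed=5)
    result = train(net, tr, va, TrainConfig(epochs=4, seed=5))
    return {"model": net, "result": result, "splits": (tr, va, te)}


@pytest.fixture()
def tiny_dataset() -> SpectraDataset:
    """Hand-built 4-spectrum dataset on a 6-point axis for exact arithmetic."""
    w = np.array([100.0, 110.0, 120.0, 130.0, 140.0, 150.0])
    X = np.array(
        [
            [2.0, 4.0, 6.0, 4.0, 2.0, 0.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [0.0, 0.0, 0.0, 2.0, 2.0, 2.0],
            [1.0, 3.0, 1.0, 3.0, 1.0, 3.0],
        ]
    )
    meta = pd.DataFrame(
        {
            "spectrum_id": ["a", "b", "c", "d"],
            "cell_id": ["c1", "c1", "c2", "c2"],
            "label": ["mature", "mature", "immature", "immature"],
        }
    )
    return SpectraDataset(w, X, meta)


@pytest.fixture(scope="session")
def default_axis() -> np.ndarray:
    return make_axis()
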