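import numpy as np
import pandas as pd
import pytest

from plumap.synthetic import SimulationConfig, generate_region

EQUAL_MIX = {"PLU1": 0.2, "PLU2": 0.2, "PLU3": 0.2, "PLU4": 0.2, "PLU5": 0.2}


@pytest.fixture(scope="session")
def region():
    """Mixed 12 x 12 km region with all five archetypes (36 cells)."""
    config = SimulationConfig(extent_m=(12_000.0, 12_000.0), plu_mix=dict(EQUAL_MIX), seed=5)
    return generate_region(config)


@pytest.fixture(scope="session")
def region_features(region):
    from plumap.pipeline import extract_features

    features, grid, unmapped = extract_features(
        region.landcover,
        region.hydrotopo,
        region.rivers,
        region.roads,
        region.establishments,
    )
    return features, grid, unmapped


def random_window(rng: np.random.Generator, max_side=8, n_classes=4, p_nodata=0.0):
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    window = rng.integers(1, n_classes + 1, size=(h, w)).astype(np.uint8)
    if p_nodata > 0:
        window[rng.random((h, w)) < p_nodata] = 255
    return window


@pytest.fixture
def toy_labels():
    """Separable two-feature, three-class toy training table."""
    rng = np.random.default_rng(42)
    rows, labels = [], []
    for i, cls in enumerate(["PLU1", "PLU2", "PLU3"]):
        for _ in range(10):
            rows.append([i * 10 + rng.normal(0, 1), rng.normal(0, 1)])
            labels.append(cls)
    features = pd.DataFrame(rows, columns=["f0", "f1"])
    return features, pd.Series(labels)
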