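import numpy as np
import pytest

from areabayes.core_io import Dataset, Entity, FeatureSpec


def random_dataset(
    rng: np.random.Generator,
    n_entities: int = 10,
    n_features: int = 4,
    families: tuple[str | None, ...] = (None, "A", "B"),
    missing_rate: float = 0.0,
) -> Dataset:
    """Small random dataset for unit tests (2–4 states per feature)."""
    ns = rng.integers(2, 5, size=n_features)
    feats = [
        FeatureSpec(f"f{j}", tuple(f"s{s}" for s in range(ns[j])))
        for j in range(n_features)
    ]
    ents = [
        Entity(
            f"e{i}",
            (float(rng.uniform(0, 10)), float(rng.uniform(0, 10))),
            families[rng.integers(len(families))],
        )
        for i in range(n_entities)
    ]
    data = np.stack(
        [rng.integers(0, ns[j], size=n_entities) for j in range(n_features)], axis=1
    ).astype(np.int16)
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data[mask] = -1
    return Dataset(ents, feats, data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
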