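import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wildtrap as wt
from wildtrap.catalog import Catalog, ImageRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return wt.load_table1_fixture()


@pytest.fixture(scope="session")
def small_world():
    """Default-condition synthetic world, generated once per session."""
    return wt.generate_world(wt.default_world_config(seed=11))


@pytest.fixture(scope="session")
def easy_world():
    return wt.generate_world(wt.easy_world_config(seed=7))


def make_catalog(labels, locations=None, prefix="r"):
    """Minimal in-memory catalog with the given labels (and optional
    per-record locations)."""
    locations = locations or ["L1"] * len(labels)
    return Catalog(tuple(
        ImageRecord(image_id=f"{prefix}{i}", path=f"{prefix}{i}.png",
                    class_label=lab, location_id=loc)
        for i, (lab, loc) in enumerate(zip(labels, locations))))


@pytest.fixture
def toy_catalog():
    return make_catalog(["A", "A", "B"], ["L1", "L2", "L1"])


def flat_images(n, size=64, value=128, seed=None):
    """n constant (or seeded-noise) RGB test images."""
    if seed is None:
        return [np.full((size, size, 3), value, dtype=np.uint8) for _ in range(n)]
    rng = np.random.default_rng(seed)
    return [rng.integers(0, 256, (size, size, 3), dtype=np.uint8).astype(np.uint8)
            for _ in range(n)]
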