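"""Shared fixtures: a miniature two-site scenario for fast end-to-end tests
and a session-scoped full default dataset for the benchmark contracts."""

import numpy as np
import pytest

from col6fl import (
    FedAvgConfig,
    PathogenicClass,
    Scenario,
    SiteProfile,
    default_scenario,
    generate_federated_dataset,
)


@pytest.fixture(scope="session")
def tiny_scenario() -> Scenario:
    """Two small sites (24 + 10 images, 96 px frames) rendering in seconds."""
    bounds = default_scenario().texture_bounds
    site_a = SiteProfile(
        site_id="A",
        brightness_gain=1.0,
        blur_sigma=0.8,
        noise_sd=0.02,
        background_level=0.08,
        native_size=(96, 96),
        class_counts={c: 6 for c in PathogenicClass},
        patients_per_class={c: 2 for c in PathogenicClass},
        images_per_patient=(2, 4),
    )
    site_b = SiteProfile(
        site_id="B",
        brightness_gain=1.5,
        blur_sigma=1.5,
        noise_sd=0.05,
        background_level=0.18,
        native_size=(128, 128),
        class_counts={c: 3 for c in PathogenicClass},
        patients_per_class={c: 1 for c in PathogenicClass},
        images_per_patient=(2, 4),
    )
    return Scenario(
        texture_bounds=bounds,
        sites=[site_a, site_b],
        test_counts={"A": 4, "B": 2},
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scenario):
    return generate_federated_dataset(tiny_scenario, rng_seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The full packaged two-site benchmark dataset (300 + 31 images)."""
    return generate_federated_dataset(default_scenario(), rng_seed=11)


@pytest.fixture()
def fast_fedavg() -> FedAvgConfig:
    return FedAvgConfig(rounds=40, local_epochs=1, learning_rate=0.03, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
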