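"""Shared fixtures: small synthetic screens built at test time."""

import numpy as np
import pandas as pd
import pytest

from sgakit import ScreenConfig, generate_screen
from sgakit.spatial import prepare_plates


@pytest.fixture()
def config():
    return ScreenConfig()


@pytest.fixture(scope="session")
def clean_screen():
    """Noiseless, spatially flat two-query screen with one injected
    interaction — the multiplicative model passes through exactly."""
    plates, layout, truth = generate_screen(
        40,
        ("wt", "q"),
        4,
        interactions={("q", "g0007"): 0.5},
        noise_sigma=0.0,
        spatial_gradient=0.0,
        seed=11,
    )
    return plates, layout, truth


@pytest.fixture(scope="session")
def noisy_screen():
    """Screen with spatial gradients, moderate lognormal noise and 3
    injected strong interactions — detection is near-certain, so tests can
    assert exact hit sets while still exercising the full noisy pipeline."""
    inter = {("q", g): 0.5 for g in ("g0005", "g0050", "g0111")}
    plates, layout, truth = generate_screen(
        120,
        ("wt", "q"),
        4,
        interactions=inter,
        noise_sigma=0.06,
        spatial_gradient=0.2,
        seed=7,
    )
    return plates, layout, truth


@pytest.fixture(scope="session")
def normalized_noisy_screen(noisy_screen):
    plates, layout, truth = noisy_screen
    normalized, surfaces = prepare_plates(plates, layout)
    return normalized, layout, truth, surfaces
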