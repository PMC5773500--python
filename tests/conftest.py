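"""Shared fixtures: small synthetic acquisitions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from carpetfcs.carpet_io import LineScanCarpet
from carpetfcs.simcarpet import (
    LaminaSpec,
    SimulationConfig,
    SpeciesSpec,
    simulate_carpet,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_diffusion_carpet():
    """One diffusing species, short record: cheap input for estimator tests."""
    cfg = SimulationConfig(
        species=[SpeciesSpec(D_um2_per_s=3.5, brightness_cpsm=6.0, n_particles=150,
                             channel_weights=(0.0, 1.0))],
        n_pixels=96, n_lines=6000, seed=101, background_rate=0.1,
    )
    return simulate_carpet(cfg)


@pytest.fixture(scope="session")
def lamina_carpet():
    """Two-channel carpet with a static lamin stripe at column 60."""
    cfg = SimulationConfig(
        species=[SpeciesSpec(D_um2_per_s=2.0, brightness_cpsm=5.0, n_particles=120,
                             channel_weights=(0.0, 1.0))],
        n_pixels=128, n_lines=4000, seed=77, background_rate=0.2,
        lamina_channel=LaminaSpec(position_px=60, width_px=3.0, amplitude=25.0),
    )
    return simulate_carpet(cfg)


def poisson_carpet(n_lines: int, n_pixels: int, lam: float, seed: int) -> LineScanCarpet:
    """Uniform immobile field: pure shot noise at rate ``lam``."""
    cfg = SimulationConfig(species=[], n_pixels=n_pixels, n_lines=n_lines,
                           background_rate=lam, seed=seed)
    return simulate_carpet(cfg)
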