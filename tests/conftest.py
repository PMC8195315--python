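"""Shared fixtures: phantoms and (expensive) pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qpibench import (
    AcquisitionConfig,
    DetectorConfig,
    SphereSpec,
    sphere_opd_map,
)
from qpibench.phantoms import random_sphere_population
from qpibench.sweeps import measure_sphere_field, tile_sphere_fields

PIXEL = 0.65


@pytest.fixture(scope="session")
def baseline_acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def baseline_det() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture(scope="session")
def noise_free_det() -> DetectorConfig:
    return DetectorConfig().noise_free()


@pytest.fixture(scope="session")
def centered_sphere() -> SphereSpec:
    """One 67.7 μm bead (Δn = 0.02) centred in a 256² field."""
    return SphereSpec(83.2, 83.2, 67.7, 1.488, 1.468)


@pytest.fixture(scope="session")
def centered_sphere_phase(centered_sphere):
    return sphere_opd_map(centered_sphere, (256, 256), PIXEL)


@pytest.fixture(scope="session")
def baseline_recovery() -> pd.DataFrame:
    """Full-pipeline measurement of 20 beads at baseline with default noise.

    The population and seed match the headline recovery experiment; several
    tests read different columns of the same (expensive) run.
    """
    population = random_sphere_population(n_spheres=20, rng_seed=1)
    fields = tile_sphere_fields(population, (512, 512), PIXEL)
    acq, det = AcquisitionConfig(), DetectorConfig()
    frames = []
    for fi, specs in enumerate(fields):
        rng = np.random.default_rng([1, fi])
        df, _ = measure_sphere_field(specs, acq, det, rng, (512, 512), PIXEL)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
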