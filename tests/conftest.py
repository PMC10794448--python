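"""Shared fixtures: random frame factory and small rendered cohorts."""

import numpy as np
import pytest

from plaquetrend.synthetic import CohortConfig, _frame_contours, simulate_cohort


def random_frame(rng: np.random.Generator, n_vertices: int = 96):
    """One random valid lumen/vessel pair, star-shaped around the origin."""
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    shape = {
        "theta": theta,
        "lumen_harmonics": {
            1: (rng.uniform(0.0, 0.10), rng.uniform(10, 25),
                rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
            2: (rng.uniform(0.0, 0.15), rng.uniform(10, 25),
                rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
            3: (rng.uniform(0.0, 0.05), rng.uniform(8, 20),
                rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
            4: (rng.uniform(0.0, 0.05), rng.uniform(8, 20),
                rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
        },
        "thickness_track": (rng.uniform(0.2, 0.8), rng.uniform(12, 30),
                            rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
    }
    vessel_area = rng.uniform(10.0, 18.0)
    pb = rng.uniform(25.0, 75.0)
    lumen_area = vessel_area * (1.0 - pb / 100.0)
    x = rng.uniform(0.0, 40.0)
    return _frame_contours(shape, x, lumen_area, vessel_area, n_vertices)


@pytest.fixture(scope="session")
def small_cohort():
    """Rendered cohort small enough for full-pipeline tests (8 arteries)."""
    cfg = CohortConfig(
        n_patients=5, n_arteries=8, length_range_mm=(14.0, 20.0), seed=42
    )
    return simulate_cohort(cfg)
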