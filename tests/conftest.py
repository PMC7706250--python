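"""Shared fixtures.

The standard-bivariate-normal pipeline run at full study conditions
(n = 10,000 iterations, 1000 bins) is expensive, so it is computed once per
session and shared by the calibration and contour-geometry tests.
"""

import numpy as np
import pytest

from psared import (
    PsaSample,
    cumulative_map,
    evaluate_kde,
    extract_contours,
    make_grid,
    normalize_density,
    select_bandwidths,
    simulate_bivariate_normal,
)

STD_NORMAL_SEED = 0
STD_NORMAL_N = 10_000
STD_NORMAL_BINS = 1000
LEVELS = (0.1, 0.5, 0.95)


@pytest.fixture(scope="session")
def std_normal_run():
    """Full pipeline on 10,000 standard-bivariate-normal draws, 1000 bins."""
    sample = simulate_bivariate_normal(
        n=STD_NORMAL_N, mean=0.0, sd=1.0, seed=STD_NORMAL_SEED
    )
    bw = select_bandwidths(sample)
    grid = make_grid(sample, STD_NORMAL_BINS)
    dg = evaluate_kde(sample, grid, bw)
    ng = normalize_density(dg)
    cg = cumulative_map(dg)
    cs = extract_contours(cg, LEVELS)
    return {
        "sample": sample, "bw": bw, "grid": grid,
        "density": dg, "normalized": ng, "cumulative": cg, "contours": cs,
    }


@pytest.fixture
def small_sample():
    """Small deterministic PSA cloud for cheap unit tests."""
    rng = np.random.Generator(np.random.PCG64(7))
    return PsaSample(
        effects=rng.normal(0.05, 0.02, size=80),
        costs=rng.normal(2000.0, 400.0, size=80),
    )
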