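"""Synthetic PSA samples with known statistical structure.

Three generator families cover the regimes a PSA-ReD plot must handle:

* ``simulate_bivariate_normal`` — the textbook worked example: independent
  Normal(mean, sd) draws per axis, whose level-p highest density region is
  a disc of radius sqrt(chi2_2 quantile at p) standard deviations.
* ``simulate_skewed_psa`` — the regime seen in real health-economic models
  where a gamma-distributed effect with shape < 1 puts the density mode at
  zero while the mean (= shape/rate) sits away from it, so the base case
  and PSA mean fall outside the densest contour region.
* ``simulate_bimodal`` — a two-component normal mixture that forces
  disjoint contour lines at a shared cumulative-probability level.

All generators use numpy's PCG64 generator seeded explicitly, so fixtures
are reproducible across platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import PsaSample, write_psa_table

__all__ = [
    "simulate_bivariate_normal",
    "simulate_skewed_psa",
    "simulate_bimodal",
    "write_fixture_csv",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def simulate_bivariate_normal(
    n: int = 10_000, mean: float = 0.0, sd: float = 1.0, seed: int = 0
) -> PsaSample:
    """Independent Normal(mean, sd) draws on both axes."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = _rng(seed)
    return PsaSample(
        effects=rng.normal(mean, sd, size=n),
        costs=rng.normal(mean, sd, size=n),
    )


def simulate_skewed_psa(
    n: int = 10_000,
    alpha: float = 0.5,
    beta: float = 5.0,
    cost_base: float = 4000.0,
    cost_slope: float = 10_000.0,
    noise_sd: float = 500.0,
    seed: int = 0,
) -> PsaSample:
    """Right-skewed PSA cloud: gamma effects, linearly coupled costs.

    Effects ~ Gamma(shape=alpha, rate=beta); costs = cost_base +
    cost_slope * effect + Normal(0, noise_sd).  With ``alpha < 1`` the
    effect density mode is at 0 while the mean is alpha/beta > 0, so the
    densest plot region is displaced from the mean/base case.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma shape and rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    effects = rng.gamma(shape=alpha, scale=1.0 / beta, size=n)
    costs = cost_base + cost_slope * effects
    if noise_sd > 0:
        costs = costs + rng.normal(0.0, noise_sd, size=n)
    return PsaSample(effects=effects, costs=costs)


def simulate_bimodal(
    n: int = 10_000,
    centers: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (10.0, 10.0)),
    sds: tuple[float, float] = (0.5, 0.5),
    weight: float = 0.5,
    seed: int = 0,
) -> PsaSample:
    """Two-component bivariate-normal mixture.

    ``weight`` is the probability of the first component.  Well-separated
    centers force disjoint polylines at shared contour levels (e.g. two
    0.5-level contours, one around each mode).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < weight < 1.0):
        raise ValueError("weight must lie strictly inside (0, 1)")
    if any(s <= 0 for s in sds):
        raise ValueError("mode standard deviations must be positive")
    rng = _rng(seed)
    pick = rng.random(n) < weight
    (cx0, cy0), (cx1, cy1) = centers
    mx = np.where(pick, cx0, cx1)
    my = np.where(pick, cy0, cy1)
    s = np.where(pick, sds[0], sds[1])
    return PsaSample(
        effects=mx + s * rng.standard_normal(n),
        costs=my + s * rng.standard_normal(n),
    )


def write_fixture_csv(sample: PsaSample, path: str | Path) -> Path:
    """Write a fixture as a two-column CSV readable by ``read_psa_table``."""
    return write_psa_table(sample, path)
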