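"""Highest-density-region mapping and contour extraction.

The contour layer of a PSA-ReD plot is built from a *cumulative probability
map*: grid-cell densities are sorted from high to low and accumulated, so a
cell's value is the total normalized in-plot mass of all cells at least as
dense.  The level-p highest density region (HDR) is then the smallest set of
cells holding probability p, and the level-p contour joins locations where
the cumulative map equals p.  Contours are extracted with marching squares
(linear edge interpolation); a single level may own several disjoint
polylines when high-density areas are separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .density import DensityGrid, GridSpec
from .io import PsaSample

__all__ = [
    "CumulativeGrid",
    "Polyline",
    "ContourSet",
    "cumulative_map",
    "extract_contours",
    "empirical_coverage",
    "contour_radius_stats",
    "contours_to_csv",
]


@dataclass(frozen=True)
class CumulativeGrid:
    """Per-cell cumulative probability (mass of all cells at least as dense).

    ``cumprob`` shares the density grid's geometry; values lie in (0, 1],
    are anti-monotone with density, and the least dense cell maps to 1.
    """

    grid: GridSpec
    cumprob: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cumprob, dtype=float)
        if c.shape != (self.grid.n_bins_y, self.grid.n_bins_x):
            raise ValueError("cumprob shape does not match grid")
        object.__setattr__(self, "cumprob", c)

    @property
    def x_coords(self) -> np.ndarray:
        return self.grid.x_coords

    @property
    def y_coords(self) -> np.ndarray:
        return self.grid.y_coords


@dataclass(frozen=True)
class Polyline:
    """Ordered (effect, cost) vertices of one contour line.

    ``closed`` is False when the line was clipped at the plot boundary.
    """

    vertices: np.ndarray  # shape (k, 2), columns (x, y)
    closed: bool


@dataclass(frozen=True)
class ContourSet:
    """Contour polylines per cumulative-probability level."""

    levels: tuple[float, ...]
    lines: dict[float, list[Polyline]]

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, level: float) -> list[Polyline]:
        return self.lines[level]


def cumulative_map(dg: DensityGrid) -> CumulativeGrid:
    """Sort-and-accumulate the density grid into cumulative probabilities.

    Cell densities are sorted descending; the running sum of density x
    cell_area, divided by the total in-plot mass, is assigned back to each
    cell.  All cells in a tie block (equal density) receive the running
    total at the *end* of the block, which makes the map independent of
    sort order and sends a uniform grid to 1 everywhere.  The level-p HDR
    is the cell set ``{cumprob <= p}``.
    """
    flat = dg.density.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("density grid has zero total mass")

    order = np.argsort(flat, kind="stable")[::-1]
    sorted_d = flat[order]
    running = np.cumsum(sorted_d) / total
    running[-1] = 1.0  # cumsum round-off; the full grid holds all in-plot mass

    # Ties share the cumulative value at the end of their block.
    n = sorted_d.size
    block_last = np.append(np.nonzero(np.diff(sorted_d))[0], n - 1)
    block_sizes = np.diff(np.concatenate([[-1], block_last]))
    block_end = np.repeat(running[block_last], block_sizes)

    cum = np.empty_like(flat)
    cum[order] = block_end
    return CumulativeGrid(grid=dg.grid, cumprob=cum.reshape(dg.density.shape))


def extract_contours(
    cg: CumulativeGrid, levels: Sequence[float]
) -> ContourSet:
    """Iso-lines of the cumulative-probability surface at the given levels.

    Marching squares with linear interpolation along cell edges.  Polylines
    that meet the grid boundary are clipped there and flagged open; a
    disconnected level set yields several polylines.  A level below the mass
    of the single densest cell has an empty line list (with a warning).
    """
    lv = [float(v) for v in levels]
    for v in lv:
        if not (0.0 < v < 1.0):
            raise ValueError(f"contour level {v} must lie inside (0, 1)")
    if any(b <= a for a, b in zip(lv, lv[1:])):
        raise ValueError("levels must be strictly ascending")

    gs = cg.grid
    lines: dict[float, list[Polyline]] = {}
    for level in lv:
        raw = measure.find_contours(cg.cumprob, level)
        polys: list[Polyline] = []
        for arr in raw:
            # find_contours yields fractional (row, col) indices.
            xs = gs.x_min + arr[:, 1] * gs.dx
            ys = gs.y_min + arr[:, 0] * gs.dy
            verts = np.column_stack([xs, ys])
            closed = bool(np.allclose(arr[0], arr[-1]))
            polys.append(Polyline(vertices=verts, closed=closed))
        if not polys:
            warnings.warn(
                f"no contour at level {level}: the densest cell alone holds "
                f"more than {level:.3g} of the in-plot mass",
                stacklevel=2,
            )
        lines[level] = polys
    return ContourSet(levels=tuple(lv), lines=lines)


def _interpolator(cg: CumulativeGrid) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (cg.y_coords, cg.x_coords), cg.cumprob,
        method="linear", bounds_error=False, fill_value=None,
    )


def interpolate_cumprob(cg: CumulativeGrid, points: np.ndarray) -> np.ndarray:
    """Bilinearly interpolated cumulative probability at (effect, cost) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return _interpolator(cg)(np.column_stack([pts[:, 1], pts[:, 0]]))


def empirical_coverage(
    sample: PsaSample, cg: CumulativeGrid, level: float
) -> float:
    """Fraction of sample points inside the level-``level`` HDR.

    A point is inside when its bilinearly interpolated cumulative
    probability is <= level.  For a well-calibrated map the coverage at
    level p is close to p (e.g. the 0.95 region holds ~95% of iterations).
    """
    if not (0.0 < level <= 1.0):
        raise ValueError(f"level must be in (0, 1], got {level}")
    pts = np.column_stack([sample.effects, sample.costs])
    vals = interpolate_cumprob(cg, pts)
    return float(np.mean(vals <= level))


def contour_radius_stats(
    cs: ContourSet, center: tuple[float, float]
) -> dict[float, dict[str, float]]:
    """Per-level mean/min/max Euclidean vertex distance from ``center``.

    For a standard bivariate normal, the 0.95 contour's radii concentrate
    near sqrt(chi2_2(0.95)) = 2.45, which makes this the natural probe for
    contour correctness.
    """
    cx, cy = float(center[0]), float(center[1])
    out: dict[float, dict[str, float]] = {}
    for level in cs.levels:
        polys = cs.lines[level]
        if not polys:
            raise ValueError(f"no polylines at level {level}")
        radii = np.concatenate([
            np.hypot(p.vertices[:, 0] - cx, p.vertices[:, 1] - cy)
            for p in polys
        ])
        out[level] = {
            "mean": float(radii.mean()),
            "min": float(radii.min()),
            "max": float(radii.max()),
        }
    return out


def contours_to_csv(cs: ContourSet, path: str | Path) -> Path:
    """Export contour vertices as CSV: level, polyline id, vertex order, x, y."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("level,polyline,vertex,x,y\n")
        for level in cs.levels:
            for pid, poly in enumerate(cs.lines[level]):
                for vid, (x, y) in enumerate(poly.vertices):
                    fh.write(f"{level},{pid},{vid},{x!r},{y!r}\n")
    return path
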