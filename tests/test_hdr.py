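"""Cumulative-probability map, HDR contours, coverage and radius stats.

``cumulative_map`` is checked against an independent brute-force
sort-and-accumulate oracle (including tie blocks), and contour geometry
against the analytic highest-density-region radii of the bivariate normal:
the level-p HDR is a disc of radius sqrt(chi2_2 quantile at p).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from psared import (
    ContourSet,
    CumulativeGrid,
    DensityGrid,
    GridSpec,
    Polyline,
    PsaSample,
    contour_radius_stats,
    contours_to_csv,
    cumulative_map,
    empirical_coverage,
    extract_contours,
    interpolate_cumprob,
)


def brute_force_cumulative(density, cell_area):
    """Independent oracle: per-cell loop over 'all cells at least as dense'."""
    flat = density.ravel()
    total = (flat * cell_area).sum()
    out = np.array([
        (flat[flat >= v] * cell_area).sum() / total for v in flat
    ])
    return out.reshape(density.shape)


def grid_for(density, extent=1.0):
    ny, nx = density.shape
    return GridSpec(n_bins_x=nx, n_bins_y=ny,
                    x_min=0.0, x_max=extent, y_min=0.0, y_max=extent)


def analytic_normal_grid(n_bins=201, half_width=5.0):
    """Standard bivariate normal density evaluated exactly on a padded grid."""
    gs = GridSpec(n_bins_x=n_bins, n_bins_y=n_bins,
                  x_min=-half_width, x_max=half_width,
                  y_min=-half_width, y_max=half_width)
    xx, yy = np.meshgrid(gs.x_coords, gs.y_coords)
    dens = np.exp(-(xx**2 + yy**2) / 2) / (2 * np.pi)
    return DensityGrid(grid=gs, density=dens)


class TestCumulativeMap:
    def test_two_by_two_hand_example(self):
        dg = DensityGrid(
            grid=grid_for(np.empty((2, 2))),
            density=np.array([[4.0, 3.0], [2.0, 1.0]]),
        )
        cg = cumulative_map(dg)
        np.testing.assert_allclose(cg.cumprob, [[0.4, 0.7], [0.9, 1.0]])

    def test_uniform_density_is_single_tie_block(self):
        dg = DensityGrid(grid=grid_for(np.empty((4, 4))),
                         density=np.full((4, 4), 2.5))
        cg = cumulative_map(dg)
        assert np.all(cg.cumprob == 1.0)

    def test_single_cell_holds_all_mass(self):
        d = np.zeros((3, 3))
        d[1, 1] = 5.0
        cg = cumulative_map(DensityGrid(grid=grid_for(d), density=d))
        assert cg.cumprob[1, 1] == 1.0
        assert cg.cumprob[1, 1] == cg.cumprob.min()

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 10_000),
        ny=st.integers(2, 10),
        nx=st.integers(2, 10),
        quantize=st.booleans(),
    )
    def test_matches_brute_force_oracle(self, seed, ny, nx, quantize):
        rng = np.random.Generator(np.random.PCG64(seed))
        d = rng.random((ny, nx))
        if quantize:  # force tie blocks
            d = np.round(d * 4) / 4
        if d.sum() == 0:
            d[0, 0] = 1.0
        dg = DensityGrid(grid=grid_for(d), density=d)
        got = cumulative_map(dg).cumprob
        expected = brute_force_cumulative(d, dg.grid.cell_area)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_anti_monotone_with_density(self, std_normal_run):
        dg, cg = std_normal_run["density"], std_normal_run["cumulative"]
        order = np.argsort(dg.density.ravel())[::-1]
        cp = cg.cumprob.ravel()[order]
        assert np.all(np.diff(cp) >= -1e-15)
        assert cg.cumprob.ravel()[order[0]] == cg.cumprob.min()
        assert cg.cumprob.max() == 1.0

    def test_hdr_mass_self_consistency(self):
        rng = np.random.Generator(np.random.PCG64(21))
        d = rng.random((30, 30))
        dg = DensityGrid(grid=grid_for(d), density=d)
        cg = cumulative_map(dg)
        total = d.sum()
        max_cell = d.max() / total
        for p in (0.1, 0.5, 0.95):
            mass = d[cg.cumprob <= p].sum() / total
            assert mass <= p + 1e-12
            assert mass >= p - max_cell

    def test_hdr_nesting_exact(self, std_normal_run):
        cp = std_normal_run["cumulative"].cumprob
        r01, r05, r95 = (cp <= p for p in (0.1, 0.5, 0.95))
        assert np.all(r01 <= r05)
        assert np.all(r05 <= r95)

    def test_zero_mass_rejected(self):
        dg = DensityGrid(grid=grid_for(np.empty((2, 2))), density=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="zero total mass"):
            cumulative_map(dg)


class TestExtractContours:
    def test_analytic_normal_radii(self):
        # On an exact (not estimated) normal density, the level-p contour is
        # a circle of radius sqrt(chi2_2.ppf(p)).
        cg = cumulative_map(analytic_normal_grid(n_bins=401))
        cs = extract_contours(cg, (0.1, 0.5, 0.95))
        stats = contour_radius_stats(cs, (0.0, 0.0))
        cell_diag = np.hypot(cg.grid.dx, cg.grid.dy)
        for p in (0.1, 0.5, 0.95):
            expected = np.sqrt(chi2.ppf(p, df=2))
            assert stats[p]["mean"] == pytest.approx(expected, abs=0.02)
            # Radius spread bounded by the marching-squares resolution.
            assert stats[p]["max"] - stats[p]["min"] < cell_diag
            assert len(cs.lines[p]) == 1
            assert cs.lines[p][0].closed

    def test_two_separated_modes_give_disjoint_lines(self):
        gs = GridSpec(n_bins_x=301, n_bins_y=301,
                      x_min=-4, x_max=14, y_min=-4, y_max=14)
        xx, yy = np.meshgrid(gs.x_coords, gs.y_coords)
        d = (np.exp(-((xx - 0)**2 + (yy - 0)**2) / 2)
             + np.exp(-((xx - 10)**2 + (yy - 10)**2) / 2))
        cg = cumulative_map(DensityGrid(grid=gs, density=d))
        cs = extract_contours(cg, (0.5,))
        assert len(cs.lines[0.5]) >= 2

    def test_boundary_mode_clipped_open(self):
        # Window cuts through the mode: contours must end on the boundary.
        gs = GridSpec(n_bins_x=101, n_bins_y=101,
                      x_min=0.0, x_max=4.0, y_min=-4.0, y_max=4.0)
        xx, yy = np.meshgrid(gs.x_coords, gs.y_coords)
        d = np.exp(-(xx**2 + yy**2) / 2) / (2 * np.pi)
        cg = cumulative_map(DensityGrid(grid=gs, density=d))
        cs = extract_contours(cg, (0.5,))
        polys = cs.lines[0.5]
        assert polys and not all(p.closed for p in polys)
        open_poly = next(p for p in polys if not p.closed)
        for end in (open_poly.vertices[0], open_poly.vertices[-1]):
            on_edge = (
                np.isclose(end[0], gs.x_min) or np.isclose(end[0], gs.x_max)
                or np.isclose(end[1], gs.y_min) or np.isclose(end[1], gs.y_max)
            )
            assert on_edge

    def test_all_vertices_inside_extents(self, std_normal_run):
        gs = std_normal_run["grid"]
        for level in std_normal_run["contours"].levels:
            for poly in std_normal_run["contours"][level]:
                v = poly.vertices
                assert np.all((v[:, 0] >= gs.x_min) & (v[:, 0] <= gs.x_max))
                assert np.all((v[:, 1] >= gs.y_min) & (v[:, 1] <= gs.y_max))

    def test_level_below_densest_cell_warns_empty(self):
        d = np.zeros((3, 3))
        d[1, 1] = 1.0
        d[0, 0] = 0.1
        cg = cumulative_map(DensityGrid(grid=grid_for(d), density=d))
        with pytest.warns(UserWarning, match="densest cell"):
            cs = extract_contours(cg, (0.5,))
        assert cs.lines[0.5] == []

    @pytest.mark.parametrize("bad", [(0.0,), (1.0,), (-0.1,)])
    def test_invalid_level_rejected(self, std_normal_run, bad):
        with pytest.raises(ValueError, match="inside"):
            extract_contours(std_normal_run["cumulative"], bad)

    def test_non_ascending_levels_rejected(self, std_normal_run):
        with pytest.raises(ValueError, match="ascending"):
            extract_contours(std_normal_run["cumulative"], (0.5, 0.1))


class TestEmpiricalCoverage:
    def test_level_one_covers_everything(self, std_normal_run):
        cov = empirical_coverage(
            std_normal_run["sample"], std_normal_run["cumulative"], 1.0
        )
        assert cov == 1.0

    def test_coverage_calibration(self, std_normal_run):
        sample, cg = std_normal_run["sample"], std_normal_run["cumulative"]
        for level in (0.1, 0.5, 0.95):
            assert empirical_coverage(sample, cg, level) == pytest.approx(
                level, abs=0.02
            )

    def test_tiny_level_covers_almost_nothing(self, std_normal_run):
        cov = empirical_coverage(
            std_normal_run["sample"], std_normal_run["cumulative"], 1e-4
        )
        assert cov < 0.01

    def test_interpolation_at_grid_nodes_is_exact(self):
        d = np.array([[4.0, 3.0], [2.0, 1.0]])
        cg = cumulative_map(DensityGrid(grid=grid_for(d), density=d))
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        vals = interpolate_cumprob(cg, pts)
        np.testing.assert_allclose(vals, [cg.cumprob[0, 0], cg.cumprob[1, 1]])


class TestContourRadiusStats:
    def _circle(self, r=1.0, k=100):
        t = np.linspace(0, 2 * np.pi, k)
        return Polyline(
            vertices=np.column_stack([r * np.cos(t), r * np.sin(t)]),
            closed=True,
        )

    def test_unit_circle(self):
        cs = ContourSet(levels=(0.5,), lines={0.5: [self._circle()]})
        st_ = contour_radius_stats(cs, (0.0, 0.0))[0.5]
        assert st_["mean"] == pytest.approx(1.0)
        assert st_["min"] == pytest.approx(1.0)
        assert st_["max"] == pytest.approx(1.0)

    def test_homogeneity_under_scaling(self):
        c = 7.5
        cs1 = ContourSet(levels=(0.5,), lines={0.5: [self._circle(1.0)]})
        cs2 = ContourSet(levels=(0.5,), lines={0.5: [self._circle(c)]})
        s1 = contour_radius_stats(cs1, (0.0, 0.0))[0.5]
        s2 = contour_radius_stats(cs2, (0.0, 0.0))[0.5]
        for key in ("mean", "min", "max"):
            assert s2[key] == pytest.approx(c * s1[key])

    def test_empty_level_rejected(self):
        cs = ContourSet(levels=(0.5,), lines={0.5: []})
        with pytest.raises(ValueError, match="no polylines"):
            contour_radius_stats(cs, (0.0, 0.0))


def test_contours_to_csv_layout(tmp_path):
    t = np.linspace(0, 2 * np.pi, 5)
    poly = Polyline(
        vertices=np.column_stack([np.cos(t), np.sin(t)]), closed=True
    )
    cs = ContourSet(levels=(0.5,), lines={0.5: [poly]})
    p = contours_to_csv(cs, tmp_path / "c.csv")
    lines = p.read_text().splitlines()
    assert lines[0] == "level,polyline,vertex,x,y"
    assert len(lines) == 6
    assert lines[1].startswith("0.5,0,0,")
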