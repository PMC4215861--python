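"""Cavity volume, mass and clinical indices against closed forms and oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lvatlas as lv
from lvatlas.geometry import (ED, ES, SurfaceGrid, SurfacePointSet,
                              cavity_volume, clinical_indices, lv_mass)
from lvatlas.synthetic import LVGeomParams, generate_lv_surface

ML = 1000.0  # mm^3 per ml


def half_spheroid_volume_ml(a: float, c: float) -> float:
    return 2.0 / 3.0 * math.pi * a * a * c / ML


def hemisphere(radius: float, wall: float, grid: SurfaceGrid) -> SurfacePointSet:
    p = LVGeomParams.from_sphericity(radius, 1.0, wall_thickness=wall)
    return generate_lv_surface(p, ED, grid)


class TestCavityVolume:
    def test_hemisphere_closed_form_default_grid(self):
        """At the default 37x37 grid the inscribed triangulation loses the
        circumferential chord area, (1 - (n/2pi) sin(2pi/n)) = 0.48% for
        n = 37, plus ~0.05% longitudinally: the volume is ~0.53% low, and
        the deficit matches that closed-form prediction."""
        s = hemisphere(30.0, 4.0, SurfaceGrid())
        expected = half_spheroid_volume_ml(30.0, 30.0)  # 56.55 ml
        assert cavity_volume(s) == pytest.approx(expected, rel=6e-3)
        n = 37
        chord_factor = n / (2 * math.pi) * math.sin(2 * math.pi / n)
        assert cavity_volume(s) / expected == pytest.approx(chord_factor,
                                                            abs=1e-3)

    def test_hemisphere_closed_form_fine_grid(self):
        s = hemisphere(30.0, 4.0, SurfaceGrid(151, 150))
        expected = half_spheroid_volume_ml(30.0, 30.0)
        assert cavity_volume(s) == pytest.approx(expected, rel=5e-4)

    def test_hemisphere_endo_points_on_sphere(self):
        """Sphericity 1 degenerates the cavity to a hemisphere: every endo
        point sits exactly one radius from the cavity center."""
        s = hemisphere(30.0, 4.0, SurfaceGrid())
        r = np.linalg.norm(s.surface("endo").reshape(-1, 3), axis=1)
        np.testing.assert_allclose(r, 30.0, atol=1e-9)

    def test_doubling_coordinates_scales_volume_by_8(self):
        s = hemisphere(25.0, 5.0, SurfaceGrid(13, 13))
        doubled = SurfacePointSet(2.0 * s.points, s.grid, s.frame)
        assert cavity_volume(doubled) == pytest.approx(8.0 * cavity_volume(s),
                                                       rel=1e-12)

    def test_monte_carlo_point_in_solid_oracle(self):
        """Divergence-theorem volume of the a=20, c=45 half-spheroid cavity
        agrees with a 1e6-sample Monte-Carlo point-in-solid estimate within
        3 MC standard errors (grid fine enough that discretization error is
        negligible against the MC noise)."""
        a, c = 20.0, 45.0
        p = LVGeomParams.from_sphericity(a, a / c, wall_thickness=5.0)
        s = generate_lv_surface(p, ED, SurfaceGrid(201, 200))
        vol = cavity_volume(s)

        rng = np.random.default_rng(2024)
        n = 1_000_000
        pts = rng.uniform([-a, -a, -c], [a, a, 0.0], size=(n, 3))
        inside = ((pts[:, 0] ** 2 + pts[:, 1] ** 2) / a ** 2
                  + pts[:, 2] ** 2 / c ** 2) <= 1.0
        box = (2 * a) * (2 * a) * c / ML
        p_hat = inside.mean()
        mc_vol = box * p_hat
        mc_se = box * math.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(vol - mc_vol) < 3.0 * mc_se

    def test_grid_refinement_error_decreases_monotonically(self):
        exact = half_spheroid_volume_ml(30.0, 30.0)
        errors = [abs(cavity_volume(hemisphere(30.0, 4.0, SurfaceGrid(n, n))) - exact)
                  for n in (10, 20, 40)]
        assert errors[0] > errors[1] > errors[2]

    def test_non_finite_surface_rejected(self):
        s = hemisphere(30.0, 4.0, SurfaceGrid(8, 8))
        pts = s.points.copy()
        pts[5, 0] = np.nan
        with pytest.raises(ValueError):
            SurfacePointSet(pts, s.grid, s.frame)


class TestMass:
    def test_concentric_hemispheres_closed_form(self):
        s = hemisphere(30.0, 4.0, SurfaceGrid())
        expected = (half_spheroid_volume_ml(34.0, 34.0)
                    - half_spheroid_volume_ml(30.0, 30.0)) * 1.05  # 26.94 g
        # same ~0.53% inscribed-chord deficit as the cavity volume
        assert lv_mass(s) == pytest.approx(expected, rel=6e-3)
        fine = hemisphere(30.0, 4.0, SurfaceGrid(151, 150))
        assert lv_mass(fine) == pytest.approx(expected, rel=5e-4)

    def test_mass_vanishes_with_wall_thickness(self):
        masses = [lv_mass(hemisphere(30.0, w, SurfaceGrid(15, 15)))
                  for w in (4.0, 1.0, 0.25, 0.05)]
        assert masses[0] > masses[1] > masses[2] > masses[3]
        assert masses[-1] < 1.0

    def test_mass_conserved_from_ed_to_es(self):
        """The generator derives ES by conserving wall volume, so the mass of
        the two frames agrees."""
        p = LVGeomParams.from_sphericity(25.0, 0.3, wall_thickness=9.0,
                                         radial_shortening=0.3,
                                         longitudinal_shortening=0.15)
        m_ed = lv_mass(generate_lv_surface(p, ED))
        m_es = lv_mass(generate_lv_surface(p, ES))
        assert m_es == pytest.approx(m_ed, rel=0.01)

    def test_inverted_surfaces_rejected(self):
        s = hemisphere(30.0, 4.0, SurfaceGrid(8, 8))
        half = s.grid.points_per_surface
        swapped = np.concatenate([s.points[half:], s.points[:half]])
        with pytest.raises(ValueError, match="[Ii]nverted"):
            lv_mass(SurfacePointSet(swapped, s.grid, s.frame))


class TestClinicalIndices:
    def test_identical_frames_have_zero_ef(self):
        p = LVGeomParams.from_sphericity(25.0, 0.3, wall_thickness=8.0)
        ed = generate_lv_surface(p, ED)
        es = SurfacePointSet(ed.points.copy(), ed.grid, ES)
        ci = clinical_indices(ed, es)
        assert ci.ejection_fraction == pytest.approx(0.0, abs=1e-12)

    def test_ef_matches_closed_form_spheroid_volumes(self):
        a, s_ratio, rs, ls = 26.0, 0.3, 0.3, 0.15
        p = LVGeomParams.from_sphericity(a, s_ratio, wall_thickness=8.0,
                                         radial_shortening=rs,
                                         longitudinal_shortening=ls)
        ci = clinical_indices(generate_lv_surface(p, ED),
                              generate_lv_surface(p, ES))
        expected_ef = 1.0 - (1.0 - rs) ** 2 * (1.0 - ls)
        assert ci.ejection_fraction == pytest.approx(expected_ef, rel=1e-3)
        assert ci.edv_ml == pytest.approx(half_spheroid_volume_ml(a, a / s_ratio),
                                          rel=6e-3)


@st.composite
def geom_params(draw):
    a = draw(st.floats(15.0, 40.0))
    s = draw(st.floats(0.2, 0.9))
    wall = draw(st.floats(2.0, 0.5 * a))
    tilt = draw(st.floats(-15.0, 15.0))
    rs = draw(st.floats(0.0, 0.5))
    ls = draw(st.floats(0.0, 0.4))
    return LVGeomParams.from_sphericity(a, s, wall_thickness=wall,
                                        mitral_tilt=tilt, radial_shortening=rs,
                                        longitudinal_shortening=ls)


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=geom_params(), frame=st.sampled_from([ED, ES]))
    def test_volume_positive_and_scaling_law(self, params, frame):
        s = generate_lv_surface(params, frame, SurfaceGrid(11, 11))
        v = cavity_volume(s)
        assert v > 0
        doubled = SurfacePointSet(2 * s.points, s.grid, s.frame)
        assert cavity_volume(doubled) == pytest.approx(8 * v, rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(params=geom_params(), bump=st.floats(1.0, 8.0))
    def test_volume_strictly_increases_with_cavity_radius(self, params, bump):
        import dataclasses

        grid = SurfaceGrid(11, 11)
        bigger = dataclasses.replace(
            params,
            base_endo_radius=params.base_endo_radius + bump,
            long_axis_length=params.long_axis_length)
        v0 = cavity_volume(generate_lv_surface(params, ED, grid))
        v1 = cavity_volume(generate_lv_surface(bigger, ED, grid))
        assert v1 > v0
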