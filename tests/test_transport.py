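"""Transporter flux law, finite-volume solver, flux audits, sweeps."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ANNULUS_R_INNER, ANNULUS_R_OUTER, annulus_spec, pixel_centres
from villimorph import phantoms
from villimorph.datatypes import CrossSectionLabels
from villimorph.errors import ConvergenceError, GeometryError
from villimorph.transport import (ConcentrationField, TransporterParams,
                                  build_problem, flux_report,
                                  permeability_sweep, solve_steady_state,
                                  transporter_flux)

ANNULUS_UPTAKE = 2 * math.pi / math.log(ANNULUS_R_OUTER / ANNULUS_R_INNER)


def annulus_analytic(cross):
    yy, xx = pixel_centres(cross)
    r = np.hypot(yy, xx)
    return np.log(np.clip(r, 1e-9, None) / ANNULUS_R_INNER) / math.log(
        ANNULUS_R_OUTER / ANNULUS_R_INNER)


class TestTransporterFlux:
    def test_unit_substitution(self):
        params = TransporterParams(V_max=1.0, K_m=0.5)
        assert transporter_flux(1.0, 0.0, params) == pytest.approx(2 / 3,
                                                                   abs=1e-15)

    def test_equal_concentrations_carry_no_flux(self):
        params = TransporterParams(V_max=2.0, K_m=0.5)
        assert transporter_flux(0.3, 0.3, params) == 0.0

    def test_saturation_approaches_vmax(self):
        params = TransporterParams(V_max=1.0, K_m=0.5)
        assert transporter_flux(1000.0, 0.0, params) == pytest.approx(
            1000 / 1000.5, abs=1e-12)  # ≈ 0.9995

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            transporter_flux(-0.1, 0.2, TransporterParams())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c1=st.floats(0.0, 100.0), c2=st.floats(0.0, 100.0),
           km=st.floats(0.01, 10.0), vmax=st.floats(0.0, 10.0))
    def test_antisymmetry_and_bound(self, c1, c2, km, vmax):
        params = TransporterParams(V_max=vmax, K_m=km)
        fwd = transporter_flux(c1, c2, params)
        rev = transporter_flux(c2, c1, params)
        assert fwd == pytest.approx(-rev, abs=1e-12)
        assert abs(fwd) <= vmax + 1e-12


class TestBuildProblem:
    def test_membrane_faces_form_one_closed_ring(self, annulus_cross_256):
        cross, _ = annulus_cross_256
        problem = build_problem(cross, TransporterParams())
        assert problem.n_membrane_faces > 0
        # The trophoblast-side membrane pixels form a single connected ring.
        from scipy import ndimage
        ring = np.zeros(problem.labels.shape, dtype=bool)
        flat = problem.cell_index >= 0
        cells = np.flatnonzero(flat.ravel())
        ring.ravel()[cells[problem.faces_membrane[0]]] = True
        _, n_components = ndimage.label(
            ring, structure=ndimage.generate_binary_structure(2, 2))
        assert n_components == 1

    def test_invaginated_geometry_has_more_membrane_faces(self, equal_area_pair):
        params = TransporterParams()
        smooth = build_problem(equal_area_pair["smooth"][1], params)
        invag = build_problem(equal_area_pair["invaginated"][1], params)
        assert invag.n_membrane_faces > smooth.n_membrane_faces

    def test_missing_capillaries_rejected(self):
        spec = phantoms.CrossSectionSpec(outer_radius=30.0,
                                         trophoblast_thickness=10.0,
                                         pixel_size=0.5)
        cross, _ = phantoms.make_cross_section(spec)
        with pytest.raises(GeometryError, match="capillary"):
            build_problem(cross, TransporterParams())

    def test_broken_trophoblast_ring_rejected(self):
        labels = np.zeros((16, 16), dtype=np.uint16)
        labels[4:12, 4:12] = 2  # stroma block touching the exterior
        labels[7:9, 7:9] = 3
        labels[4, 4] = 1
        with pytest.raises(GeometryError, match="exterior"):
            build_problem(CrossSectionLabels(labels, pixel_size=1.0),
                          TransporterParams())


class TestSimpleDiffusion:
    def test_annulus_matches_closed_form(self, annulus_simple_field_256):
        cross, problem, field = annulus_simple_field_256
        analytic = annulus_analytic(cross)
        tissue = ~np.isnan(field.c)
        assert np.abs(field.c - analytic)[tissue].max() <= 0.01
        report = flux_report(field, problem)
        assert report.capillary_uptake == pytest.approx(ANNULUS_UPTAKE, rel=0.01)

    def test_grid_convergence_is_monotone(self):
        errors = []
        for n in (96, 160, 256):
            cross, _ = phantoms.make_cross_section(annulus_spec(2 * 103 / n))
            problem = build_problem(cross, TransporterParams(mode="simple"))
            field = solve_steady_state(problem)
            analytic = annulus_analytic(cross)
            tissue = ~np.isnan(field.c)
            errors.append(np.abs(field.c - analytic)[tissue].max())
        assert errors[0] > errors[1] > errors[2]

    def test_maximum_principle(self, annulus_simple_field_256):
        _, _, field = annulus_simple_field_256
        assert np.nanmin(field.c) >= -1e-9
        assert np.nanmax(field.c) <= 1 + 1e-9


class TestFacilitatedDiffusion:
    @pytest.mark.parametrize("membrane_number", [0.1, 1.0, 10.0])
    def test_conservation_at_all_regimes(self, annulus_cross_256,
                                         membrane_number):
        cross, _ = annulus_cross_256
        params = TransporterParams(V_max=membrane_number / ANNULUS_R_OUTER)
        problem = build_problem(cross, params)
        field = solve_steady_state(problem)
        report = flux_report(field, problem)
        assert report.imbalance <= 1e-6
        assert report.membrane_flux_integral == pytest.approx(
            report.capillary_uptake, rel=1e-6)
        assert -1e-8 <= np.nanmin(field.c) and np.nanmax(field.c) <= 1 + 1e-8

    def test_high_vmax_limit_recovers_simple_mode(self, annulus_cross_256,
                                                  annulus_simple_field_256):
        cross, _ = annulus_cross_256
        _, _, simple_field = annulus_simple_field_256
        params = TransporterParams(V_max=1000.0 / ANNULUS_R_OUTER)
        field = solve_steady_state(build_problem(cross, params))
        assert np.nanmax(np.abs(field.c - simple_field.c)) < 0.01

    def test_sealed_membrane_at_vmax_zero(self, annulus_cross_256):
        cross, _ = annulus_cross_256
        problem = build_problem(cross, TransporterParams(V_max=0.0))
        field = solve_steady_state(problem)
        report = flux_report(field, problem)
        troph = cross.labels == 1
        stroma = cross.labels == 2
        assert np.allclose(field.c[troph], 1.0, atol=1e-9)
        assert np.allclose(field.c[stroma], 0.0, atol=1e-9)
        assert report.capillary_uptake == pytest.approx(0.0, abs=1e-12)
        assert report.membrane_flux_integral == pytest.approx(0.0, abs=1e-12)

    def test_uptake_monotone_in_vmax(self, annulus_cross_256):
        cross, _ = annulus_cross_256
        uptakes = []
        for bi in (0.0, 0.1, 1.0, 10.0, 100.0):
            problem = build_problem(
                cross, TransporterParams(V_max=bi / ANNULUS_R_OUTER))
            uptakes.append(flux_report(solve_steady_state(problem),
                                       problem).capillary_uptake)
        assert all(b >= a - 1e-12 for a, b in zip(uptakes, uptakes[1:]))

    def test_nonconvergence_raises_with_residual(self, annulus_cross_256):
        cross, _ = annulus_cross_256
        problem = build_problem(cross, TransporterParams(V_max=0.1))
        with pytest.raises(ConvergenceError) as excinfo:
            solve_steady_state(problem, tol=1e-14, max_iter=2)
        assert excinfo.value.residual is not None

    def test_flux_report_refuses_unconverged_field(self, annulus_cross_256):
        cross, _ = annulus_cross_256
        problem = build_problem(cross, TransporterParams(V_max=0.1))
        field = solve_steady_state(problem)
        fake = ConcentrationField(c=field.c, residual=1.0, iterations=1,
                                  converged=False,
                                  cell_values=field.cell_values,
                                  membrane_flux_density=field.membrane_flux_density)
        with pytest.raises(ConvergenceError):
            flux_report(fake, problem)


class TestPermeabilitySweep:
    def test_membrane_limited_ratio_tracks_membrane_length(self, equal_area_pair):
        smooth_cross = equal_area_pair["smooth"][1]
        invag_cross = equal_area_pair["invaginated"][1]
        v_low = 0.01 / 60.0  # membrane number 0.01 at r_o = 60 µm
        table = permeability_sweep(smooth_cross, invag_cross, [v_low])
        row = table.iloc[0]
        assert row.uptake_invaginated > row.uptake_smooth
        assert row.uptake_ratio == pytest.approx(row.membrane_length_ratio,
                                                 rel=0.10)

    def test_high_vmax_ratio_matches_simple_mode_ratio(self, equal_area_pair):
        smooth_cross = equal_area_pair["smooth"][1]
        invag_cross = equal_area_pair["invaginated"][1]
        v_high = 1000.0 / 60.0
        table = permeability_sweep(smooth_cross, invag_cross, [v_high])
        simple_uptakes = {}
        for name, cross in (("smooth", smooth_cross), ("invag", invag_cross)):
            problem = build_problem(cross, TransporterParams(mode="simple"))
            simple_uptakes[name] = flux_report(
                solve_steady_state(problem), problem).capillary_uptake
        simple_ratio = simple_uptakes["invag"] / simple_uptakes["smooth"]
        assert table.iloc[0].uptake_ratio == pytest.approx(simple_ratio,
                                                           rel=0.02)

    def test_duplicated_geometry_gives_unit_ratios(self, equal_area_pair):
        cross = equal_area_pair["smooth"][1]
        table = permeability_sweep(cross, cross, [0.001, 0.1])
        assert np.allclose(table.uptake_ratio, 1.0, atol=1e-9)
        assert np.allclose(table.membrane_length_ratio, 1.0)
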