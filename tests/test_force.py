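import math

import numpy as np
import pytest

from archflow.force import (
    FieldError,
    ForceVector,
    UndefinedDirectionError,
    classify_direction,
    graft_surface_area,
    integrate_force,
    systolic_peak_time,
)
from archflow.meshes import (
    TriSurface,
    assign_poiseuille_fields,
    assign_uniform_pressure,
    gen_closed_sphere,
    gen_tube_mesh,
)
from archflow.waveform import gen_inflow_waveform
from archflow.windkessel import PressureTrace, WindkesselParams, simulate_wk3


class TestIntegrateForce:
    def test_closed_surface_uniform_pressure_vanishes(self):
        """Divergence theorem: uniform p over a closed surface is force-free."""
        for refinement in (2, 3):
            s = assign_uniform_pressure(gen_closed_sphere(1.0, refinement), 10000.0)
            f = integrate_force(s)
            assert f.magnitude <= 1e-9 * 10000.0 * s.total_area

    def test_bend_tube_pressure_force(self):
        """90-degree bend under uniform p: |F| = sqrt(2) p pi r^2 (cap defect)."""
        exact = math.sqrt(2) * 15000.0 * math.pi * 0.02**2  # 26.657 N
        m = assign_uniform_pressure(
            gen_tube_mesh(0.02, 90.0, "bend", 128, 128, bend_radius=0.05), 15000.0
        )
        assert integrate_force(m).magnitude == pytest.approx(exact, rel=1e-3)

    def test_bend_tube_force_second_order_convergence(self):
        exact = math.sqrt(2) * 15000.0 * math.pi * 0.02**2
        ns = [16, 32, 64]
        errs = []
        for n in ns:
            m = assign_uniform_pressure(
                gen_tube_mesh(0.02, 90.0, "bend", n, n, bend_radius=0.05), 15000.0
            )
            errs.append(abs(integrate_force(m).magnitude - exact))
        slope = np.polyfit(np.log([1.0 / n for n in ns]), np.log(errs), 1)[0]
        assert 1.7 <= slope <= 2.3

    def test_poiseuille_shear_force_matches_closed_form(self):
        """Viscous drag on the wall: 8 mu L Q / r^2, summed face by face."""
        mu, L, Q, r = 0.004, 0.1, 8.3333e-5, 0.01
        m = assign_poiseuille_fields(
            gen_tube_mesh(r, L, "straight", 96, 96), Q, mu, 13000.0
        )
        f = integrate_force(m)
        exact = 8 * mu * L * Q / r**2  # 2.667e-3 N, axial
        assert np.linalg.norm(f.shear_part) == pytest.approx(exact, rel=5e-3)
        assert f.shear_part[2] > 0  # directed along the flow axis

    def test_linearity_in_fields(self):
        m = gen_tube_mesh(0.02, 90.0, "bend", 24, 24, bend_radius=0.05)
        a = assign_uniform_pressure(m, 8000.0)
        b = assign_poiseuille_like = m.with_fields(
            np.linspace(0.0, 500.0, len(m.faces)),
            np.tile([0.0, 0.0, 2.0], (len(m.faces), 1)),
        )
        summed = m.with_fields(
            a.face_pressure + b.face_pressure, a.face_shear + b.face_shear
        )
        fa, fb, fs = integrate_force(a), integrate_force(b), integrate_force(summed)
        assert np.allclose(
            fs.components, fa.components + fb.components, rtol=1e-12, atol=1e-15
        )

    def test_pressure_dominates_shear_at_physiologic_fields(self):
        """p ~ 1e4 Pa vs tau ~ 5 Pa: viscous part is under 1% of pressure part."""
        m = gen_tube_mesh(0.015, 120.0, "bend", 48, 48, bend_radius=0.04)
        tangents = np.cross([0.0, 0.0, 1.0], m.face_normals)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        fields = m.with_fields(np.full(len(m.faces), 1.2e4), 5.0 * tangents)
        f = integrate_force(fields)
        assert np.linalg.norm(f.shear_part) < 0.01 * np.linalg.norm(f.pressure_part)

    def test_missing_fields_rejected(self):
        m = gen_tube_mesh(0.01, 0.1, "straight", 16, 16)
        with pytest.raises(FieldError):
            integrate_force(m)

    def test_parts_sum_exactly(self):
        f = ForceVector(np.array([1.0, 2.0, 3.0]), np.array([0.1, -0.2, 0.3]))
        assert np.array_equal(f.components, f.pressure_part + f.shear_part)
        assert f.magnitude == pytest.approx(np.linalg.norm(f.components), rel=1e-12)


class TestSystolicPeak:
    def test_unique_maximum(self):
        t = np.linspace(0.0, 1.0, 101)
        p = 80 + 40 * np.exp(-((t - 0.30) ** 2) / 0.005)
        trace = PressureTrace(t, p, np.array([0, 100]))
        assert systolic_peak_time(trace) == pytest.approx(0.30, abs=0.005)

    def test_flat_trace_ties_to_earliest(self):
        t = np.linspace(0.0, 2.0, 201)
        trace = PressureTrace(t, np.full(201, 90.0), np.array([0, 100, 200]))
        assert systolic_peak_time(trace) == pytest.approx(1.0)  # start of last cycle

    def test_peak_in_systolic_third(self, inflow):
        trace = simulate_wk3(WindkesselParams(0.09, 1.2, 0.91), inflow, 6, 500)
        t_peak = systolic_peak_time(trace) - 5 * inflow.period
        assert 0.0 < t_peak <= inflow.period / 3


class TestDirection:
    @pytest.mark.parametrize("vec,label", [
        ((-1.0, 0.0, 1.0), "dorsocranial"),
        ((1.0, 0.0, -1.0), "ventrocaudal"),
        ((1.0, 0.5, 1.0), "ventrocranial"),
        ((-2.0, 0.0, -0.5), "dorsocaudal"),
    ])
    def test_octant_labels(self, vec, label):
        f = ForceVector(np.array(vec), np.zeros(3))
        got, _ = classify_direction(f)
        assert got == label

    def test_zero_vector_has_no_direction(self):
        with pytest.raises(UndefinedDirectionError):
            classify_direction(ForceVector(np.zeros(3), np.zeros(3)))

    def test_boundary_case_flagged(self):
        # within 5 degrees of the x = 0 plane
        f = ForceVector(np.array([0.01, 0.0, 1.0]), np.zeros(3))
        _, boundary = classify_direction(f)
        assert boundary
        f2 = ForceVector(np.array([-1.0, 0.0, 1.0]), np.zeros(3))
        assert not classify_direction(f2)[1]


class TestSurfaceArea:
    def test_cylinder(self):
        m = gen_tube_mesh(0.021, 0.15, "straight", 96, 96)
        assert graft_surface_area(m) == pytest.approx(197.9, rel=1e-3)

    def test_sphere(self):
        s = gen_closed_sphere(0.05, refinement=4)
        assert graft_surface_area(s) == pytest.approx(314.2, rel=2e-3)

    def test_empty_mesh_warns(self):
        empty = TriSurface(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.warns(UserWarning):
            assert graft_surface_area(empty) == 0.0
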