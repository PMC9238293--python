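"""Solver correctness: stencil, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermassage.anatomy import (
    AnatomyVolume,
    TissueLayerSpec,
    build_layered_anatomy,
    property_table,
    surface_condition_masks,
)
from thermassage.bioheat import (
    SteadySolveOptions,
    ThermalBoundarySpec,
    analytic_slab_1d,
    assemble_steady_system,
    baseline_field,
    manufactured_solution_check,
    solve_steady,
)

PROPS = property_table()


def column_volume(tissue, depth_mm, spacing_mm):
    """Single-voxel-wide 1D column along depth."""
    return build_layered_anatomy([TissueLayerSpec(tissue, depth_mm)],
                                 spacing_mm, spacing_mm, depth_mm, spacing_mm)


def solve_column(tissue, depth_mm, spacing_mm, t_surface, t_cut, rtol=1e-10):
    vol = column_volume(tissue, depth_mm, spacing_mm)
    surf = surface_condition_masks(vol, None, mat_temperature_C=t_surface)
    bcs = ThermalBoundarySpec(surface=surf, cut_temperature_C=t_cut,
                              lateral_mode="adiabatic")
    system = assemble_steady_system(vol, PROPS, bcs)
    return vol, solve_steady(system, SteadySolveOptions(rtol=rtol))


class TestAssembly:
    def test_harmonic_mean_face_conductivity(self):
        # two-voxel 1D skin|muscle system at 1 mm spacing
        vol = build_layered_anatomy(
            [TissueLayerSpec("skin", 1.0), TissueLayerSpec("muscle", 1.0)],
            1.0, 1.0, 2.0, 1.0)
        surf = surface_condition_masks(vol, None, 40.0)
        system = assemble_steady_system(
            vol, PROPS, ThermalBoundarySpec(surface=surf, lateral_mode="adiabatic"))
        k1, k2 = 0.37, 0.47
        expected = 2 * k1 * k2 / (k1 + k2) * 1e-3  # kf * A / d = kf * s
        assert system.A[0, 1] == pytest.approx(-expected)
        assert system.A[1, 0] == pytest.approx(-expected)

    def test_matrix_symmetric(self, coarse_scene):
        A = coarse_scene["system"].A
        assert abs(A - A.T).max() == 0.0

    def test_unregistered_label_rejected(self):
        vol = build_layered_anatomy([TissueLayerSpec("muscle", 10.0)],
                                    10, 10, 10, 2.0)
        partial = {k: v for k, v in PROPS.items() if k != "muscle"}
        with pytest.raises(KeyError):
            assemble_steady_system(vol, partial, ThermalBoundarySpec())


class TestTrivialSolutions:
    def test_all_dirichlet_37_without_sources_is_uniform(self):
        # i.v. disc has w_b = 0 and Q_m = 0: pure conduction, constant data
        vol, field = solve_column("i.v. disc", 20.0, 1.0, 37.0, 37.0)
        np.testing.assert_allclose(field.values, 37.0, atol=1e-9)

    def test_baseline_field_uniform_and_congruent(self):
        vol = build_layered_anatomy(spacing_mm=4.0)
        base = baseline_field(vol)
        assert base.dims == vol.dims
        assert (base.values == 37.0).all()
        assert (base.values - baseline_field(vol).values == 0).all()


class TestAnalyticSlab:
    def test_muscle_penetration_length(self):
        p = PROPS["muscle"]
        lam_mm = np.sqrt(p.k / (p.rho_b * p.c_b * p.w_b)) * 1000
        assert lam_mm == pytest.approx(17.6, abs=0.1)

    def test_boundary_values_reproduced(self):
        p = PROPS["muscle"]
        T = analytic_slab_1d(p.k, p.rho_b, p.c_b, p.w_b, p.T_b, p.Q_m,
                             30.0, 45.0, 37.0, np.array([0.0, 30.0]))
        np.testing.assert_allclose(T, [45.0, 37.0], rtol=1e-12)

    def test_particular_solution_is_constant(self):
        p = PROPS["muscle"]
        pv = p.rho_b * p.c_b * p.w_b
        T_p = p.T_b + p.Q_m / pv
        T = analytic_slab_1d(p.k, p.rho_b, p.c_b, p.w_b, p.T_b, p.Q_m,
                             30.0, T_p, T_p, np.linspace(0, 30, 7))
        np.testing.assert_allclose(T, T_p, rtol=1e-12)

    def test_solver_matches_analytic_perfused_slab(self):
        vol, field = solve_column("muscle", 50.0, 0.5, 45.0, 37.0)
        p = PROPS["muscle"]
        exact = analytic_slab_1d(p.k, p.rho_b, p.c_b, p.w_b, p.T_b, p.Q_m,
                                 50.0, 45.0, 37.0, vol.z_centers_mm)
        assert np.max(np.abs(field.values.ravel() - exact)) < 0.05

    def test_solver_matches_conduction_slab(self):
        # w_b = 0 branch: linear profile between the Dirichlet values
        vol, field = solve_column("i.v. disc", 20.0, 0.5, 44.0, 36.0)
        p = PROPS["i.v. disc"]
        exact = analytic_slab_1d(p.k, p.rho_b, p.c_b, p.w_b, p.T_b, p.Q_m,
                                 20.0, 44.0, 36.0, vol.z_centers_mm)
        assert np.max(np.abs(field.values.ravel() - exact)) < 0.01

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            analytic_slab_1d(0.5, 1057, 3600, 4e-4, 36.55, 0, 0.0, 45, 37, [0])


class TestManufacturedSolution:
    def test_convergence_order_and_monotone_errors(self):
        report = manufactured_solution_check()
        assert report["order"] >= 1.8
        errs = report["l2_errors"]
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_constant_field_reproduced_exactly(self):
        # zero source with matching Dirichlet data: solution is the constant
        vol = build_layered_anatomy([TissueLayerSpec("i.v. disc", 16.0)],
                                    16, 16, 16, 2.0)
        system = assemble_steady_system(
            vol, PROPS, ThermalBoundarySpec(),
            dirichlet_field=lambda x, y, z: np.full(np.shape(x), 40.0),
            source_override=np.zeros(vol.dims),
        )
        field = solve_steady(system, SteadySolveOptions(rtol=1e-12))
        np.testing.assert_allclose(field.values, 40.0, atol=1e-8)

    def test_requires_geometric_spacings(self):
        with pytest.raises(ValueError):
            manufactured_solution_check(spacings_mm=(4.0, 2.0))
        with pytest.raises(ValueError):
            manufactured_solution_check(spacings_mm=(4.0, 3.0, 1.0))


TISSUES = st.sampled_from(["skin", "subcutaneous fat", "muscle", "i.v. disc", "CSF"])


class TestInvariants:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        labels=st.lists(TISSUES, min_size=1, max_size=4),
        t_mat=st.floats(38.0, 60.0),
        t_cut=st.floats(30.0, 40.0),
        data=st.data(),
    )
    def test_discrete_maximum_principle(self, labels, t_mat, t_cut, data):
        """With Q_m = 0 the field stays inside the range of boundary data
        and blood temperatures present."""
        names = tuple(dict.fromkeys(labels))
        rng_codes = data.draw(st.lists(
            st.integers(0, len(names) - 1), min_size=5 * 5 * 6, max_size=5 * 5 * 6))
        grid = np.array(rng_codes, dtype=np.int16).reshape(5, 5, 6)
        vol = AnatomyVolume(labels=grid, spacing_mm=2.0, label_names=names)
        surf = surface_condition_masks(vol, None, t_mat)
        bcs = ThermalBoundarySpec(surface=surf, cut_temperature_C=t_cut)
        system = assemble_steady_system(vol, PROPS, bcs,
                                        source_override=np.zeros(vol.dims))
        field = solve_steady(system, SteadySolveOptions(rtol=1e-10))
        bounds = [t_mat, t_cut] + [PROPS[n].T_b for n in names if PROPS[n].w_b > 0]
        assert field.values.min() >= min(bounds) - 1e-6
        assert field.values.max() <= max(bounds) + 1e-6

    def test_monotone_in_actuator_setting(self, coarse_scene):
        t45, t65 = coarse_scene["t45"], coarse_scene["t65"]
        assert (t65.values >= t45.values - 1e-6).all()

    def test_mirror_symmetry_of_field(self, coarse_scene):
        v = coarse_scene["t65"].values
        rtol = 1e-8
        assert np.max(np.abs(v - v[::-1, :, :])) <= 10 * rtol * np.max(np.abs(v))

    def test_depth_decay_under_actuator_monotone(self, coarse_scene):
        """Temperature directly anterior to the actuator centroid decreases
        with depth (exponential-decay regime)."""
        vol, t45 = coarse_scene["volume"], coarse_scene["t45"]
        i = np.argmin(np.abs(vol.x_centers_mm - 60))
        j = np.argmin(np.abs(vol.y_centers_mm - 16))
        line = t45.values[i, j, :]
        heated = line > 37.1  # decay holds until the core/cut plateau
        assert heated[:5].all()
        assert (np.diff(line[heated]) < 0).all()


class TestSolverBehaviour:
    def test_nonconvergence_reports_residual(self, coarse_scene):
        with pytest.raises(RuntimeError, match="relative residual"):
            solve_steady(coarse_scene["system"], SteadySolveOptions(maxiter=2))

    def test_deterministic_resolve(self):
        _, f1 = solve_column("muscle", 20.0, 1.0, 45.0, 37.0)
        _, f2 = solve_column("muscle", 20.0, 1.0, 45.0, 37.0)
        assert np.array_equal(f1.values, f2.values)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            SteadySolveOptions(rtol=0.0)
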