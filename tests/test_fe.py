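"""Finite-element bar tests: mesh, equilibrium, Laplacian, specimen runs."""

import math

import numpy as np
import pytest
from dataclasses import replace

from fatiguesim import (
    LoadProgram,
    MaterialParams,
    StepControls,
    build_bar_mesh,
    discrete_laplacian_f,
    hourglass_profile,
    simulate_material_point,
    simulate_specimen,
    solve_equilibrium,
)
from fatiguesim.fe import project_f_to_nodes

E = 110e9


def uniform_profile(d=5e-3, L=60e-3):
    return hourglass_profile(gauge_diameter=d, end_diameter=d, gauge_length=L, total_length=L, flat_length=0.0)


class TestMeshBuild:
    def test_constant_profile_gives_equal_areas(self):
        mesh = build_bar_mesh(uniform_profile(), 4)
        assert np.allclose(mesh.areas, math.pi * 25e-6 / 4)

    def test_symmetric_profile_gives_symmetric_areas(self):
        mesh = build_bar_mesh(hourglass_profile(), 64)
        assert np.allclose(mesh.areas, mesh.areas[::-1], rtol=1e-12)

    def test_min_area_matches_profile_minimum(self):
        prof = hourglass_profile()
        mesh = build_bar_mesh(prof, 64)
        assert mesh.areas.min() == pytest.approx(prof.min_area, rel=1e-6)

    def test_invalid_element_count_rejected(self):
        with pytest.raises(ValueError):
            build_bar_mesh(hourglass_profile(), 0)


class TestEquilibrium:
    def test_uniform_bar_series_spring(self):
        mesh = build_bar_mesh(uniform_profile(), 8)
        A, L = mesh.areas[0], mesh.length
        u = 1e-5
        _, F = solve_equilibrium(mesh, np.ones(8), u, E)
        assert F == pytest.approx(E * A * u / L, rel=1e-12)

    def test_zero_displacement_zero_reaction(self):
        mesh = build_bar_mesh(hourglass_profile(), 16)
        _, F = solve_equilibrium(mesh, np.ones(16), 0.0, E)
        assert F == pytest.approx(0.0, abs=1e-9)

    def test_mesh_independence_for_homogeneous_state(self):
        u = 2e-5
        F = {}
        for n in (1, 10):
            mesh = build_bar_mesh(uniform_profile(), n)
            _, F[n] = solve_equilibrium(mesh, np.ones(n), u, E)
        assert F[1] == pytest.approx(F[10], rel=1e-10)

    def test_reaction_equals_harmonic_mean_closed_form(self):
        """Assembled reaction matches the series-compliance closed form."""
        rng = np.random.default_rng(7)
        mesh = build_bar_mesh(hourglass_profile(), 32)
        f = rng.uniform(0.05, 1.0, 32)
        u = 3e-5
        _, F = solve_equilibrium(mesh, f, u, E)
        series = u / np.sum(mesh.h / (f * E * mesh.areas))
        assert F == pytest.approx(series, rel=1e-12)

    def test_fully_degraded_bar_diverges(self):
        mesh = build_bar_mesh(uniform_profile(), 4)
        with pytest.raises(FloatingPointError):
            solve_equilibrium(mesh, np.zeros(4), 1e-5, E)


class TestDiscreteLaplacian:
    def test_constant_field_has_zero_laplacian(self):
        mesh = build_bar_mesh(hourglass_profile(), 32)
        assert np.allclose(discrete_laplacian_f(mesh, np.full(33, 0.7)), 0.0, atol=1e-20)

    def test_linear_field_zero_on_uniform_mesh(self):
        mesh = build_bar_mesh(uniform_profile(), 16)
        f = 0.3 + 5.0 * mesh.nodes
        lap = discrete_laplacian_f(mesh, f)
        assert np.allclose(lap[1:-1], 0.0, atol=1e-6)

    def test_quadratic_field_recovers_second_derivative(self):
        mesh = build_bar_mesh(uniform_profile(), 16)
        lap = discrete_laplacian_f(mesh, mesh.nodes**2)
        assert np.allclose(lap[1:-1], 2.0, rtol=1e-9)

    def test_zero_flux_volume_weighted_sum(self):
        """Natural boundary: lumped-volume-weighted Laplacian sums to zero."""
        mesh = build_bar_mesh(hourglass_profile(), 24)
        f = np.random.default_rng(3).uniform(0.1, 1.0, 25)
        lap = discrete_laplacian_f(mesh, f)
        vol = mesh.areas * mesh.h / 2.0
        M = np.zeros(25)
        M[:-1] += vol
        M[1:] += vol
        assert abs(np.sum(M * lap)) < 1e-12 * np.sum(M * np.abs(lap) + 1e-30)

    def test_projection_preserves_constants(self):
        mesh = build_bar_mesh(hourglass_profile(), 16)
        assert np.allclose(project_f_to_nodes(mesh, np.full(16, 0.42)), 0.42)


class TestSpecimenSimulation:
    def test_uniform_bar_reproduces_material_point_life(self, ti64_params):
        """Homogeneous displacement-held bar equals the strain-controlled point."""
        mesh = build_bar_mesh(uniform_profile(), 32)
        load = LoadProgram(sigma_a=350e6, max_cycles=1e7)
        traj, _ = simulate_specimen(mesh, load, ti64_params)
        point = simulate_material_point(
            LoadProgram(sigma_a=350e6, control_mode="strain", max_cycles=1e7), ti64_params
        )
        assert traj.status == point.status == "failed"
        assert traj.n_f == pytest.approx(point.n_f, rel=1e-2)

    def test_failure_localizes_at_the_waist(self, ti64_params, default_mesh):
        load = LoadProgram(sigma_a=450e6, max_cycles=1e7)
        traj, state = simulate_specimen(default_mesh, load, ti64_params)
        assert traj.status == "failed"
        waist = np.flatnonzero(default_mesh.areas == default_mesh.areas.min())
        assert state.damage.argmax() in waist

    def test_sub_threshold_runs_out_with_zero_damage(self, default_mesh):
        q0 = (350e6) ** 2 / (2 * E)
        params = MaterialParams(r_d=2.0 * q0)
        load = LoadProgram(sigma_a=350e6, max_cycles=1e6)
        traj, state = simulate_specimen(default_mesh, load, params)
        assert traj.status == "runout"
        assert np.all(state.damage == 0.0)
        assert traj.N[-1] == 1e6

    def test_mesh_convergence_with_regularization(self, ti64_params):
        """With beta = 0.1 N the lifetime changes <2% from 64 to 128 elements."""
        lives = {}
        for n in (64, 128):
            mesh = build_bar_mesh(hourglass_profile(), n)
            traj, _ = simulate_specimen(mesh, LoadProgram(sigma_a=350e6, max_cycles=1e7), ti64_params)
            lives[n] = traj.n_f
        assert abs(lives[128] - lives[64]) / lives[64] < 0.02

    def test_regularization_reduces_mesh_sensitivity(self, ti64_params):
        """Paired runs: beta > 0 changes less under refinement than beta = 0."""
        def refinement_change(params):
            lives = []
            for n in (64, 128):
                mesh = build_bar_mesh(hourglass_profile(), n)
                traj, _ = simulate_specimen(mesh, LoadProgram(sigma_a=350e6, max_cycles=1e7), params)
                lives.append(traj.n_f)
            return abs(lives[1] - lives[0]) / lives[0]

        with_beta = refinement_change(ti64_params)
        without_beta = refinement_change(replace(ti64_params, beta_regularization=0.0))
        assert with_beta <= without_beta

    def test_reaction_amplitude_monotone_to_failure_fraction(self, ti64_params, default_mesh):
        load = LoadProgram(sigma_a=400e6, max_cycles=1e7)
        traj, _ = simulate_specimen(default_mesh, load, ti64_params)
        r = np.abs(traj.reaction)
        assert traj.status == "failed"
        # terminal record sits essentially at the 10% criterion
        assert r[-1] / r[0] == pytest.approx(0.1, abs=0.02)

    def test_stress_controlled_mode_runs_away_faster(self, ti64_params, default_mesh):
        held = simulate_specimen(default_mesh, LoadProgram(sigma_a=400e6, max_cycles=1e7), ti64_params)[0]
        stress = simulate_specimen(
            default_mesh, LoadProgram(sigma_a=400e6, control_mode="stress", max_cycles=1e7), ti64_params
        )[0]
        assert stress.status == "failed"
        assert stress.n_f < held.n_f
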