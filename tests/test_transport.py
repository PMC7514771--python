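import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from detomo.benchmarks import forward_convergence_1d
from detomo.media import DiskMedia2D, Media1D, make_example_media, three_bump_medium
from detomo.transport import (
    C_D,
    InflowData,
    PhaseGrid,
    PhaseSolution,
    apply_collision,
    assemble_rte,
    boundary_current,
    boundary_nodes,
    density,
    inflow_mask,
    solve_rte,
)


class TestCollisionOperator:
    def test_annihilates_constants(self):
        w = np.full(16, 1 / 16)
        np.testing.assert_allclose(apply_collision(np.full(16, 3.0), w), 0.0, atol=1e-15)

    def test_odd_symmetry_of_cosine(self):
        grid = PhaseGrid.unit_interval()
        f = np.cos(grid.theta)
        np.testing.assert_allclose(apply_collision(f, grid.weights), -f, atol=1e-14)

    def test_matches_explicit_loop(self, rng):
        w = np.full(16, 1 / 16)
        f = rng.standard_normal(16)
        avg = sum(wi * fi for wi, fi in zip(w, f))  # brute-force loop oracle
        expected = np.array([avg - fi for fi in f])
        np.testing.assert_allclose(apply_collision(f, w), expected, rtol=1e-13)

    @given(f=arrays(np.float64, 12, elements=st.floats(-1e3, 1e3)))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, f):
        w = np.full(12, 1 / 12)
        assert abs(np.sum(w * apply_collision(f, w))) < 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_collision(np.ones(8), np.full(4, 0.25))


class TestGridConstruction:
    def test_benchmark_slab_system_size(self, slab_grid):
        # 21 nodes x 16 directions
        system = assemble_rte(
            slab_grid, three_bump_medium(), 1.0, InflowData.constant(slab_grid, 0.0)
        )
        assert system.matrix.shape == (336, 336)

    def test_no_vanishing_direction_components(self, square_grid):
        assert np.all(np.abs(np.cos(square_grid.theta)) > 1e-12)
        assert np.all(np.abs(np.sin(square_grid.theta)) > 1e-12)

    def test_boundary_enumeration_counts(self, slab_grid, square_grid):
        assert len(boundary_nodes(slab_grid)) == 2
        assert len(boundary_nodes(square_grid)) == 80  # corners once

    def test_nonpositive_epsilon_rejected(self, slab_grid):
        with pytest.raises(ValueError, match="epsilon"):
            assemble_rte(slab_grid, three_bump_medium(), 0.0, InflowData.constant(slab_grid, 0.0))


class TestConstantPreservation:
    @pytest.mark.parametrize("epsilon", [1.0, 2**-3, 2**-6])
    def test_slab_constant_inflow(self, slab_grid, epsilon):
        inflow = InflowData.constant(slab_grid, 2.5)
        sol = solve_rte(assemble_rte(slab_grid, three_bump_medium(), epsilon, inflow))
        np.testing.assert_allclose(sol.f, 2.5, atol=1e-9)
        np.testing.assert_allclose(density(sol), 2.5, atol=1e-9)

    def test_square_constant_inflow(self, coarse_square_grid):
        media = make_example_media(1, [0.4, 10.0])
        inflow = InflowData.constant(coarse_square_grid, 1.0)
        sol = solve_rte(assemble_rte(coarse_square_grid, media, 2**-3, inflow))
        np.testing.assert_allclose(sol.f, 1.0, atol=1e-9)


def dense_oracle_1d(grid, sigma, epsilon, inflow_values):
    """Loop-assembled dense system for the 1-D slab, solved with lapack."""
    nx, nv = grid.n_x, grid.n_angles
    ct = np.cos(grid.theta)
    A = np.zeros((nx * nv, nx * nv))
    b = np.zeros(nx * nv)
    for i in range(nx):
        for m in range(nv):
            r = i * nv + m
            if (ct[m] > 0 and i == 0) or (ct[m] < 0 and i == nx - 1):
                A[r, r] = 1.0
                b[r] = inflow_values[i, m]
                continue
            up = i - 1 if ct[m] > 0 else i + 1
            A[r, r] += abs(ct[m]) / grid.dx
            A[r, up * nv + m] -= abs(ct[m]) / grid.dx
            s = sigma[i] / epsilon
            A[r, r] += s
            for mp in range(nv):
                A[r, i * nv + mp] -= s * grid.weights[mp]
    return np.linalg.solve(A, b).reshape(nx, nv)


def dense_oracle_2d(grid, sigma_flat, epsilon, inflow_values):
    """Loop-assembled dense system on the unit square."""
    nx, ny, nv = grid.n_x, grid.n_y, grid.n_angles
    ct, st_ = np.cos(grid.theta), np.sin(grid.theta)
    n = nx * ny * nv
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(nx):
        for j in range(ny):
            for m in range(nv):
                r = (i * ny + j) * nv + m
                incoming = (
                    (ct[m] > 0 and i == 0)
                    or (ct[m] < 0 and i == nx - 1)
                    or (st_[m] > 0 and j == 0)
                    or (st_[m] < 0 and j == ny - 1)
                )
                if incoming:
                    A[r, r] = 1.0
                    b[r] = inflow_values[i * ny + j, m]
                    continue
                ui = i - 1 if ct[m] > 0 else i + 1
                A[r, r] += abs(ct[m]) / grid.dx
                A[r, (ui * ny + j) * nv + m] -= abs(ct[m]) / grid.dx
                uj = j - 1 if st_[m] > 0 else j + 1
                A[r, r] += abs(st_[m]) / grid.dx
                A[r, (i * ny + uj) * nv + m] -= abs(st_[m]) / grid.dx
                s = sigma_flat[i * ny + j] / epsilon
                A[r, r] += s
                for mp in range(nv):
                    A[r, (i * ny + j) * nv + mp] -= s * grid.weights[mp]
    return np.linalg.solve(A, b).reshape(nx, ny, nv)


class TestAgainstDenseOracle:
    def test_small_slab_matches_dense_solve(self, rng):
        grid = PhaseGrid.unit_interval(dx=0.25, n_angles=4)
        media = Media1D(baseline=1.0, bumps=((0.3, 0.8, 4.0),))
        sigma = grid.sigma_on_grid(media)
        inflow_values = rng.uniform(0, 2, size=(grid.n_space, grid.n_angles))
        inflow = InflowData(inflow_values, grid)
        sol = solve_rte(assemble_rte(grid, media, 0.5, inflow))
        expected = dense_oracle_1d(grid, sigma, 0.5, inflow_values)
        np.testing.assert_allclose(sol.f, expected, atol=1e-10)

    def test_small_square_matches_dense_solve(self, rng):
        grid = PhaseGrid.unit_square(dx=0.5, n_angles=4)
        media = DiskMedia2D(baseline=2.0, disks=((0.5, 0.5, 0.3, 3.0),))
        sigma = grid.sigma_on_grid(media)
        inflow_values = rng.uniform(0, 1, size=(grid.n_space, grid.n_angles))
        inflow = InflowData(inflow_values, grid)
        sol = solve_rte(assemble_rte(grid, media, 0.25, inflow))
        expected = dense_oracle_2d(grid, sigma, 0.25, inflow_values)
        np.testing.assert_allclose(sol.f, expected, atol=1e-10)

    def test_gmres_backend_matches_direct(self, rng):
        grid = PhaseGrid.unit_interval(dx=0.1, n_angles=8)
        media = three_bump_medium()
        inflow = InflowData.isotropic(grid, {0: 1.0})
        system = assemble_rte(grid, media, 2**-2, inflow)
        direct = solve_rte(system, method="direct")
        gmres = solve_rte(system, method="gmres")
        np.testing.assert_allclose(gmres.f, direct.f, atol=1e-8)


class TestMaximumPrinciple:
    def test_solution_bounded_by_inflow_range(self, rng):
        # upwinding with pure scattering admits no interior extrema
        for _ in range(20):
            dx = rng.choice([0.25, 0.2])
            grid = PhaseGrid.unit_interval(dx=dx, n_angles=8)
            a, b = sorted(rng.uniform(0, 1, 2))
            media = Media1D(baseline=rng.uniform(0.5, 2), bumps=((a, b, rng.uniform(0, 10)),))
            vals = rng.uniform(0, 5, size=(grid.n_space, grid.n_angles))
            inflow = InflowData(vals, grid)
            sol = solve_rte(assemble_rte(grid, media, rng.uniform(0.05, 1), inflow))
            mask = inflow_mask(grid)
            lo, hi = vals[mask].min(), vals[mask].max()
            assert sol.f.min() >= lo - 1e-9
            assert sol.f.max() <= hi + 1e-9


class TestBoundaryCurrent:
    def test_isotropic_field_has_zero_net_current(self, slab_grid):
        inflow = InflowData.constant(slab_grid, 2.0)
        sol = solve_rte(assemble_rte(slab_grid, three_bump_medium(), 1.0, inflow))
        np.testing.assert_allclose(boundary_current(sol), 0.0, atol=1e-8)

    def test_half_vacuum_current_matches_quadrature(self, slab_grid):
        # f = c on outgoing directions, 0 on incoming, at the left node
        c, eps = 3.0, 0.5
        f = np.full((slab_grid.n_x, slab_grid.n_angles), c)
        ct = np.cos(slab_grid.theta)
        f[0, ct > 0] = 0.0  # incoming at x=0 replaced by vacuum
        sol = PhaseSolution(f=f, grid=slab_grid, epsilon=eps)
        # independent quadrature of the outgoing half-moment of cos(theta)
        half_moment = sum(
            w * (-ct_m) * c for w, ct_m in zip(slab_grid.weights, ct) if ct_m < 0
        )
        expected_left = half_moment / (C_D * eps)  # v.n = -cos at the left node
        h = boundary_current(sol)
        np.testing.assert_allclose(h[0], expected_left, rtol=1e-12)
        # the 16-point rule approximates the exact half-moment 1/pi
        assert abs(half_moment - c / np.pi) < 0.01

    def test_outgoing_only_variant_keeps_density_term(self, slab_grid):
        inflow = InflowData.constant(slab_grid, 2.0)
        sol = solve_rte(assemble_rte(slab_grid, three_bump_medium(), 1.0, inflow))
        h_half = boundary_current(sol, outgoing_only=True)
        assert np.all(h_half > 1.0)  # O(rho/eps), not the vanishing net current


class TestDiffusionLimit:
    def test_error_ladder_decreases_monotonically(self):
        errors, _, _, _ = forward_convergence_1d()
        vals = list(errors.values())
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_density_flattens_in_velocity(self, slab_grid):
        inflow = InflowData.isotropic(slab_grid, {0: 1.0})
        spreads = []
        for eps in (1.0, 2**-6):
            sol = solve_rte(assemble_rte(slab_grid, three_bump_medium(), eps, inflow))
            spreads.append(np.ptp(sol.f[10]))  # direction spread at mid-domain
        assert spreads[1] < 0.1 * spreads[0]

    def test_boundary_current_approaches_dtn_flux_under_refinement(self):
        # upwinding carries O(sigma dx / eps) numerical diffusion, so the
        # current converges to the DtN flux as the mesh refines at fixed eps
        from detomo.diffusion import DirichletData, dtn_flux, solve_de

        media = three_bump_medium()
        eps = 2**-3
        gaps = []
        for dx in (0.1, 0.05, 0.025):
            grid = PhaseGrid.unit_interval(dx=dx, n_angles=16)
            h_de = dtn_flux(solve_de(grid, media, DirichletData.from_pair(grid, 1.0, 0.0)))
            inflow = InflowData.isotropic(grid, {0: 1.0})
            sol = solve_rte(assemble_rte(grid, media, eps, inflow))
            gaps.append(abs(boundary_current(sol)[1] - h_de[1]))  # right boundary
        assert gaps[0] > gaps[1] > gaps[2]


class TestDeterminism:
    def test_repeated_solves_are_bitwise_identical(self, slab_grid):
        inflow = InflowData.isotropic(slab_grid, {0: 1.0})
        sys1 = assemble_rte(slab_grid, three_bump_medium(), 2**-3, inflow)
        sys2 = assemble_rte(slab_grid, three_bump_medium(), 2**-3, inflow)
        f1 = solve_rte(sys1).f
        f2 = solve_rte(sys2).f
        assert np.array_equal(f1, f2)
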