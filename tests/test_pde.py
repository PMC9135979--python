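"""Discretized reaction-diffusion dynamics: stencil, operator G, Euler stepping."""

import numpy as np
import pytest

from petpde import (
    Grid2D,
    LAPLACIAN_STENCIL,
    Quantity,
    ReactionDiffusionParams,
    ScalarField2D,
    discrete_laplacian,
    diffusion_proliferation,
    euler_step,
    linear_kill_response,
    saturating_kill_response,
    simulate_forward,
)
from petpde.pde import ZERO_RESPONSE, discrete_laplacian_adjoint


class TestStencil:
    def test_unit_impulse_reproduces_stencil_coefficients(self):
        U = np.zeros((5, 5))
        U[2, 2] = 1.0
        L = discrete_laplacian(U)
        assert L[2, 2] == -3.0
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            assert L[2 + di, 2 + dj] == 0.5
        for di in (-1, 1):
            for dj in (-1, 1):
                assert L[2 + di, 2 + dj] == 0.25

    def test_coefficients_sum_to_zero_and_symmetric(self):
        assert LAPLACIAN_STENCIL.sum() == 0.0
        assert np.array_equal(LAPLACIAN_STENCIL, LAPLACIAN_STENCIL.T)
        assert np.array_equal(LAPLACIAN_STENCIL, np.rot90(LAPLACIAN_STENCIL))

    @pytest.mark.parametrize("boundary", ["replicate", "periodic", "zero"])
    def test_constant_field_maps_to_zero_interior(self, boundary):
        L = discrete_laplacian(np.full((5, 5), 7.0), boundary)
        if boundary == "zero":
            # zero padding breaks constancy only at the border
            assert np.allclose(L[1:-1, 1:-1], 0.0, atol=1e-12)
        else:
            assert np.allclose(L, 0.0, atol=1e-12)

    def test_affine_fields_annihilated_in_interior(self):
        r, c = np.meshgrid(np.arange(7), np.arange(9), indexing="ij")
        for U in (c.astype(float), r.astype(float), 2.0 + 3.0 * r - 5.0 * c):
            L = discrete_laplacian(U)
            # direct summation oracle on an interior pixel
            i, j = 3, 4
            manual = sum(
                LAPLACIAN_STENCIL[di + 1, dj + 1] * U[i + di, j + dj]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
            )
            assert np.allclose(L[1:-1, 1:-1], 0.0, atol=1e-10)
            assert L[i, j] == pytest.approx(manual, abs=1e-12)

    def test_too_small_field_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            discrete_laplacian(np.ones((2, 5)))

    @pytest.mark.parametrize("boundary", ["replicate", "periodic", "zero"])
    def test_adjoint_matches_inner_product_identity(self, boundary, rng):
        # <L u, v> == <u, L* v> for arbitrary fields
        u = rng.normal(size=(6, 7))
        v = rng.normal(size=(6, 7))
        lhs = np.sum(discrete_laplacian(u, boundary) * v)
        rhs = np.sum(u * discrete_laplacian_adjoint(v, boundary))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestDiffusionProliferation:
    def test_pure_proliferation_scales_field(self):
        params = ReactionDiffusionParams(alpha=0.0, beta=2.0)
        out = diffusion_proliferation(np.ones((4, 4)), params)
        assert np.array_equal(out, np.full((4, 4), 2.0))

    def test_constant_field_reduces_to_beta_scaling(self):
        params = ReactionDiffusionParams(alpha=0.7, beta=-0.3)
        out = diffusion_proliferation(np.full((5, 5), 4.0), params)
        assert np.allclose(out, -1.2, atol=1e-12)

    def test_unit_alpha_impulse_recovers_stencil(self):
        U = np.zeros((5, 5))
        U[2, 2] = 1.0
        params = ReactionDiffusionParams(alpha=1.0, beta=0.0)
        out = diffusion_proliferation(U, params)
        assert np.allclose(out[1:4, 1:4], LAPLACIAN_STENCIL)


class TestEulerStep:
    def test_identity_dynamics(self):
        params = ReactionDiffusionParams(alpha=0.0, beta=0.0)
        U = np.arange(16.0).reshape(4, 4)
        out = euler_step(U, np.ones_like(U), params, ZERO_RESPONSE)
        assert np.array_equal(out, U)

    def test_constant_proliferation_closed_form(self):
        params = ReactionDiffusionParams(alpha=0.3, beta=1.0, n_steps=4, total_time=1.0)
        out = euler_step(np.full((4, 4), 2.0), np.zeros((4, 4)), params)
        assert np.allclose(out, 2.5, atol=1e-14)  # c * (1 + h*beta)

    def test_linear_kill_closed_form(self):
        # u <- c (1 - h*gamma*d) for constant fields, beta = 0
        params = ReactionDiffusionParams(alpha=0.0, beta=0.0, n_steps=4, total_time=1.0)
        out = euler_step(
            np.full((4, 4), 3.0), np.full((4, 4), 2.0), params, linear_kill_response(1.0)
        )
        assert np.allclose(out, 3.0 * (1 - 0.25 * 2.0), atol=1e-14)

    def test_shape_mismatch_rejected(self):
        params = ReactionDiffusionParams()
        with pytest.raises(ValueError, match="shape"):
            euler_step(np.ones((4, 4)), np.ones((4, 5)), params)

    def test_linear_in_state_for_linear_response(self, rng):
        params = ReactionDiffusionParams(alpha=0.1, beta=0.4, n_steps=4, total_time=1.0)
        F = linear_kill_response(0.5)
        D = rng.uniform(0, 1, (6, 6))
        U1, U2 = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        a, b = 1.7, -0.6
        lhs = euler_step(a * U1 + b * U2, D, params, F)
        rhs = a * euler_step(U1, D, params, F) + b * euler_step(U2, D, params, F)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


class TestSimulateForward:
    def test_pure_proliferation_compounds_to_closed_form(self, grid8):
        U0 = ScalarField2D(grid8, np.ones(grid8.shape), Quantity.SUV)
        D = ScalarField2D(grid8, np.zeros(grid8.shape), Quantity.DOSE_GY)
        params = ReactionDiffusionParams(alpha=0.0, beta=1.0, n_steps=4, total_time=1.0)
        traj = simulate_forward(U0, D, params)
        assert np.allclose(traj.final.values, 1.25**4, rtol=1e-15)
        assert traj.final.values[0, 0] == 2.44140625

    def test_trajectory_has_n_steps_plus_one_frames(self, grid8, rng):
        U0 = ScalarField2D(grid8, rng.uniform(0, 2, grid8.shape), Quantity.SUV)
        D = ScalarField2D(grid8, rng.uniform(0, 20, grid8.shape), Quantity.DOSE_GY)
        params = ReactionDiffusionParams(alpha=0.05, beta=-0.1, n_steps=6, total_time=1.0)
        traj = simulate_forward(U0, D, params, linear_kill_response(0.2))
        assert len(traj.frames) == 7
        assert traj.times == pytest.approx([i / 6 for i in range(7)])
        assert np.array_equal(traj.frames[0].values, U0.values)

    def test_periodic_diffusion_conserves_total_intensity(self, rng):
        grid = Grid2D(12, 12, 1.0, 1.0)
        U0 = ScalarField2D(grid, rng.uniform(0, 3, grid.shape), Quantity.SUV)
        D = ScalarField2D(grid, np.zeros(grid.shape), Quantity.DOSE_GY)
        params = ReactionDiffusionParams(
            alpha=0.2, beta=0.0, n_steps=8, total_time=1.0, boundary="periodic"
        )
        traj = simulate_forward(U0, D, params)
        total0 = U0.values.sum()
        for f in traj.frames:
            assert f.values.sum() == pytest.approx(total0, rel=1e-10)

    def test_stable_diffusion_obeys_extremum_principle(self, rng):
        # with h*alpha <= 1/3 all update weights are nonnegative
        grid = Grid2D(10, 10, 1.0, 1.0)
        U0 = ScalarField2D(grid, rng.uniform(0, 5, grid.shape), Quantity.SUV)
        D = ScalarField2D(grid, np.zeros(grid.shape), Quantity.DOSE_GY)
        params = ReactionDiffusionParams(
            alpha=0.3, beta=0.0, n_steps=10, total_time=1.0, boundary="periodic"
        )
        traj = simulate_forward(U0, D, params)
        maxes = [f.values.max() for f in traj.frames]
        mins = [f.values.min() for f in traj.frames]
        assert all(m2 <= m1 + 1e-12 for m1, m2 in zip(maxes, maxes[1:]))
        assert all(m2 >= m1 - 1e-12 for m1, m2 in zip(mins, mins[1:]))

    def test_euler_error_shrinks_at_first_order(self):
        # scalar proliferation: |(1 + bT/n)^n - e^(bT)| = O(h)
        beta, T = 1.0, 1.0
        grid = Grid2D(4, 4, 1.0, 1.0)
        U0 = ScalarField2D(grid, np.ones(grid.shape), Quantity.SUV)
        D = ScalarField2D(grid, np.zeros(grid.shape), Quantity.DOSE_GY)
        errors = []
        for n in (4, 8, 16, 32, 64):
            params = ReactionDiffusionParams(alpha=0.0, beta=beta, n_steps=n, total_time=T)
            traj = simulate_forward(U0, D, params)
            errors.append(abs(traj.final.values[0, 0] - np.exp(beta * T)))
        orders = [np.log2(e1 / e2) for e1, e2 in zip(errors, errors[1:])]
        assert all(0.8 < o < 1.2 for o in orders)

    def test_matches_bruteforce_pixel_loop(self, rng):
        """Independent oracle: explicit per-pixel stencil summation on 4x4."""
        grid = Grid2D(4, 4, 1.0, 1.0)
        U0v = rng.uniform(0, 2, (4, 4))
        Dv = rng.uniform(0, 20, (4, 4))
        params = ReactionDiffusionParams(alpha=0.04, beta=-0.2, n_steps=3, total_time=1.0)
        gamma = 0.3
        h = params.h
        S = np.array([[0.25, 0.5, 0.25], [0.5, -3.0, 0.5], [0.25, 0.5, 0.25]])

        U = U0v.copy()
        for _ in range(params.n_steps):
            lap = np.zeros_like(U)
            for i in range(4):
                for j in range(4):
                    acc = 0.0
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii = min(max(i + di, 0), 3)  # replicate boundary
                            jj = min(max(j + dj, 0), 3)
                            acc += S[di + 1, dj + 1] * U[ii, jj]
                    lap[i, j] = acc
            U = U + h * (params.alpha * lap + params.beta * U) + h * (-gamma * Dv * U)

        traj = simulate_forward(
            ScalarField2D(grid, U0v, Quantity.SUV),
            ScalarField2D(grid, Dv, Quantity.DOSE_GY),
            params,
            linear_kill_response(gamma),
        )
        assert np.allclose(traj.final.values, U, rtol=1e-12, atol=1e-12)

    def test_divergence_raises_named_step(self, grid8):
        U0 = ScalarField2D(grid8, np.full(grid8.shape, 1e300), Quantity.SUV)
        D = ScalarField2D(grid8, np.zeros(grid8.shape), Quantity.DOSE_GY)
        params = ReactionDiffusionParams(alpha=0.0, beta=1e10, n_steps=4, total_time=1.0)
        with pytest.raises(FloatingPointError, match="step"):
            simulate_forward(U0, D, params)


class TestResponseOperators:
    def test_linear_kill(self):
        assert np.array_equal(linear_kill_response(0.0)(np.ones((3, 3))), np.zeros((3, 3)))
        out = linear_kill_response(1.0)(np.full((3, 3), 2.0))
        assert np.array_equal(out, np.full((3, 3), -2.0))

    def test_saturating_kill_half_point_and_bound(self):
        F = saturating_kill_response(1.0, psi_half=4.0)
        assert np.array_equal(F(np.zeros((3, 3))), np.zeros((3, 3)))
        assert np.allclose(F(np.full((3, 3), 4.0)), -2.0)  # -psi_half/2
        psi = np.logspace(0, 6, 20).reshape(4, 5)
        assert np.all(np.abs(F(psi)) <= 1.0 * 4.0)

    def test_scalar_recurrence_oracle(self, grid8):
        # constant fields reduce the PDE to u <- u (1 + h*beta - h*gamma*d)
        gamma, beta, d, u0 = 0.5, 0.2, 3.0, 2.0
        params = ReactionDiffusionParams(alpha=0.9, beta=beta, n_steps=5, total_time=1.0)
        U0 = ScalarField2D(grid8, np.full(grid8.shape, u0), Quantity.SUV)
        D = ScalarField2D(grid8, np.full(grid8.shape, d), Quantity.DOSE_GY)
        traj = simulate_forward(U0, D, params, linear_kill_response(gamma))
        u = u0
        for _ in range(5):
            u = u * (1 + params.h * beta - params.h * gamma * d)
        assert np.allclose(traj.final.values, u, rtol=1e-12)


class TestParams:
    def test_stability_warning_when_h_alpha_large(self):
        with pytest.warns(UserWarning, match="stability"):
            ReactionDiffusionParams(alpha=2.0, beta=0.0, n_steps=4, total_time=1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ReactionDiffusionParams(alpha=-0.1)
        with pytest.raises(ValueError):
            ReactionDiffusionParams(n_steps=0)
        with pytest.raises(ValueError):
            ReactionDiffusionParams(total_time=0.0)

    def test_step_size(self):
        assert ReactionDiffusionParams(n_steps=4, total_time=1.0).h == 0.25
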