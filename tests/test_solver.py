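"""Split Bregman solver: shrinkage proximal maps, fidelity calculus,
Newton updates, Bregman recurrences, energy, and end-to-end behavior."""

from dataclasses import replace

import numpy as np
import pytest

import riciantv as rtv
from riciantv import diffops, solver
from riciantv.rician import log_i0
from riciantv.weightmap import WeightParams


def fid_phi(u, f, sigma):
    """Per-pixel convexified Rician fidelity (the function whose calculus
    fidelity_grad/fidelity_hess implement)."""
    s2 = sigma * sigma
    return u * u / (2 * s2) - log_i0(u * f / s2) + (np.sqrt(u) - np.sqrt(f)) ** 2 / sigma


def fid_min_1d(f, sigma, lo=1e-3, hi=400.0):
    """Per-pixel fidelity minimizer by two-stage dense grid search."""
    f = np.atleast_1d(np.asarray(f, dtype=float))
    coarse = np.linspace(lo, hi, 4001)
    vals = fid_phi(coarse[:, None], f[None, :], sigma)
    idx = np.argmin(vals, axis=0)
    centers = coarse[idx]
    offsets = np.linspace(-0.15, 0.15, 301)
    fine = np.maximum(centers[None, :] + offsets[:, None], lo)
    vals = fid_phi(fine, f[None, :], sigma)
    return fine[np.argmin(vals, axis=0), np.arange(f.size)]


def prox_grid_2d(qx, qy, alpha, theta, final_res=0.002):
    """Hierarchical brute-force minimizer of alpha|d| + theta/2 |d - q|^2."""
    cx, cy = qx, qy
    span = np.hypot(qx, qy) + alpha / theta + 0.5
    while True:
        ax = np.linspace(cx - span, cx + span, 41)
        ay = np.linspace(cy - span, cy + span, 41)
        DX, DY = np.meshgrid(ax, ay, indexing="ij")
        F = alpha * np.hypot(DX, DY) + theta / 2 * ((DX - qx) ** 2 + (DY - qy) ** 2)
        i, j = np.unravel_index(np.argmin(F), F.shape)
        cx, cy = ax[i], ay[j]
        res = span / 20
        if res <= final_res:
            return cx, cy
        span = 3 * res


def prox_grid_4d(q, beta, theta, final_res=0.002):
    """Hierarchical brute-force minimizer of beta|z|_F + theta/2 |z - q|^2."""
    c = np.array(q, dtype=float)
    span = np.linalg.norm(q) + beta / theta + 0.5
    while True:
        axes = [np.linspace(ci - span, ci + span, 9) for ci in c]
        grids = np.meshgrid(*axes, indexing="ij")
        Z = np.stack([g.ravel() for g in grids], axis=1)
        F = beta * np.linalg.norm(Z, axis=1) \
            + theta / 2 * np.sum((Z - np.array(q)) ** 2, axis=1)
        c = Z[np.argmin(F)]
        res = span / 4
        if res <= final_res:
            return c
        span = 2 * res


class TestShrinkVector:
    def test_three_four_shrinks_to_three_fifths(self):
        d = solver.shrink_vector((np.array([[3.0]]), np.array([[4.0]])), 10.0, 5.0)
        np.testing.assert_allclose(d[0], 1.8)
        np.testing.assert_allclose(d[1], 2.4)

    def test_below_threshold_gives_zero(self):
        d = solver.shrink_vector((np.array([[0.3]]), np.array([[0.4]])), 5.0, 5.0)
        assert d[0] == 0 and d[1] == 0

    def test_zero_input_gives_zero(self):
        z = np.zeros((3, 3))
        d = solver.shrink_vector((z, z), 1.0, 1.0)
        np.testing.assert_array_equal(d[0], 0.0)

    def test_matches_brute_force_prox(self, rng):
        for _ in range(100):
            qx, qy = rng.uniform(-5, 5, size=2)
            alpha = rng.uniform(0, 8)
            theta = rng.uniform(0.5, 10)
            dx, dy = solver.shrink_vector((np.array([[qx]]), np.array([[qy]])),
                                          alpha, theta)
            ox, oy = prox_grid_2d(qx, qy, alpha, theta)
            assert abs(dx[0, 0] - ox) < 0.005 and abs(dy[0, 0] - oy) < 0.005

    def test_perturbation_never_improves_objective(self, rng):
        qx, qy = rng.normal(size=(2, 6, 6))
        alpha, theta = 2.0, 5.0
        dx, dy = solver.shrink_vector((qx, qy), alpha, theta)

        def obj(ax, ay):
            return alpha * np.hypot(ax, ay) + theta / 2 * ((ax - qx) ** 2 + (ay - qy) ** 2)

        base = obj(dx, dy)
        for eps in (0.01, -0.01):
            assert np.all(obj(dx + eps, dy) >= base - 1e-12)
            assert np.all(obj(dx, dy + eps) >= base - 1e-12)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            solver.shrink_vector((np.ones((2, 2)), np.ones((2, 2))), 1.0, 0.0)


class TestShrinkHessian:
    def test_unit_components_shrink_by_half(self):
        q = tuple(np.ones((2, 2)) for _ in range(4))  # Frobenius magnitude 2
        z = solver.shrink_hessian(q, beta=5.0, theta2=5.0)
        for c in z:
            np.testing.assert_allclose(c, 0.5)

    def test_beta_zero_is_identity(self, rng):
        q = tuple(rng.normal(size=(4, 4)) for _ in range(4))
        z = solver.shrink_hessian(q, beta=0.0, theta2=3.0)
        for a, b in zip(z, q):
            np.testing.assert_array_equal(a, b)

    def test_matches_brute_force_prox(self, rng):
        for _ in range(25):
            q = rng.uniform(-3, 3, size=4)
            beta = rng.uniform(0, 5)
            theta = rng.uniform(0.5, 8)
            z = solver.shrink_hessian(tuple(np.array([[v]]) for v in q), beta, theta)
            closed = np.array([c[0, 0] for c in z])
            oracle = prox_grid_4d(q, beta, theta)
            assert np.max(np.abs(closed - oracle)) < 0.005


class TestFidelityCalculus:
    def test_grad_matches_finite_differences(self, rng):
        for _ in range(200):
            u = rng.uniform(1.0, 250.0)
            f = rng.uniform(0.0, 250.0)
            sigma = rng.uniform(3.0, 30.0)
            h = 1e-3 * max(u, 1.0)
            fd = (fid_phi(u + h, f, sigma) - fid_phi(u - h, f, sigma)) / (2 * h)
            g = solver.fidelity_grad(np.array([[u]]), np.array([[f]]), sigma)[0, 0]
            assert g == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_hess_matches_finite_differences_of_grad(self, rng):
        for _ in range(200):
            u = rng.uniform(1.0, 250.0)
            f = rng.uniform(0.0, 250.0)
            sigma = rng.uniform(3.0, 30.0)
            h = 1e-3 * max(u, 1.0)
            gp = solver.fidelity_grad(np.array([[u + h]]), np.array([[f]]), sigma)[0, 0]
            gm = solver.fidelity_grad(np.array([[u - h]]), np.array([[f]]), sigma)[0, 0]
            hess = solver.fidelity_hess(np.array([[u]]), np.array([[f]]), sigma)[0, 0]
            assert hess == pytest.approx((gp - gm) / (2 * h), rel=1e-4, abs=1e-10)

    def test_zero_f_limits(self):
        sigma = 15.0
        u = np.array([[30.0]])
        f = np.array([[0.0]])
        g = solver.fidelity_grad(u, f, sigma)[0, 0]
        assert g == pytest.approx(30.0 / sigma ** 2 + 1.0 / sigma, rel=1e-12)
        h = solver.fidelity_hess(u, f, sigma)[0, 0]
        assert h == pytest.approx(1.0 / sigma ** 2, rel=1e-12)

    @pytest.mark.parametrize("sigma", [5.0, 15.0, 25.0])
    def test_hess_positive_on_grid(self, sigma):
        u = np.linspace(1e-3, 255, 200)
        f = np.linspace(0, 255, 200)
        U, F = np.meshgrid(u, f, indexing="ij")
        H = solver.fidelity_hess(U, F, sigma)
        assert np.all(H > 0)

    def test_grad_vanishes_at_grid_search_minimizer(self, rng):
        sigma = 15.0
        f = rng.uniform(5.0, 250.0, size=20)
        ustar = fid_min_1d(f, sigma)
        g = solver.fidelity_grad(ustar.reshape(4, 5), f.reshape(4, 5), sigma)
        assert np.max(np.abs(g)) < 1e-3

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            solver.fidelity_grad(np.array([[1e-6]]), np.array([[1.0]]), 5.0)


class TestNewton:
    def test_decoupled_newton_reaches_1d_minimizer(self, rng):
        # alpha0 = beta = 0 makes the shrinkage thresholds vanish, the
        # splitting residuals stay identically zero and the u-step reduces
        # to independent per-pixel Newton on the fidelity
        sigma = 15.0
        f = rng.uniform(0.0, 250.0, size=(8, 8))
        params = rtv.SolverParams(sigma=sigma, k_max=40, hess_augment=False,
                                  beta=0.0, weight=WeightParams(alpha0=0.0))
        res = rtv.denoise(f, params)
        ustar = fid_min_1d(f.ravel(), sigma).reshape(8, 8)
        assert np.max(np.abs(res.u_hat - ustar)) < 0.01
        assert np.sqrt(np.mean((res.u_hat - ustar) ** 2)) < 0.5

    def test_single_step_definition_replay(self, noisy_pair_64):
        _, noisy = noisy_pair_64
        params = rtv.SolverParams(sigma=15.0, n_max=1)
        u0 = np.maximum(noisy, params.u_floor)
        alpha = rtv.compute_weight(noisy, params.weight)
        gx, gy = diffops.grad(u0)
        hh = diffops.hessian(u0)
        state = solver.BregmanState(
            u=u0,
            d=solver.shrink_vector((gx, gy), alpha, params.theta1),
            z=solver.shrink_hessian(hh, params.beta, params.theta2),
            b1=(np.zeros_like(u0), np.zeros_like(u0)),
            b2=tuple(np.zeros_like(u0) for _ in range(4)),
            alpha=alpha)
        out = solver.newton_u_step(state, noisy, params)
        # independent per-pixel recomputation of the printed update rule
        e1 = solver.fidelity_grad(u0, noisy, params.sigma) \
            + (params.theta1 * diffops.div((state.d[0] - gx, state.d[1] - gy))
               - params.theta2 * diffops.div2(tuple(zc - hc
                                                    for zc, hc in zip(state.z, hh))))
        e2 = np.maximum(solver.fidelity_hess(u0, noisy, params.sigma)
                        + params.theta1 * 8.0 + params.theta2 * 64.0, 1e-8)
        expected = np.maximum(u0 - e1 / e2, params.u_floor)
        np.testing.assert_array_equal(out, expected)


class TestUpdateBregman:
    def _state(self, u, d=None, z=None):
        shape = u.shape
        zeros2 = (np.zeros(shape), np.zeros(shape))
        zeros4 = tuple(np.zeros(shape) for _ in range(4))
        return solver.BregmanState(u=u, d=d or zeros2, z=z or zeros4,
                                   b1=zeros2, b2=zeros4,
                                   alpha=np.ones(shape))

    def test_zero_residual_leaves_b_unchanged(self, rng):
        u = rng.uniform(1, 100, size=(6, 6))
        st = self._state(u, d=diffops.grad(u), z=diffops.hessian(u))
        out = solver.update_bregman(st)
        for c in (*out.b1, *out.b2):
            np.testing.assert_allclose(c, 0.0, atol=1e-14)

    def test_base_case_and_unrolled_recurrence(self, rng):
        u_list = [rng.uniform(1, 100, size=(5, 5)) for _ in range(5)]
        d_list = [(rng.normal(size=(5, 5)), rng.normal(size=(5, 5)))
                  for _ in range(5)]
        st = self._state(u_list[0], d=d_list[0])
        # first update: b1 = grad(u1) - d1
        st.u, st.d = u_list[0], d_list[0]
        st = solver.update_bregman(st)
        g = diffops.grad(u_list[0])
        np.testing.assert_allclose(st.b1[0], g[0] - d_list[0][0], atol=1e-14)
        # accumulate and compare with direct summation
        for u, d in zip(u_list[1:], d_list[1:]):
            st.u, st.d = u, d
            st = solver.update_bregman(st)
        expx = sum(diffops.grad(u)[0] - d[0] for u, d in zip(u_list, d_list))
        expy = sum(diffops.grad(u)[1] - d[1] for u, d in zip(u_list, d_list))
        np.testing.assert_allclose(st.b1[0], expx, atol=1e-12)
        np.testing.assert_allclose(st.b1[1], expy, atol=1e-12)


class TestEnergy:
    def test_constant_image_closed_form(self):
        sigma, c, shape = 15.0, 80.0, (8, 8)
        params = rtv.SolverParams(sigma=sigma)
        u = np.full(shape, c)
        alpha = np.full(shape, 3.0)
        e = solver.energy(u, u, params, alpha)
        expected = shape[0] * shape[1] * (c * c / (2 * sigma ** 2)
                                          - log_i0(c * c / sigma ** 2))
        assert e == pytest.approx(expected, rel=1e-12)

    def test_pure_fidelity_matches_per_pixel_sum(self, rng):
        sigma = 10.0
        u = rng.uniform(1, 200, size=(7, 7))
        f = rng.uniform(0, 200, size=(7, 7))
        params = rtv.SolverParams(sigma=sigma, beta=0.0,
                                  weight=WeightParams(alpha0=0.0))
        e = solver.energy(u, f, params, np.zeros_like(u))
        assert e == pytest.approx(float(np.sum(fid_phi(u, f, sigma))), rel=1e-12)

    def test_energy_decreases_over_first_iterations(self, noisy_pair_64):
        _, noisy = noisy_pair_64
        params = rtv.SolverParams(sigma=15.0, k_max=10)
        res = rtv.denoise(noisy, params)
        e0 = solver.energy(np.maximum(noisy, params.u_floor), noisy, params,
                           rtv.compute_weight(noisy, params.weight))
        trace = [e0] + res.energy_trace
        assert trace[-1] < trace[0]
        assert sum(b > a for a, b in zip(trace, trace[1:])) <= 2


class TestDenoise:
    def test_deterministic_and_nonnegative(self, noisy_pair_64):
        _, noisy = noisy_pair_64
        params = rtv.SolverParams(sigma=15.0, k_max=15)
        r1 = rtv.denoise(noisy, params)
        r2 = rtv.denoise(noisy, params)
        np.testing.assert_array_equal(r1.u_hat, r2.u_hat)
        assert np.all(r1.u_hat >= 0)
        assert r1.iterations_run == 15

    def test_near_identity_on_clean_input(self, flat_disks_64):
        clean, _, _ = flat_disks_64
        params = rtv.SolverParams(sigma=5.0, beta=0.2, k_max=100,
                                  weight=WeightParams(alpha0=0.5))
        res = rtv.denoise(clean, params)
        rms = np.sqrt(np.mean((res.u_hat - clean) ** 2))
        assert rms < 2.0

    def test_final_weight_lower_on_edges(self, noisy_pair_64, flat_disks_64):
        _, noisy = noisy_pair_64
        _, edge, _ = flat_disks_64
        params = rtv.SolverParams(sigma=15.0, k_max=60)
        res = rtv.denoise(noisy, params)
        assert res.alpha_final[edge].mean() < res.alpha_final[~edge].mean()

    def test_early_stop_tolerance(self, noisy_pair_64):
        _, noisy = noisy_pair_64
        params = rtv.SolverParams(sigma=15.0, k_max=300, tol=1e-3)
        res = rtv.denoise(noisy, params)
        assert res.iterations_run < 300

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rtv.denoise(np.array([[-1.0, 2.0], [3.0, 4.0]]), rtv.SolverParams())


class TestTuneParams:
    def test_single_point_grids(self, noisy_pair_64):
        clean, noisy = noisy_pair_64
        params = rtv.SolverParams(sigma=15.0, k_max=5)
        tuned = rtv.tune_params(noisy, clean, params, [7.0], [3.0])
        assert tuned.weight.alpha0 == 7.0 and tuned.beta == 3.0

    def test_alternating_finds_exhaustive_argmax(self, noisy_pair_64):
        clean, noisy = noisy_pair_64
        params = rtv.SolverParams(sigma=15.0, k_max=40)
        ga, gb = [20.0, 80.0, 320.0], [0.5, 2.0, 8.0]
        tuned = rtv.tune_params(noisy, clean, params, ga, gb)
        best, best_psnr = None, -np.inf
        for a in ga:
            for b in gb:
                p = replace(params, beta=b, weight=WeightParams(alpha0=a,
                                                                kappa=0.8))
                psnr = rtv.psnr(rtv.denoise(noisy, p).u_hat, clean)
                if psnr > best_psnr:
                    best, best_psnr = (a, b), psnr
        assert (tuned.weight.alpha0, tuned.beta) == best

    def test_empty_grid_rejected(self, noisy_pair_64):
        clean, noisy = noisy_pair_64
        with pytest.raises(ValueError):
            rtv.tune_params(noisy, clean, rtv.SolverParams(), [], [1.0])
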