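"""Truncated-ℓ1 objective, gradient, solvers and the constrained oracle."""

import numpy as np
import pytest

from icdrecon.metrics import rlne
from icdrecon.operators import CosupportSet, FiniteDifferenceOperator
from icdrecon.phantoms import piecewise_constant_image, simulate_measurements
from icdrecon.sampling import SamplingMask, adjoint_fourier, forward_fourier, variable_density_mask
from icdrecon.solver import (
    ReconConfig,
    gradient,
    objective,
    oracle_constrained_solve,
    solve_truncated_l1,
)

DIRS4 = ("vertical", "horizontal", "diag_main", "diag_anti")


def full_mask(shape):
    return SamplingMask(np.ones(shape, dtype=bool), "full", {})


def random_mask(shape, m, seed):
    """m sampled k-space cells including DC, uniformly at random."""
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    idx = rng.choice(n - 1, size=m - 1, replace=False) + 1
    arr = np.zeros(n, dtype=bool)
    arr[0] = True
    arr[idx] = True
    return SamplingMask(arr.reshape(shape), "random", {"seed": seed})


class TestObjective:
    def test_zero_at_truth_with_full_mask_and_no_penalty(self):
        image, cs = piecewise_constant_image((8, 8), 3, seed=0)
        mask = full_mask((8, 8))
        y = simulate_measurements(image, mask)
        cfg = ReconConfig(lam=0.0)
        assert objective(image, y, mask, cs, cfg) <= 1e-20

    def test_empty_cosupport_reduces_to_data_term(self, rng):
        mask = variable_density_mask((8, 8), 0.5, seed=1)
        y = rng.normal(size=mask.num_samples) + 1j * rng.normal(size=mask.num_samples)
        x = rng.normal(size=(8, 8))
        cs = CosupportSet.empty(DIRS4, 64)
        cfg = ReconConfig(lam=0.7)
        resid = forward_fourier(x, mask) - y
        assert objective(x, y, mask, cs, cfg) == pytest.approx(
            float(np.vdot(resid, resid).real), rel=1e-12
        )

    def test_matches_dense_matrix_evaluation(self, rng):
        """Brute-force oracle: explicit dense Ω_i matrices on a 4x4 image."""
        op = FiniteDifferenceOperator((4, 4), DIRS4)
        image, cs = piecewise_constant_image((4, 4), 2, seed=5)
        mask = variable_density_mask((4, 4), 0.6, seed=2)
        y = simulate_measurements(image, mask)
        x = rng.normal(size=(4, 4))
        cfg = ReconConfig(lam=0.3, smoothing_mu=1e-12)
        expected = np.linalg.norm(forward_fourier(x, mask) - y) ** 2
        for d in DIRS4:
            coeffs = op.dense_matrix(d) @ x.ravel()
            sel = coeffs[cs.indices[d]]
            expected += cfg.lam * np.sqrt(np.abs(sel) ** 2 + cfg.smoothing_mu).sum()
        assert objective(x, y, mask, cs, cfg) == pytest.approx(expected, rel=1e-12)

    def test_nan_rejected(self):
        mask = full_mask((4, 4))
        y = np.zeros(16, dtype=complex)
        x = np.full((4, 4), np.nan)
        cs = CosupportSet.full(DIRS4, 16)
        with pytest.raises(FloatingPointError):
            objective(x, y, mask, cs, ReconConfig())


class TestGradient:
    def test_central_difference_check(self, rng):
        image, cs = piecewise_constant_image((8, 8), 3, seed=7)
        mask = variable_density_mask((8, 8), 0.6, seed=3)
        y = simulate_measurements(image, mask)
        cfg = ReconConfig(lam=5e-4, use_wavelet=False)
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        g = gradient(x, y, mask, cs, cfg)
        h = 1e-6
        for _ in range(10):
            d = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
            d /= np.linalg.norm(d)
            fd = (
                objective(x + h * d, y, mask, cs, cfg)
                - objective(x - h * d, y, mask, cs, cfg)
            ) / (2 * h)
            an = float(np.vdot(g, d).real)
            assert abs(fd - an) <= 1e-5 * max(1.0, abs(an))

    def test_data_term_gradient_is_analytic(self, rng):
        mask = variable_density_mask((8, 8), 0.5, seed=9)
        y = rng.normal(size=mask.num_samples) + 1j * rng.normal(size=mask.num_samples)
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        cs = CosupportSet.empty(DIRS4, 64)
        g = gradient(x, y, mask, cs, ReconConfig(lam=0.0))
        expected = 2.0 * adjoint_fourier(forward_fourier(x, mask) - y, mask)
        assert np.allclose(g, expected, atol=1e-12)

    def test_stationary_at_global_minimum(self):
        image, cs = piecewise_constant_image((8, 8), 2, seed=1)
        mask = full_mask((8, 8))
        y = simulate_measurements(image, mask)
        g = gradient(image, y, mask, cs, ReconConfig(lam=0.0))
        assert np.linalg.norm(g) <= 1e-8


class TestSolveTruncatedL1:
    @pytest.mark.parametrize("flavor", ["irls", "ncg"])
    def test_full_mask_least_squares_recovers_truth(self, flavor):
        image, cs = piecewise_constant_image((16, 16), 4, seed=2)
        mask = full_mask((16, 16))
        y = simulate_measurements(image, mask)
        cfg = ReconConfig(lam=0.0, solver=flavor)
        x, stats = solve_truncated_l1(y, mask, cs, cfg)
        assert rlne(x, image) <= 1e-8

    @pytest.mark.parametrize("flavor", ["irls", "ncg"])
    def test_objective_trace_non_increasing(self, flavor):
        image, cs = piecewise_constant_image((16, 16), 4, seed=3)
        mask = variable_density_mask((16, 16), 0.6, seed=4)
        y = simulate_measurements(image, mask)
        cfg = ReconConfig(lam=5e-4, solver=flavor)
        _, stats = solve_truncated_l1(y, mask, cs, cfg)
        trace = stats.objective_trace
        assert len(trace) >= 2
        assert all(b <= a * (1 + 1e-9) for a, b in zip(trace, trace[1:]))

    def test_exact_cosupport_matches_oracle(self):
        image, cs = piecewise_constant_image((16, 16), 4, seed=11)
        mask = variable_density_mask((16, 16), 0.6, seed=12)
        y = simulate_measurements(image, mask)
        x_l1, _ = solve_truncated_l1(y, mask, cs, ReconConfig(lam=5e-4))
        x_oracle = oracle_constrained_solve(y, mask, cs)
        assert rlne(x_l1, image) <= 1e-3
        assert rlne(x_l1, x_oracle) <= 1e-2

    def test_penalty_non_increasing_in_lambda(self):
        """Stronger regularization shrinks the cosupport-restricted analysis
        coefficients of the returned solution (regularization path)."""
        op = FiniteDifferenceOperator((8, 8), DIRS4)
        worse = 0
        for seed in range(10):
            image, cs = piecewise_constant_image((8, 8), 3, seed=seed)
            mask = variable_density_mask((8, 8), 0.6, seed=100 + seed)
            y = simulate_measurements(image, mask)

            def penalty_at_solution(lam):
                x, _ = solve_truncated_l1(y, mask, cs, ReconConfig(lam=lam))
                return sum(
                    np.abs(op.apply(x, d)[cs.indices[d]]).sum()
                    for d in DIRS4
                )

            if penalty_at_solution(2e-3) > penalty_at_solution(1e-3) * (1 + 1e-6):
                worse += 1
        assert worse == 0

    def test_ncg_line_search_failure_is_reported_not_raised(self):
        image, cs = piecewise_constant_image((8, 8), 2, seed=4)
        mask = full_mask((8, 8))
        y = simulate_measurements(image, mask)
        # start at the exact minimum: no descent is possible
        cfg = ReconConfig(lam=0.0, solver="ncg", max_cg_iters=5, grad_tol=-1.0)
        x, stats = solve_truncated_l1(y, mask, cs, cfg, x_init=image)
        assert np.allclose(x, image)


class TestOracleConstrainedSolve:
    def test_constant_image_any_mask_with_dc(self):
        image = np.full((8, 8), 0.7)
        cs = CosupportSet.full(DIRS4, 64)
        mask = random_mask((8, 8), 5, seed=0)
        x = oracle_constrained_solve(simulate_measurements(image, mask), mask, cs)
        assert rlne(x, image) <= 1e-10

    def test_size_guard(self):
        mask = full_mask((128, 128))
        cs = CosupportSet.full(DIRS4, 128 * 128)
        with pytest.raises(ValueError, match="refused"):
            oracle_constrained_solve(np.zeros(mask.num_samples), mask, cs)

    @staticmethod
    def _effective_subspace_dim(image_shape, cs):
        """n - rank of the stacked cosupport rows (SVD oracle)."""
        op = FiniteDifferenceOperator(image_shape, cs.directions)
        rows = [
            op.dense_matrix(d)[cs.indices[d]]
            for d in cs.directions
            if cs.indices[d].size
        ]
        mat = np.vstack(rows)
        svals = np.linalg.svd(mat, compute_uv=False)
        return image_shape[0] * image_shape[1] - int((svals > 1e-9).sum())

    def test_recovery_at_the_measurement_bound(self):
        """With exact cosupport, m = dim W_Λ (= n - l_eff) random Fourier
        measurements recover the image in at least 95% of seeded trials."""
        successes = 0
        for seed in range(50):
            image, cs = piecewise_constant_image((16, 16), 4, seed=seed)
            d = self._effective_subspace_dim((16, 16), cs)
            mask = random_mask((16, 16), max(d, 2), seed=1000 + seed)
            y = simulate_measurements(image, mask)
            x = oracle_constrained_solve(y, mask, cs)
            if rlne(x, image) <= 1e-8:
                successes += 1
        assert successes >= 48  # >= 95% of 50

    def test_failure_below_the_measurement_bound(self):
        """m < dim W_Λ leaves a non-trivial null space: recovery fails in
        the majority of trials."""
        failures = 0
        for seed in range(50):
            image, cs = piecewise_constant_image((16, 16), 6, seed=seed)
            d = self._effective_subspace_dim((16, 16), cs)
            m = max(d - 2, 1)
            if m >= d:
                continue
            mask = random_mask((16, 16), max(m, 2), seed=2000 + seed)
            y = simulate_measurements(image, mask)
            x = oracle_constrained_solve(y, mask, cs)
            if rlne(x, image) > 1e-8:
                failures += 1
        assert failures > 25
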