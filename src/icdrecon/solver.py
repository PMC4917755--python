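"""Truncated-ℓ1 reconstruction solvers.

The inner problem of cosupport-aware reconstruction is the unconstrained

.. math::

    \\hat{x} = \\arg\\min_x \\;\\|y - F_u x\\|_2^2
        + \\lambda \\sum_i \\big\\|(\\Omega_i x)_{\\Lambda_i}\\big\\|_1
        \\;(+\\; \\eta_2 \\|\\Psi x\\|_1),

i.e. least-squares data consistency plus an ℓ1 penalty on the analysis
coefficients *restricted to the current cosupport estimate* — a truncated
(weighted) total-variation penalty.  With the cosupport equal to the full
index set this is exactly the ordinary four-direction TV(+wavelet)
reconstruction with no cosupport prior, which is exposed as the comparison
baseline.

The ℓ1 magnitude is smoothed as ``φ(u) = sqrt(|u|² + μ)`` with a tiny ``μ``
so the objective is differentiable.  Two solver flavors are available:

* ``"irls"`` (default) — majorize–minimize iteratively reweighted least
  squares (lagged diffusivity): each sweep majorizes every ``φ`` term by
  the quadratic ``|u|²/(2φ(u_k)) + φ(u_k)/2`` and minimizes the resulting
  least-squares problem by matrix-free linear conjugate gradient with a
  Fourier-diagonal preconditioner (the periodic difference operators and
  the sampled-DFT normal operator are both diagonal in the Fourier basis
  up to the spatially varying weights).  The majorize–minimize property
  guarantees a monotonically non-increasing objective even with truncated
  inner CG, and the reweighting drives cosupport coefficients to zero at an
  asymptotically quadratic rate — vastly faster than first-order steps on
  the nearly-kinked ℓ1 surface.
* ``"ncg"`` — Polak–Ribière nonlinear conjugate gradient with Armijo
  backtracking from a quadratic-model initial step.  All linear maps
  (``F_u``, ``Ω_i``, ``Ψ``) are applied once per search direction, so
  backtracking steps cost only element-wise work.

A direct oracle is also provided: with an exactly known cosupport the image
satisfies the stacked linear system ``[F_u; Ω_Λ] x = [y; 0]`` and can be
recovered (on small grids) as its minimum-norm least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np

from .operators import (
    DIRECTIONS,
    CosupportSet,
    FiniteDifferenceOperator,
    WaveletOperator,
)
from .sampling import SamplingMask, adjoint_fourier, forward_fourier

__all__ = [
    "ReconConfig",
    "SolverStats",
    "objective",
    "gradient",
    "solve_truncated_l1",
    "oracle_constrained_solve",
]


@dataclass
class ReconConfig:
    """Parameters of the truncated-ℓ1 reconstruction problem and its solver.

    ``lam`` is the regularization weight λ balancing data consistency
    against the truncated analysis-ℓ1 penalty.  When ``use_wavelet`` is on,
    ``eta1`` replaces λ as the analysis weight and ``eta2`` weights the
    additional wavelet-ℓ1 term (defaults: ``eta1 = lam``, ``eta2 = lam/2``).
    ``smoothing_mu`` is the ℓ1 smoothing constant μ in
    ``φ(u) = sqrt(|u|² + μ)`` (dimensionless, on max-1-normalized images).

    ``solver`` selects the minimization flavor: ``"irls"`` runs
    ``reweight_sweeps`` majorize–minimize sweeps with ``max_cg_iters``
    preconditioned linear-CG iterations each; ``"ncg"`` runs
    ``max_cg_iters`` nonlinear-CG iterations with backtracking governed by
    ``linesearch_alpha``/``linesearch_beta``.
    """

    lam: float = 5e-4
    eta1: Optional[float] = None
    eta2: Optional[float] = None
    smoothing_mu: float = 1e-12
    solver: str = "irls"
    mu_start: float = 1e-2
    mu_decay: float = 100.0
    reweight_sweeps: int = 4
    inner_tol: float = 1e-8
    max_cg_iters: int = 25
    grad_tol: float = 0.0
    linesearch_alpha: float = 0.05
    linesearch_beta: float = 0.6
    max_backtracks: int = 50
    use_wavelet: bool = False
    wavelet: str = "db4"
    wavelet_levels: int = 4

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.smoothing_mu <= 0:
            raise ValueError("smoothing_mu must be positive")
        if not 0.0 < self.linesearch_alpha < 0.5:
            raise ValueError("linesearch_alpha must lie in (0, 0.5)")
        if not 0.0 < self.linesearch_beta < 1.0:
            raise ValueError("linesearch_beta must lie in (0, 1)")
        if self.max_cg_iters < 1:
            raise ValueError("max_cg_iters must be positive")
        if self.solver not in ("irls", "ncg"):
            raise ValueError(f"unknown solver flavor {self.solver!r}")
        if self.reweight_sweeps < 1:
            raise ValueError("reweight_sweeps must be positive")
        if self.eta1 is None:
            self.eta1 = self.lam
        if self.eta2 is None:
            self.eta2 = self.lam / 2.0
        if self.eta1 < 0 or self.eta2 < 0:
            raise ValueError("eta1/eta2 must be non-negative")

    @property
    def analysis_weight(self) -> float:
        """λ (plain objective) or η1 (wavelet-augmented objective)."""
        return float(self.eta1 if self.use_wavelet else self.lam)


@dataclass
class SolverStats:
    """Per-solve diagnostics (JSON-serializable via :meth:`to_dict`)."""

    iterations: int = 0
    objective_trace: List[float] = field(default_factory=list)
    gradient_norms: List[float] = field(default_factory=list)
    converged: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


class _Problem:
    """Caches the linear-map applications needed by objective/gradient."""

    def __init__(
        self,
        y: np.ndarray,
        mask: SamplingMask,
        cosupport: CosupportSet,
        config: ReconConfig,
        operator: Optional[FiniteDifferenceOperator] = None,
    ) -> None:
        self.y = np.asarray(y, dtype=complex)
        self.mask = mask
        self.config = config
        self.operator = operator or FiniteDifferenceOperator(
            mask.shape, cosupport.directions
        )
        if tuple(cosupport.directions) != tuple(self.operator.directions):
            raise ValueError("cosupport directions do not match the operator")
        self.cos_masks = np.stack(
            [cosupport.mask(d) for d in self.operator.directions]
        )
        self.wavelet_op = (
            WaveletOperator(mask.shape, config.wavelet, config.wavelet_levels)
            if config.use_wavelet
            else None
        )
        self.mu = config.smoothing_mu
        self.w_fd = config.analysis_weight
        self.w_wt = float(config.eta2) if config.use_wavelet else 0.0

    # -- cached state for an iterate -------------------------------------
    def state(self, x: np.ndarray) -> dict:
        st = {
            "x": x,
            "resid": forward_fourier(x, self.mask) - self.y,
            "fd": self.operator.apply_all(x),
        }
        if self.wavelet_op is not None:
            st["wt"] = self.wavelet_op.forward(x)
        return st

    def direction_maps(self, d: np.ndarray) -> dict:
        mp = {
            "d": d,
            "resid": forward_fourier(d, self.mask),
            "fd": self.operator.apply_all(d),
        }
        if self.wavelet_op is not None:
            mp["wt"] = self.wavelet_op.forward(d)
        return mp

    def _phi(self, coeffs: np.ndarray) -> np.ndarray:
        return np.sqrt(np.abs(coeffs) ** 2 + self.mu)

    def objective_from(self, resid, fd, wt=None) -> float:
        val = float(np.vdot(resid, resid).real)
        if self.w_fd > 0:
            val += self.w_fd * float(self._phi(fd).sum(where=self.cos_masks))
        if self.wavelet_op is not None and self.w_wt > 0:
            val += self.w_wt * float(self._phi(wt).sum())
        return val

    def objective_at_step(self, st: dict, mp: dict, alpha: float) -> float:
        wt = None
        if self.wavelet_op is not None:
            wt = st["wt"] + alpha * mp["wt"]
        return self.objective_from(
            st["resid"] + alpha * mp["resid"], st["fd"] + alpha * mp["fd"], wt
        )

    def objective(self, x: np.ndarray) -> float:
        st = self.state(np.asarray(x, dtype=complex))
        return self.objective_from(st["resid"], st["fd"], st.get("wt"))

    def gradient_from(self, st: dict) -> np.ndarray:
        g = 2.0 * adjoint_fourier(st["resid"], self.mask)
        if self.w_fd > 0:
            fd = st["fd"]
            weights = np.where(self.cos_masks, 1.0 / self._phi(fd), 0.0)
            g = g + self.w_fd * self.operator.adjoint_all(fd * weights)
        if self.wavelet_op is not None and self.w_wt > 0:
            wt = st["wt"]
            g = g + self.w_wt * self.wavelet_op.adjoint(wt / self._phi(wt))
        return g

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.gradient_from(self.state(np.asarray(x, dtype=complex)))

    # -- IRLS machinery ---------------------------------------------------
    def fd_fourier_symbol(self) -> np.ndarray:
        """Fourier symbol of ``Σ_i Ω_iᵀ Ω_i`` (periodic differences)."""
        rows, cols = self.mask.shape
        kr = np.fft.fftfreq(rows)[:, None]
        kc = np.fft.fftfreq(cols)[None, :]
        sym = np.zeros((rows, cols))
        for d in self.operator.directions:
            dr, dc = DIRECTIONS[d]
            sym += np.abs(1.0 - np.exp(-2j * np.pi * (dr * kr + dc * kc))) ** 2
        return sym

    def apply_normal(
        self,
        v: np.ndarray,
        weights_fd: Optional[np.ndarray],
        weights_wt: Optional[np.ndarray],
    ) -> np.ndarray:
        """``A v`` for the majorizer normal operator
        ``A = 2 F_uᴴ F_u + w_fd Ω_Λᵀ W Ω_Λ (+ w_wt Ψᵀ V Ψ)``."""
        spec = np.fft.fft2(v, norm="ortho")
        out = 2.0 * np.fft.ifft2(spec * self.mask.array, norm="ortho")
        if weights_fd is not None:
            fd = self.operator.apply_all(v)
            out = out + self.w_fd * self.operator.adjoint_all(fd * weights_fd)
        if weights_wt is not None:
            wt = self.wavelet_op.forward(v)
            out = out + self.w_wt * self.wavelet_op.adjoint(wt * weights_wt)
        return out


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"{name} contains NaN or Inf")


def objective(
    x: np.ndarray,
    y: np.ndarray,
    mask: SamplingMask,
    cosupport: CosupportSet,
    config: ReconConfig,
    operator: Optional[FiniteDifferenceOperator] = None,
) -> float:
    """Smoothed truncated-ℓ1 objective value at ``x``."""
    _check_finite(np.asarray(x), "x")
    _check_finite(np.asarray(y), "y")
    return _Problem(y, mask, cosupport, config, operator).objective(x)


def gradient(
    x: np.ndarray,
    y: np.ndarray,
    mask: SamplingMask,
    cosupport: CosupportSet,
    config: ReconConfig,
    operator: Optional[FiniteDifferenceOperator] = None,
) -> np.ndarray:
    """Analytic gradient of :func:`objective` with respect to ``x``.

    For complex images this is the conjugate-coordinate (Wirtinger) gradient
    scaled so that ``d/dh f(x + h d) = Re⟨g, d⟩`` for real steps ``h``.
    """
    _check_finite(np.asarray(x), "x")
    _check_finite(np.asarray(y), "y")
    return _Problem(y, mask, cosupport, config, operator).gradient(x)


def solve_truncated_l1(
    y: np.ndarray,
    mask: SamplingMask,
    cosupport: CosupportSet,
    config: ReconConfig,
    x_init: Optional[np.ndarray] = None,
    operator: Optional[FiniteDifferenceOperator] = None,
) -> Tuple[np.ndarray, SolverStats]:
    """Minimize the smoothed truncated-ℓ1 objective.

    Dispatches on ``config.solver``: majorize–minimize IRLS with
    preconditioned linear CG (default) or Polak–Ribière nonlinear CG with
    Armijo backtracking.  Both keep the objective non-increasing across
    accepted steps; neither raises on non-convergence (the stats carry a
    converged flag and message).  ``x_init`` defaults to the zero-filled
    adjoint reconstruction ``F_uᴴ y``.
    """
    problem = _Problem(y, mask, cosupport, config, operator)
    x = (
        np.array(x_init, dtype=complex)
        if x_init is not None
        else adjoint_fourier(problem.y, mask)
    )
    _check_finite(x, "x_init")
    if config.solver == "irls":
        return _solve_irls(problem, x, config)
    return _solve_ncg(problem, x, config)


def _solve_irls(
    problem: _Problem, x: np.ndarray, config: ReconConfig
) -> Tuple[np.ndarray, SolverStats]:
    """Majorize–minimize sweeps with smoothing (μ) continuation.

    The smoothing constant is walked down geometrically from
    ``config.mu_start`` to ``config.smoothing_mu`` (factor
    ``config.mu_decay`` per stage); each stage runs up to
    ``config.reweight_sweeps`` reweighting sweeps, each sweep one
    warm-started preconditioned linear-CG solve of the quadratic majorizer.
    The returned objective trace is evaluated at the target μ and is
    non-increasing (the best-so-far iterate is kept).
    """
    stats = SolverStats()
    op = problem.operator
    b = 2.0 * adjoint_fourier(problem.y, problem.mask)
    dsym = problem.fd_fourier_symbol()
    has_fd = problem.w_fd > 0 and problem.cos_masks.any()
    has_wt = problem.wavelet_op is not None and problem.w_wt > 0
    mu_target = config.smoothing_mu

    def phi(coeffs: np.ndarray, mu: float) -> np.ndarray:
        return np.sqrt(np.abs(coeffs) ** 2 + mu)

    def target_objective(xc: np.ndarray) -> float:
        resid = forward_fourier(xc, problem.mask) - problem.y
        val = float(np.vdot(resid, resid).real)
        if has_fd:
            val += problem.w_fd * float(
                phi(op.apply_all(xc), mu_target).sum(where=problem.cos_masks)
            )
        if has_wt:
            val += problem.w_wt * float(
                phi(problem.wavelet_op.forward(xc), mu_target).sum()
            )
        return val

    # geometric continuation schedule down to the target smoothing
    schedule = []
    mu = max(config.mu_start, mu_target)
    while mu > mu_target * (1.0 + 1e-12):
        schedule.append(mu)
        mu /= config.mu_decay
    schedule.append(mu_target)

    best_x = x
    best_f = target_objective(x)
    stats.objective_trace.append(best_f)
    total_sweeps = 0

    for mu in schedule:
        for _ in range(config.reweight_sweeps):
            fd = op.apply_all(x)
            weights_fd = (
                np.where(problem.cos_masks, 1.0 / phi(fd, mu), 0.0)
                if has_fd
                else None
            )
            weights_wt = None
            if has_wt:
                weights_wt = 1.0 / phi(problem.wavelet_op.forward(x), mu)

            # Fourier-diagonal preconditioner with scalar average weights
            denom = 2.0 * problem.mask.array.astype(float)
            if has_fd:
                denom = denom + (
                    problem.w_fd
                    * float(weights_fd.mean(where=problem.cos_masks))
                    * dsym
                )
            if has_wt:
                denom = denom + problem.w_wt * float(weights_wt.mean())
            floor = max(float(denom.max()) * 1e-12, 1e-300)
            pre = 1.0 / np.maximum(denom, floor)

            def apply_pre(v: np.ndarray) -> np.ndarray:
                return np.fft.ifft2(
                    np.fft.fft2(v, norm="ortho") * pre, norm="ortho"
                )

            # linear CG on the majorizer normal equations, warm-started
            r = b - problem.apply_normal(x, weights_fd, weights_wt)
            z = apply_pre(r)
            p = z
            rz = float(np.vdot(r, z).real)
            x_old = x
            for _ in range(config.max_cg_iters):
                ap = problem.apply_normal(p, weights_fd, weights_wt)
                p_ap = float(np.vdot(p, ap).real)
                if p_ap <= 0:
                    break
                alpha = rz / p_ap
                x = x + alpha * p
                r = r - alpha * ap
                z = apply_pre(r)
                rz_new = float(np.vdot(r, z).real)
                if rz_new <= 0:
                    break
                p = z + (rz_new / rz) * p
                rz = rz_new

            total_sweeps += 1
            stats.iterations = total_sweeps
            f = target_objective(x)
            if f < best_f:
                best_f = f
                best_x = x
                stats.objective_trace.append(f)

            step = float(np.linalg.norm(x - x_old))
            denom_x = max(float(np.linalg.norm(x_old)), 1e-300)
            if step / denom_x <= config.inner_tol:
                break

    stats.converged = True
    stats.message = (
        f"continuation finished: {len(schedule)} stages, "
        f"{total_sweeps} sweeps"
    )
    return best_x, stats


def _solve_ncg(
    problem: _Problem, x: np.ndarray, config: ReconConfig
) -> Tuple[np.ndarray, SolverStats]:
    """Polak–Ribière NCG with backtracking from a quadratic-model step."""
    stats = SolverStats()
    st = problem.state(x)
    f = problem.objective_from(st["resid"], st["fd"], st.get("wt"))
    g = problem.gradient_from(st)
    d = -g
    stats.objective_trace.append(f)
    t0 = 1.0

    for it in range(config.max_cg_iters):
        gnorm = float(np.linalg.norm(g))
        stats.gradient_norms.append(gnorm)
        if gnorm <= config.grad_tol:
            stats.converged = True
            stats.message = "gradient tolerance reached"
            break

        dir_deriv = float(np.vdot(g, d).real)
        if dir_deriv >= 0:  # restart on non-descent
            d = -g
            dir_deriv = -gnorm**2

        mp = problem.direction_maps(d)
        # quadratic-model initial step: exact curvature of the data term
        # plus the IRLS-majorizer curvature of the smoothed-ℓ1 terms
        c_data = 2.0 * float(np.vdot(mp["resid"], mp["resid"]).real)
        c_pen = 0.0
        if problem.w_fd > 0:
            phi = problem._phi(st["fd"])
            c_pen += problem.w_fd * float(
                (np.abs(mp["fd"]) ** 2 / phi).sum(where=problem.cos_masks)
            )
        if problem.wavelet_op is not None and problem.w_wt > 0:
            c_pen += problem.w_wt * float(
                (np.abs(mp["wt"]) ** 2 / problem._phi(st["wt"])).sum()
            )
        curvature = c_data + c_pen
        alpha = t0 * (-dir_deriv / curvature) if curvature > 0 else t0
        n_back = 0
        f_new = problem.objective_at_step(st, mp, alpha)
        while (
            f_new > f + alpha * config.linesearch_alpha * dir_deriv
            and n_back < config.max_backtracks
        ):
            alpha *= config.linesearch_beta
            n_back += 1
            f_new = problem.objective_at_step(st, mp, alpha)
        if f_new > f:
            stats.converged = False
            stats.message = (
                f"line search failed to decrease the objective after "
                f"{config.max_backtracks} backtracks at iteration {it}"
            )
            break

        # adapt the initial step like standard CS-MRI NCG implementations
        if n_back > 2:
            t0 *= config.linesearch_beta
        elif n_back < 1:
            t0 = min(t0 / config.linesearch_beta, 1e4)

        x = x + alpha * d
        new_st = {
            "x": x,
            "resid": st["resid"] + alpha * mp["resid"],
            "fd": st["fd"] + alpha * mp["fd"],
        }
        if problem.wavelet_op is not None:
            new_st["wt"] = st["wt"] + alpha * mp["wt"]
        st = new_st
        f = f_new
        stats.objective_trace.append(f)
        stats.iterations = it + 1

        g_new = problem.gradient_from(st)
        beta_pr = float(np.vdot(g_new, g_new - g).real) / max(gnorm**2, 1e-300)
        beta_pr = max(beta_pr, 0.0)
        d = -g_new + beta_pr * d
        g = g_new
    else:
        stats.converged = True
        stats.message = "maximum CG iterations reached"

    return x, stats


def oracle_constrained_solve(
    y: np.ndarray,
    mask: SamplingMask,
    cosupport: CosupportSet,
    operator: Optional[FiniteDifferenceOperator] = None,
) -> np.ndarray:
    """Direct recovery from an exactly known cosupport (small grids).

    Stacks the measurement rows and the cosupport-restricted analysis rows
    into ``[F_u; Ω_Λ] x = [y; 0]`` and returns the minimum-norm
    least-squares solution.  Recovery is exact when the stacked operator has
    a trivial null space and ``y`` is consistent.  Dense construction:
    refuses images with side > 64.
    """
    rows, cols = mask.shape
    if max(rows, cols) > 64:
        raise ValueError(
            f"oracle_constrained_solve builds dense systems; side "
            f"{max(rows, cols)} > 64 refused"
        )
    operator = operator or FiniteDifferenceOperator(
        mask.shape, cosupport.directions
    )
    n = rows * cols
    # dense unitary DFT restricted to the mask: F_u[k] = row of sampled freq
    eye = np.eye(n).reshape(n, rows, cols)
    spectrum = np.fft.fft2(eye, norm="ortho", axes=(1, 2)).reshape(n, n)
    f_u = spectrum[:, mask.array.ravel()].T  # (m, n), ascending flat order

    blocks = [f_u]
    for d in operator.directions:
        idx = cosupport.indices[d]
        if idx.size:
            blocks.append(operator.dense_matrix(d)[idx])
    a = np.vstack(blocks).astype(complex)
    b = np.concatenate([np.asarray(y, dtype=complex),
                        np.zeros(a.shape[0] - len(y), dtype=complex)])
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    return x.reshape(rows, cols)
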