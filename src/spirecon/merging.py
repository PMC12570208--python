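"""Autocorrelation merging: regularized least squares on oriented samples.

The slicing operator ``A`` maps the autocorrelation volume ``x`` (cubic
grid, spacing ``ac_voxel``) to intensity values at the oriented
Ewald-sphere points: ``(A x)_j = sum_k x_k exp(-2 pi i p_j . x_k)``.
Given measured intensities ``y`` (optionally weighted), the merge solves

    (A^H W A + lambda I) x = A^H W y

by conjugate gradient.  Both right-hand side and system operator come
from type-1 NUFFTs: the rhs is the adjoint applied to the data; the
operator is Toeplitz with symbol ``T(d) = sum_j w_j exp(2 pi i p_j . d)``
on a 2x-padded grid, so each application is one padded FFT convolution.

Sample sets are Friedel-symmetrized (each point is mirrored to ``-p``)
before setup, which the physics guarantees and which makes the Toeplitz
symbol real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ParameterError
from .nufft import FourierVolume, NonuniformSamples, nufft_type1, nufft_type2

__all__ = [
    "NormalEquations",
    "MergeSolution",
    "setup_normal_equations",
    "apply_system",
    "solve_autocorrelation",
    "hyperparameter_sweep",
    "select_solution",
]


@dataclass
class NormalEquations:
    """Precomputed rhs and Toeplitz kernel of the merge linear system."""

    rhs: np.ndarray                    # (M, M, M) real
    kernel: np.ndarray                 # (2M, 2M, 2M) real Toeplitz symbol
    lam: float
    M: int
    ac_voxel: float
    samples: NonuniformSamples         # Friedel-augmented; kept for misfit
    kernel_hat: np.ndarray = field(default=None, repr=False)  # rfftn of circulant

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ParameterError(f"lambda must be >= 0, got {self.lam}")
        if self.kernel_hat is None:
            circ = self.kernel
            for ax in range(3):
                circ = np.roll(circ, -self.M, axis=ax)
            self.kernel_hat = np.fft.rfftn(circ)

    @property
    def kernel_zero_lag(self) -> float:
        """T(0) = total sample weight; the diagonal of A^H W A."""
        c = self.kernel.shape[0] // 2
        return float(self.kernel[c, c, c])


@dataclass
class MergeSolution:
    """CG solution and its selection diagnostics."""

    autocorrelation: FourierVolume
    lambda_used: float
    data_misfit: float
    solution_norm: float
    cg_iterations: int
    converged: bool
    residual_history: np.ndarray = field(default=None, repr=False)


def _friedel_augment(samples: NonuniformSamples) -> NonuniformSamples:
    if samples.values is None:
        raise ParameterError("samples carry no values")
    pts = np.concatenate([samples.points, -samples.points])
    vals = np.concatenate([samples.values, samples.values])
    w = samples.weights
    if w is None:
        w = np.ones(len(samples))
    wts = np.concatenate([w, w]) * 0.5  # mirror halves the weight: total preserved
    return NonuniformSamples(points=pts, values=vals, weights=wts)


def setup_normal_equations(samples: NonuniformSamples, M: int, lam: float,
                           ac_voxel: float, eps: float = 1e-6,
                           friedel: bool = True) -> NormalEquations:
    """Build rhs and Toeplitz kernel with two type-1 NUFFTs.

    ``rhs = A^H W y`` on the M-grid; the kernel is the type-1 transform
    of the weights alone on the 2M-grid (all lags of the Toeplitz
    operator).  Both are computed once per generation.
    """
    if len(samples) == 0:
        raise ParameterError("empty sample set")
    if M < 8:
        raise ParameterError(f"M must be >= 8, got {M}")
    if samples.values is None:
        raise ParameterError("samples carry no values")
    s = _friedel_augment(samples) if friedel else NonuniformSamples(
        points=samples.points,
        values=samples.values,
        weights=samples.weights if samples.weights is not None else np.ones(len(samples)),
    )
    rhs = nufft_type1(s.points, s.weights * np.asarray(s.values, dtype=float),
                      M, ac_voxel, eps=eps)
    kern = nufft_type1(s.points, s.weights.astype(float), 2 * M, ac_voxel, eps=eps)
    scale = max(np.abs(kern).max(), 1e-300)
    if np.abs(kern.imag).max() > 1e-5 * scale:
        if friedel:  # pragma: no cover - Friedel augmentation guarantees realness
            raise NumericalError("Toeplitz kernel unexpectedly complex")
    return NormalEquations(
        rhs=rhs.real, kernel=kern.real, lam=lam, M=M, ac_voxel=ac_voxel, samples=s,
    )


def apply_system(ne: NormalEquations, x: np.ndarray, lam: float | None = None) -> np.ndarray:
    """Return ``(A^H W A) x + lambda x`` via padded-FFT Toeplitz convolution."""
    if lam is None:
        lam = ne.lam
    x = np.asarray(x)
    M = ne.M
    if x.shape != (M, M, M):
        raise ParameterError(f"x must be {M}^3, got {x.shape}")
    pad = np.zeros((2 * M,) * 3)
    pad[:M, :M, :M] = x
    conv = np.fft.irfftn(np.fft.rfftn(pad) * ne.kernel_hat,
                         s=(2 * M,) * 3, axes=(0, 1, 2))
    return conv[:M, :M, :M] + lam * x


def solve_autocorrelation(ne: NormalEquations, tol: float = 1e-6,
                          max_iter: int = 500, eps: float = 1e-6) -> MergeSolution:
    """Krylov solve of the SPD normal equations, zero initial guess.

    Uses the conjugate-residual variant of the conjugate-gradient
    family (same cost: one operator application per iteration) because
    it minimizes the residual norm at every step, so the reported
    residual history is non-increasing.  Stops when the relative
    residual drops below ``tol``.  The reported ``data_misfit`` is
    ``sqrt(sum w |A x - y|^2)`` evaluated with a type-2 NUFFT on the
    solution, and ``solution_norm`` is ``||x||``.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    b = ne.rhs
    bnorm = np.linalg.norm(b)
    M = ne.M
    x = np.zeros((M, M, M))
    history = []
    it = 0
    converged = True
    if bnorm > 0:
        r = b.copy()
        p = r.copy()
        Ar = apply_system(ne, r)
        Ap = Ar.copy()
        rAr = float(np.vdot(r, Ar).real)
        converged = False
        for it in range(1, max_iter + 1):
            denom = float(np.vdot(Ap, Ap).real)
            if denom <= 0:
                break
            alpha = rAr / denom
            x += alpha * p
            r -= alpha * Ap
            rnorm = float(np.linalg.norm(r))
            if not np.isfinite(rnorm):
                raise NumericalError(f"solver produced non-finite residual at iteration {it}")
            history.append(rnorm / bnorm)
            if history[-1] <= tol:
                converged = True
                break
            Ar = apply_system(ne, r)
            rAr_new = float(np.vdot(r, Ar).real)
            beta = rAr_new / rAr
            p = r + beta * p
            Ap = Ar + beta * Ap
            rAr = rAr_new
    pred = nufft_type2(x.astype(complex), ne.ac_voxel, ne.samples.points, eps=eps)
    resid = pred.real - np.asarray(ne.samples.values, dtype=float)
    misfit = float(np.sqrt(np.sum(ne.samples.weights * resid**2)))
    ac = FourierVolume(values=x, voxel_q=1.0 / (M * ne.ac_voxel), role="autocorrelation")
    return MergeSolution(
        autocorrelation=ac,
        lambda_used=ne.lam,
        data_misfit=misfit,
        solution_norm=float(np.linalg.norm(x)),
        cg_iterations=it,
        converged=converged,
        residual_history=np.asarray(history),
    )


def select_solution(solutions: list[MergeSolution]) -> MergeSolution:
    """Pick the best solution of a lambda sweep.

    Uses the L-curve corner (maximum curvature of the parametric
    ``(log misfit, log norm)`` curve ordered by lambda); with fewer than
    three points, or a degenerate curve, falls back to the smallest
    lambda whose misfit is within 5% of the sweep minimum.
    """
    if not solutions:
        raise ParameterError("no solutions to select from")
    sols = sorted(solutions, key=lambda s: s.lambda_used)
    if len(sols) >= 3:
        xs = np.log(np.maximum([s.data_misfit for s in sols], 1e-300))
        ys = np.log(np.maximum([s.solution_norm for s in sols], 1e-300))
        curv = np.full(len(sols), -np.inf)
        for i in range(1, len(sols) - 1):
            x1, x2, x3 = xs[i - 1], xs[i], xs[i + 1]
            y1, y2, y3 = ys[i - 1], ys[i], ys[i + 1]
            area2 = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
            d12 = np.hypot(x2 - x1, y2 - y1)
            d23 = np.hypot(x3 - x2, y3 - y2)
            d13 = np.hypot(x3 - x1, y3 - y1)
            if min(d12, d23, d13) > 1e-12:
                curv[i] = 2.0 * abs(area2) / (d12 * d23 * d13)
        if np.isfinite(curv).any() and curv.max() > 0:
            return sols[int(np.argmax(curv))]
    min_misfit = min(s.data_misfit for s in sols)
    for s in sols:  # ascending lambda; pick smallest acceptable
        if s.data_misfit <= 1.05 * min_misfit:
            return s
    return sols[0]  # pragma: no cover


def hyperparameter_sweep(samples: NonuniformSamples, M: int, lambdas,
                         ac_voxel: float, tol: float = 1e-6,
                         max_iter: int = 500, eps: float = 1e-6,
                         friedel: bool = True) -> MergeSolution:
    """Solve the merge at every lambda and return the selected solution.

    The sweep result is independent of the order of ``lambdas`` (the
    selection works on the lambda-sorted list).  The expensive NUFFTs
    are shared: only the CG solve is repeated per lambda.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ParameterError("lambdas must be nonempty")
    base = setup_normal_equations(samples, M, 0.0, ac_voxel, eps=eps, friedel=friedel)
    solutions = []
    failures = []
    for lam in sorted(set(float(l) for l in lambdas)):
        ne = NormalEquations(rhs=base.rhs, kernel=base.kernel, lam=lam, M=M,
                             ac_voxel=ac_voxel, samples=base.samples,
                             kernel_hat=base.kernel_hat)
        try:
            solutions.append(solve_autocorrelation(ne, tol=tol, max_iter=max_iter, eps=eps))
        except NumericalError as exc:
            failures.append((lam, exc))
    if not solutions:
        raise NumericalError(f"all merge solves failed: {failures}")
    return select_solution(solutions)
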