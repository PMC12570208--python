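import numpy as np
import pytest

from spirecon.errors import ParameterError
from spirecon.geometry import pixel_to_q, quat_to_matrix, random_orientations
from spirecon.merging import (
    NormalEquations,
    apply_system,
    hyperparameter_sweep,
    select_solution,
    setup_normal_equations,
    solve_autocorrelation,
)
from spirecon.nufft import NonuniformSamples
from spirecon.simulate import NoiseSpec, exact_autocorrelation, simulate_patterns

VOX = 1e-10


def dense_operator(ne):
    """Explicit A^H W A matrix and rhs from the (augmented) sample set."""
    M = ne.M
    x = (np.arange(M) - M // 2) * ne.ac_voxel
    grid = np.stack(np.meshgrid(x, x, x, indexing="ij")).reshape(3, -1)
    E = np.exp(-2j * np.pi * ne.samples.points @ grid)
    AHA = ((E.conj().T * ne.samples.weights) @ E).real
    rhs = (E.conj().T @ (ne.samples.weights * np.asarray(ne.samples.values))).real
    return AHA, rhs


@pytest.fixture(scope="module")
def small_system():
    rng = np.random.default_rng(7)
    M, P = 8, 200
    pts = rng.uniform(-0.5, 0.5, (P, 3))
    y = rng.standard_normal(P)
    samples = NonuniformSamples(points=pts, values=y)
    ne = setup_normal_equations(samples, M, 0.3, 1.0, eps=1e-10)
    return ne


class TestSetup:
    def test_zero_data_zero_rhs_kernel_unchanged(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.4, 0.4, (50, 3))
        a = setup_normal_equations(NonuniformSamples(points=pts, values=np.zeros(50)),
                                   8, 0.0, 1.0)
        b = setup_normal_equations(NonuniformSamples(points=pts,
                                                     values=rng.standard_normal(50)),
                                   8, 0.0, 1.0)
        assert np.allclose(a.rhs, 0.0, atol=1e-8 * 50)
        assert np.allclose(a.kernel, b.kernel)

    def test_rhs_linear_in_data(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-0.4, 0.4, (50, 3))
        y = rng.standard_normal(50)
        a = setup_normal_equations(NonuniformSamples(points=pts, values=y), 8, 0.0, 1.0)
        b = setup_normal_equations(NonuniformSamples(points=pts, values=2 * y), 8, 0.0, 1.0)
        assert np.allclose(b.rhs, 2 * a.rhs, rtol=1e-10, atol=1e-10 * np.abs(a.rhs).max())

    def test_kernel_zero_lag_counts_samples(self, small_system):
        # T(0) = sum of weights = P for unit weights (Friedel mirror halves them)
        assert np.isclose(small_system.kernel_zero_lag, 200.0, rtol=1e-7)

    def test_empty_samples_rejected(self):
        with pytest.raises(ParameterError, match="empty"):
            setup_normal_equations(
                NonuniformSamples(points=np.zeros((0, 3)), values=np.zeros(0)),
                8, 0.0, 1.0)


class TestApplySystem:
    def test_zero_maps_to_zero(self, small_system):
        assert np.all(apply_system(small_system, np.zeros((8, 8, 8))) == 0)

    def test_matches_dense_matrix_oracle(self, small_system):
        AHA, _ = dense_operator(small_system)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, 8, 8))
        got = apply_system(small_system, x)
        want = (AHA @ x.ravel()).reshape(8, 8, 8) + small_system.lam * x
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-7

    def test_self_adjoint(self, small_system):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 8, 8))
        y = rng.standard_normal((8, 8, 8))
        lhs = np.vdot(apply_system(small_system, x), y)
        rhs = np.vdot(x, apply_system(small_system, y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_large_lambda_dominates(self, small_system):
        # power iteration estimates the top eigenvalue of A^H W A
        rng = np.random.default_rng(4)
        v = rng.standard_normal((8, 8, 8))
        for _ in range(30):
            v = apply_system(small_system, v, lam=0.0)
            v /= np.linalg.norm(v)
        top = float(np.vdot(v, apply_system(small_system, v, lam=0.0)).real)
        lam = 100.0 * top
        x = rng.standard_normal((8, 8, 8))
        out = apply_system(small_system, x, lam=lam)
        assert np.linalg.norm(out - lam * x) / np.linalg.norm(lam * x) < 0.01

    def test_shape_mismatch_rejected(self, small_system):
        with pytest.raises(ParameterError, match="8"):
            apply_system(small_system, np.zeros((6, 6, 6)))


class TestSolve:
    def test_zero_rhs_gives_zero_solution(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-0.4, 0.4, (30, 3))
        ne = setup_normal_equations(
            NonuniformSamples(points=pts, values=np.zeros(30)), 8, 1.0, 1.0)
        ne.rhs[:] = 0.0  # exact zero rhs
        sol = solve_autocorrelation(ne, tol=1e-8, max_iter=50)
        assert np.all(sol.autocorrelation.values == 0)
        assert sol.cg_iterations <= 1

    def test_matches_dense_direct_solve(self, small_system):
        AHA, rhs = dense_operator(small_system)
        want = np.linalg.solve(AHA + small_system.lam * np.eye(8**3), rhs)
        sol = solve_autocorrelation(small_system, tol=1e-12, max_iter=2000)
        got = sol.autocorrelation.values.ravel()
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-6

    def test_residual_monotonically_non_increasing(self, small_system):
        sol = solve_autocorrelation(small_system, tol=1e-12, max_iter=300)
        h = sol.residual_history
        assert np.all(np.diff(h) <= 1e-10 + 1e-10 * h[:-1])

    def test_phantom_recovery_within_five_percent(self, phantom32, geom64):
        # noise-free oriented samples at >= 10 per Shannon voxel
        exact = exact_autocorrelation(phantom32, 2)
        qg = pixel_to_q(geom64)
        quats = random_orientations(150, 5)
        stack = simulate_patterns(phantom32, geom64, quats, None,
                                  NoiseSpec(poisson=False, fluence_mean=1.0, seed=0))
        pts = np.einsum("dij,pj->dpi", quat_to_matrix(quats), qg.flat).reshape(-1, 3)
        vals = stack.images.reshape(len(quats), -1).ravel() / VOX**3
        ne = setup_normal_equations(NonuniformSamples(points=pts, values=vals),
                                    64, 1e-6 * len(pts), VOX, eps=1e-6)
        sol = solve_autocorrelation(ne, tol=1e-6, max_iter=200)
        err = np.linalg.norm(sol.autocorrelation.values - exact.values)
        err /= np.linalg.norm(exact.values)
        assert err < 0.05

    def test_lambda_continuity(self, small_system):
        base = small_system
        out = {}
        for lam in (0.3, 0.303):
            ne = NormalEquations(rhs=base.rhs, kernel=base.kernel, lam=lam,
                                 M=base.M, ac_voxel=base.ac_voxel,
                                 samples=base.samples, kernel_hat=base.kernel_hat)
            out[lam] = solve_autocorrelation(ne, tol=1e-10, max_iter=1000)
        a = out[0.3].autocorrelation.values
        b = out[0.303].autocorrelation.values
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.02


class TestSweep:
    def test_single_lambda_equals_plain_solve(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-0.4, 0.4, (60, 3))
        samples = NonuniformSamples(points=pts, values=rng.standard_normal(60))
        sweep = hyperparameter_sweep(samples, 8, [0.5], 1.0, tol=1e-10, max_iter=500)
        ne = setup_normal_equations(samples, 8, 0.5, 1.0)
        plain = solve_autocorrelation(ne, tol=1e-10, max_iter=500)
        assert np.allclose(sweep.autocorrelation.values, plain.autocorrelation.values)
        assert sweep.lambda_used == 0.5

    def test_selection_permutation_invariant(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-0.4, 0.4, (60, 3))
        samples = NonuniformSamples(points=pts, values=rng.standard_normal(60))
        lams = [1e-3, 1e-1, 1e-5, 1.0]
        a = hyperparameter_sweep(samples, 8, lams, 1.0, tol=1e-8, max_iter=300)
        b = hyperparameter_sweep(samples, 8, lams[::-1], 1.0, tol=1e-8, max_iter=300)
        assert a.lambda_used == b.lambda_used
        assert np.array_equal(a.autocorrelation.values, b.autocorrelation.values)

    def test_selected_not_worse_than_median_on_phantom(self, phantom32, geom64):
        from spirecon.merging import solve_autocorrelation as solve

        exact = exact_autocorrelation(phantom32, 2)
        qg = pixel_to_q(geom64)
        quats = random_orientations(100, 9)
        stack = simulate_patterns(phantom32, geom64, quats, None,
                                  NoiseSpec(poisson=False, fluence_mean=1.0, seed=0))
        pts = np.einsum("dij,pj->dpi", quat_to_matrix(quats), qg.flat).reshape(-1, 3)
        vals = stack.images.reshape(len(quats), -1).ravel() / VOX**3
        samples = NonuniformSamples(points=pts, values=vals)
        lams = [1e-8 * len(pts), 1e-5 * len(pts), 1e-2 * len(pts)]
        base = setup_normal_equations(samples, 64, 0.0, VOX, eps=1e-5)
        errs = []
        sols = []
        for lam in lams:
            ne = NormalEquations(rhs=base.rhs, kernel=base.kernel, lam=lam, M=64,
                                 ac_voxel=VOX, samples=base.samples,
                                 kernel_hat=base.kernel_hat)
            s = solve(ne, tol=1e-5, max_iter=120, eps=1e-5)
            sols.append(s)
            errs.append(np.linalg.norm(s.autocorrelation.values - exact.values)
                        / np.linalg.norm(exact.values))
        chosen = select_solution(sols)
        chosen_err = errs[[s.lambda_used for s in sols].index(chosen.lambda_used)]
        assert chosen_err <= np.median(errs) + 1e-12
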