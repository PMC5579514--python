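"""Interior-point L1 solver, KKT residual, reconstruction, and baseline."""

import numpy as np
import pytest
import scipy.linalg

from csmat import (
    AddressPlan,
    PressureFrame,
    SolverConfig,
    build_sensing_matrix,
    generate_addresses,
    interpolate_frame,
    reconstruct_frame,
    solve_l1,
    solve_l1_linprog,
    subsample,
)
from csmat.cs_solver import SolverState, kkt_residual
from csmat.errors import DegenerateGeometryError
from csmat.synthetic import Blob, PhantomSpec, gen_phantom, gen_sparse_signal

TIGHT = SolverConfig(gap_tol=1e-8, max_iters=60)


def _small_phantom(noise_sd=0.02):
    """Two-blob phantom sized for small test grids."""
    return PhantomSpec(
        blobs=[Blob(5.0, 5.0, 2.5, 3.0, 3.0), Blob(11.0, 10.0, 3.0, 2.5, 2.0)],
        noise_sd=noise_sd,
    )


def _random_instance(seed, P=4, Q=4, S=2, M=8):
    coeffs, frame = gen_sparse_signal(P, Q, S=S, seed=seed)
    plan = generate_addresses(M, P, Q, seed=seed + 1000)
    A = build_sensing_matrix(plan)
    b = subsample(frame, plan).values
    return A, b, coeffs


class TestKKTResidual:
    def _state(self, rng, N, M):
        z = rng.normal(size=N)
        mu = np.abs(z) + rng.uniform(0.1, 1.0, size=N)
        lam = rng.uniform(0.1, 2.0, size=2 * N)
        nu = rng.normal(size=M)
        return SolverState(z=z, mu=mu, lam=lam, nu=nu, tau=1.0)

    def test_primal_feasibility_zeroes_third_block(self):
        rng = np.random.default_rng(0)
        A, _, _ = _random_instance(0)
        state = self._state(rng, 16, 8)
        b = A.entries @ state.z
        r = kkt_residual(state, A, b, tau=1.0)
        np.testing.assert_allclose(r[-8:], 0.0, atol=1e-12)

    def test_relaxed_kkt_point_has_zero_residual(self):
        # z = 0, mu = 2/tau gives lambda = 1/2 per constraint: centering,
        # stationarity (lam1 - lam2 = 0, nu = 0), and Az = 0 all hold.
        A, _, _ = _random_instance(1)
        tau = 3.0
        N, M = 16, 8
        state = SolverState(
            z=np.zeros(N),
            mu=np.full(N, 2.0 / tau),
            lam=np.full(2 * N, 0.5),
            nu=np.zeros(M),
            tau=tau,
        )
        r = kkt_residual(state, A, np.zeros(M), tau=tau)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_centering_block_matches_elementwise_loop(self):
        rng = np.random.default_rng(2)
        A, b, _ = _random_instance(2)
        state = self._state(rng, 16, 8)
        r = kkt_residual(state, A, b, tau=1.0)
        centering = r[32:64]
        for i in range(16):
            f1 = state.z[i] - state.mu[i]
            f2 = -state.z[i] - state.mu[i]
            assert centering[i] == pytest.approx(-state.lam[i] * f1 - 1.0)
            assert centering[16 + i] == pytest.approx(
                -state.lam[16 + i] * f2 - 1.0
            )

    def test_dimension_mismatch(self):
        A, b, _ = _random_instance(3)
        state = SolverState(
            z=np.zeros(9), mu=np.ones(9), lam=np.ones(18), nu=np.zeros(8),
            tau=1.0,
        )
        with pytest.raises(ValueError):
            kkt_residual(state, A, b, tau=1.0)


class TestSolveL1:
    def test_zero_measurements_give_zero_solution(self):
        A, _, _ = _random_instance(4)
        res = solve_l1(A, np.zeros(8), TIGHT)
        assert res.objective == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.z, 0.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_matches_lp_oracle(self, seed):
        A, b, _ = _random_instance(seed)
        res = solve_l1(A, b, TIGHT)
        lp_objective = float(np.abs(solve_l1_linprog(A, b)).sum())
        assert res.objective == pytest.approx(lp_objective, rel=1e-4)
        assert np.linalg.norm(A.entries @ res.z - b) <= 1e-6 * (
            1 + np.linalg.norm(b)
        )

    def test_exact_recovery_of_sparse_truth(self):
        coeffs, frame = gen_sparse_signal(32, 32, S=10, seed=9)
        plan = generate_addresses(200, 32, 32, seed=90)
        A = build_sensing_matrix(plan)
        b = subsample(frame, plan).values
        res = solve_l1(A, b, TIGHT)
        z0 = coeffs.vec()
        assert np.linalg.norm(res.z - z0) / np.linalg.norm(z0) < 1e-4
        assert res.converged

    def test_objective_never_exceeds_feasible_start(self):
        # ||z||_1 at termination <= ||z_init||_1 + gap_tol, with z_init the
        # minimum-norm feasible point the solver starts from.
        for seed in range(5):
            A, b, _ = _random_instance(seed, P=8, Q=8, S=4, M=24)
            Amat = A.entries
            z_init = Amat.T @ scipy.linalg.solve(Amat @ Amat.T, b)
            res = solve_l1(A, b, SolverConfig(gap_tol=1e-6, max_iters=60))
            assert res.objective <= np.abs(z_init).sum() + 1e-6

    def test_unconverged_result_is_flagged(self):
        A, b, _ = _random_instance(6)
        with pytest.warns(RuntimeWarning, match="stopped at gap"):
            res = solve_l1(A, b, SolverConfig(gap_tol=1e-8, max_iters=2))
        assert not res.converged

    def test_bad_shapes_rejected(self):
        A, b, _ = _random_instance(7)
        with pytest.raises(ValueError):
            solve_l1(A, b[:-1], TIGHT)


class TestReconstructFrame:
    def test_full_sampling_reproduces_frame(self):
        frame = gen_phantom(_small_phantom(), P=16, Q=16, seed=1)
        plan = generate_addresses(256, 16, 16, seed=2)
        result = reconstruct_frame(subsample(frame, plan), TIGHT)
        assert np.max(np.abs(result.frame.values - frame.values)) < 1e-6

    def test_agrees_with_measurements_at_sampled_cells(self):
        frame = gen_phantom(_small_phantom(), P=16, Q=16, seed=3)
        plan = generate_addresses(100, 16, 16, seed=4)
        samples = subsample(frame, plan)
        result = reconstruct_frame(samples, TIGHT)
        recon_at_samples = result.frame.values[
            plan.addresses[:, 0] - 1, plan.addresses[:, 1] - 1
        ]
        np.testing.assert_allclose(recon_at_samples, samples.values, atol=1e-6)

    def test_zero_frame_reconstructs_to_zero(self):
        frame = PressureFrame(np.zeros((8, 8)))
        plan = generate_addresses(20, 8, 8, seed=5)
        result = reconstruct_frame(subsample(frame, plan), TIGHT)
        np.testing.assert_allclose(result.frame.values, 0.0, atol=1e-6)

    def test_cleanup_zeroes_speckle_and_negatives(self):
        frame = gen_phantom(_small_phantom(noise_sd=0.0), P=16, Q=16, seed=6)
        plan = generate_addresses(60, 16, 16, seed=7)
        raw = reconstruct_frame(subsample(frame, plan), TIGHT)
        cleaned = reconstruct_frame(subsample(frame, plan), TIGHT, cleanup=True)
        assert np.min(cleaned.frame.values) >= 0.0
        peak = cleaned.frame.values.max()
        small = (cleaned.frame.values > 0) & (cleaned.frame.values < 0.01 * peak)
        assert not small.any()
        # cleanup only ever zeroes cells
        changed = cleaned.frame.values != raw.frame.values
        assert np.all(cleaned.frame.values[changed] == 0.0)


class TestInterpolateFrame:
    def test_reproduces_planar_field_inside_hull(self):
        from scipy.spatial import Delaunay

        x = np.arange(1, 9)[:, None]
        y = np.arange(1, 9)[None, :]
        frame = PressureFrame(2.0 * x + 3.0 * y + 0.0 * (x + y), v_max=100.0)
        plan = generate_addresses(30, 8, 8, seed=8)
        result = interpolate_frame(subsample(frame, plan))
        tri = Delaunay(plan.addresses.astype(float))
        gx, gy = np.meshgrid(np.arange(1, 9), np.arange(1, 9), indexing="ij")
        inside = tri.find_simplex(
            np.column_stack([gx.reshape(-1), gy.reshape(-1)])
        ).reshape(8, 8) >= 0
        np.testing.assert_allclose(
            result.frame.values[inside], frame.values[inside], atol=1e-9
        )

    def test_full_sampling_is_identity(self):
        frame = gen_phantom(PhantomSpec(blobs=[Blob(4.0, 4.0, 2.0, 2.0, 3.0)]), P=8, Q=8, seed=9)
        plan = generate_addresses(64, 8, 8, seed=10)
        result = interpolate_frame(subsample(frame, plan))
        np.testing.assert_allclose(result.frame.values, frame.values, atol=1e-9)

    def test_out_of_hull_cell_takes_nearest_sample(self):
        plan = AddressPlan(np.array([[2, 2], [2, 3], [3, 2]]), P=4, Q=4)
        frame_values = np.zeros((4, 4))
        frame_values[1, 1] = 4.0
        frame_values[1, 2] = 5.0
        frame_values[2, 1] = 1.0
        samples = subsample(PressureFrame(frame_values), plan)
        result = interpolate_frame(samples)
        assert result.frame.values[0, 0] == pytest.approx(4.0)

    def test_collinear_addresses_rejected(self):
        plan = AddressPlan(np.array([[1, 1], [2, 2], [3, 3], [4, 4]]), P=4, Q=4)
        samples = subsample(PressureFrame(np.eye(4)), plan)
        with pytest.raises(DegenerateGeometryError):
            interpolate_frame(samples)

    def test_too_few_samples_rejected(self):
        plan = AddressPlan(np.array([[1, 1], [2, 2]]), P=4, Q=4)
        samples = subsample(PressureFrame(np.zeros((4, 4))), plan)
        with pytest.raises(DegenerateGeometryError):
            interpolate_frame(samples)
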