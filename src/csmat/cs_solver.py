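"""Basis-pursuit reconstruction by a primal-dual interior-point method.

The reconstruction problem is the equality-constrained L1 program

    min ||z||_1   subject to   A z = b,

the convex relaxation of seeking the sparsest DCT coefficient vector that
agrees with the M measured sensor voltages.  The non-differentiable L1
objective is lifted with slack variables mu,

    min 1' mu   s.t.  z - mu <= 0,  -z - mu <= 0,  A z = b,

and solved by Newton iterations on the relaxed KKT system: complementary
slackness lambda_l f_l = 0 is relaxed to lambda_l f_l = -1/tau, tau grows
with the surrogate duality gap eta = -f' lambda, and each Newton step is
damped by a backtracking line search that keeps the iterate strictly
interior (f < 0, lambda > 0) and decreases the KKT residual norm.

Per iteration the (dz, dmu, dlambda, dnu) system is reduced by eliminating
dlambda and dmu to an M x M symmetric positive-definite system in dnu,
which is the dominant cost (A diag(w) A' and a Cholesky solve).

An independent exact reference, :func:`solve_l1_linprog`, solves the same
program through the standard positive-split linear-programming formulation
with :func:`scipy.optimize.linprog`; it shares no code with the
interior-point path and exists for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.linalg.blas import dsyrk
from scipy.interpolate import NearestNDInterpolator, griddata
from scipy.optimize import linprog
from scipy.spatial import QhullError

from .errors import DegenerateGeometryError, RankDeficientSensingError
from .gridframe import PressureFrame
from .sampler import SampleSet, SensingMatrix, build_sensing_matrix
from .sparse_transform import CoefficientMatrix, idct2


@dataclass
class SolverConfig:
    """Interior-point tuning knobs (standard values; none are data-dependent).

    gap_tol
        Surrogate-duality-gap stopping threshold.  1e-3 suffices for frame
        display and waveform work; exact-recovery studies use ~1e-8.
    max_iters
        Iteration cap; hitting it flags the result as unconverged.
    tau_growth
        Barrier growth factor: tau = tau_growth * 2N / eta each iteration.
    ls_alpha, ls_beta
        Backtracking sufficient-decrease fraction and shrink factor.
    """

    gap_tol: float = 1e-3
    max_iters: int = 50
    tau_growth: float = 10.0
    ls_alpha: float = 0.01
    ls_beta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_tol <= 0:
            raise ValueError("gap_tol must be positive")
        if not (0 < self.ls_alpha < 0.5):
            raise ValueError("ls_alpha must lie in (0, 0.5)")
        if not (0 < self.ls_beta < 1):
            raise ValueError("ls_beta must lie in (0, 1)")
        if self.tau_growth <= 1:
            raise ValueError("tau_growth must exceed 1")


@dataclass
class SolverState:
    """One primal-dual iterate: primal (z, mu), dual (lambda, nu), barrier tau.

    ``lam`` stacks the multipliers of the two inequality families,
    [lambda_1; lambda_2] for f_1 = z - mu and f_2 = -z - mu (length 2N).
    """

    z: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    nu: np.ndarray
    tau: float
    residual: np.ndarray | None = None
    surrogate_gap: float | None = None


@dataclass
class L1Result:
    z: np.ndarray
    iterations: int
    surrogate_gap: float
    converged: bool
    objective: float
    state: SolverState | None = None


@dataclass
class ReconstructionResult:
    coeffs: CoefficientMatrix
    frame: PressureFrame
    method: str
    iterations: int = 0
    final_gap: float = 0.0
    objective: float = 0.0
    converged: bool = True
    samples: SampleSet | None = field(default=None, repr=False)


def _entries(A: SensingMatrix | np.ndarray) -> np.ndarray:
    return A.entries if isinstance(A, SensingMatrix) else np.asarray(A, float)


def kkt_residual(
    state: SolverState, A: SensingMatrix | np.ndarray, b: np.ndarray, tau: float
) -> np.ndarray:
    """Relaxed-KKT residual r_tau, concatenated blocks (2N, 2N, M).

    Block 1 is dual feasibility over the joint primal (z, mu); block 2 the
    relaxed centering condition -lambda o f - (1/tau) 1; block 3 is Az - b.
    """
    Amat = _entries(A)
    M, N = Amat.shape
    z, mu = state.z, state.mu
    if z.shape != (N,) or mu.shape != (N,) or state.lam.shape != (2 * N,):
        raise ValueError("state dimensions inconsistent with A")
    if state.nu.shape != (M,) or b.shape != (M,):
        raise ValueError("dual/measurement dimensions inconsistent with A")
    lam1, lam2 = state.lam[:N], state.lam[N:]
    f1 = z - mu
    f2 = -z - mu
    r_dual = np.concatenate([lam1 - lam2 + Amat.T @ state.nu,
                             1.0 - lam1 - lam2])
    r_cent = np.concatenate([-lam1 * f1, -lam2 * f2]) - 1.0 / tau
    r_pri = Amat @ z - b
    return np.concatenate([r_dual, r_cent, r_pri])


def solve_l1(
    A: SensingMatrix | np.ndarray, b: np.ndarray, config: SolverConfig | None = None
) -> L1Result:
    """Minimize ||z||_1 subject to A z = b (M <= N, A full row rank).

    Starts from the minimum-norm feasible point z0 = A'(AA')^{-1} b with
    slacks mu0 = max(0.95 |z0| + 0.10 max|z0|, floor), and iterates damped
    Newton steps on the relaxed KKT system until the surrogate duality gap
    drops below ``config.gap_tol`` or ``config.max_iters`` is reached (the
    latter flags ``converged=False`` rather than failing silently).
    """
    if config is None:
        config = SolverConfig()
    Amat = _entries(A)
    b = np.asarray(b, dtype=float)
    M, N = Amat.shape
    if b.shape != (M,):
        raise ValueError(f"b must have length {M}")
    if not np.all(np.isfinite(b)):
        raise ValueError("b must be finite")

    AAt = Amat @ Amat.T
    try:
        cho = scipy.linalg.cho_factor(AAt)
    except scipy.linalg.LinAlgError as exc:
        raise RankDeficientSensingError(
            "sensing matrix rows are linearly dependent; regenerate the "
            "address plan with a different seed"
        ) from exc
    z = Amat.T @ scipy.linalg.cho_solve(cho, b)

    absz = np.abs(z)
    zmax = float(absz.max()) if N else 0.0
    floor = 1e-3 * zmax if zmax > 0 else 1e-3
    mu = np.maximum(0.95 * absz + 0.10 * zmax, floor)
    f1 = z - mu
    f2 = -z - mu
    lam1 = -1.0 / f1
    lam2 = -1.0 / f2
    nu = -Amat @ (lam1 - lam2)

    eta = float(-(f1 @ lam1 + f2 @ lam2))
    iterations = 0
    converged = eta < config.gap_tol
    tau = config.tau_growth * 2 * N / eta if eta > 0 else np.inf

    while not converged and iterations < config.max_iters:
        tau = config.tau_growth * 2 * N / eta
        inv_f1, inv_f2 = 1.0 / f1, 1.0 / f2
        Atnu = Amat.T @ nu
        r_dual = np.concatenate([lam1 - lam2 + Atnu, 1.0 - lam1 - lam2])
        r_cent = np.concatenate([-lam1 * f1, -lam2 * f2]) - 1.0 / tau
        r_pri = Amat @ z - b
        res_norm = np.sqrt(
            r_dual @ r_dual + r_cent @ r_cent + r_pri @ r_pri
        )

        # Reduced Newton system: eliminate (dlam1, dlam2) then dmu.
        w1 = (1.0 / tau) * (inv_f1 - inv_f2) - Atnu
        w2 = -1.0 - (1.0 / tau) * (inv_f1 + inv_f2)
        w3 = -r_pri
        a1 = lam1 * inv_f1  # negative
        a2 = lam2 * inv_f2  # negative
        sig1 = -(a1 + a2)
        sig2 = a1 - a2
        # sig1 - sig2^2 / sig1 in cancellation-free form:
        sigx = 4.0 * a1 * a2 / sig1
        rhs = Amat @ ((w1 - w2 * sig2 / sig1) / sigx) - w3
        # H = A diag(1/sigx) A' = (A w)(A w)' with w = sigx^{-1/2} > 0;
        # symmetric rank-k update fills the upper triangle at half cost,
        # which is all the (upper-triangular) solvers below read.
        # (passing the transposed view keeps BLAS in Fortran order, no copy)
        H = dsyrk(1.0, (Amat * np.sqrt(1.0 / sigx)).T, trans=1)
        # Jacobi-scaled Cholesky: the weights 1/sigx span many orders of
        # magnitude near convergence, and scaling keeps H factorable longer.
        d = np.sqrt(np.diag(H))
        try:
            choH = scipy.linalg.cho_factor(H / d[:, None] / d[None, :])
            dnu = scipy.linalg.cho_solve(choH, rhs / d) / d
        except (scipy.linalg.LinAlgError, ValueError):
            try:
                with warnings.catch_warnings():
                    # ill-conditioning is expected here; handled below
                    warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                    dnu = scipy.linalg.solve(H, rhs, assume_a="sym")
            except (scipy.linalg.LinAlgError, ValueError):
                # Keep the last strictly interior iterate instead of
                # stepping into numerical noise.
                break
        dz = (w1 - w2 * sig2 / sig1 - Amat.T @ dnu) / sigx
        dmu = (w2 - sig2 * dz) / sig1
        dlam1 = (lam1 * inv_f1) * (-dz + dmu) - lam1 - (1.0 / tau) * inv_f1
        dlam2 = (lam2 * inv_f2) * (dz + dmu) - lam2 - (1.0 / tau) * inv_f2

        # Largest step keeping lambda > 0 and f < 0 strictly.
        s = 1.0
        for val, dval in ((lam1, dlam1), (lam2, dlam2)):
            neg = dval < 0
            if np.any(neg):
                s = min(s, float(np.min(-val[neg] / dval[neg])))
        df1 = dz - dmu
        df2 = -dz - dmu
        for fval, dfval in ((f1, df1), (f2, df2)):
            pos = dfval > 0
            if np.any(pos):
                s = min(s, float(np.min(-fval[pos] / dfval[pos])))
        s *= 0.99

        Adz = Amat @ dz
        Atdnu = Amat.T @ dnu
        accepted = False
        for _ in range(32):
            z_n = z + s * dz
            mu_n = mu + s * dmu
            lam1_n = lam1 + s * dlam1
            lam2_n = lam2 + s * dlam2
            f1_n = z_n - mu_n
            f2_n = -z_n - mu_n
            r_dual_n = np.concatenate(
                [lam1_n - lam2_n + Atnu + s * Atdnu, 1.0 - lam1_n - lam2_n]
            )
            r_cent_n = np.concatenate([-lam1_n * f1_n, -lam2_n * f2_n]) - 1.0 / tau
            r_pri_n = r_pri + s * Adz
            new_norm = np.sqrt(
                r_dual_n @ r_dual_n + r_cent_n @ r_cent_n + r_pri_n @ r_pri_n
            )
            if new_norm <= (1.0 - config.ls_alpha * s) * res_norm:
                accepted = True
                break
            s *= config.ls_beta
        if not accepted:
            break  # stalled line search; report the last interior iterate

        z, mu, lam1, lam2 = z_n, mu_n, lam1_n, lam2_n
        nu = nu + s * dnu
        f1, f2 = f1_n, f2_n
        iterations += 1
        eta = float(-(f1 @ lam1 + f2 @ lam2))
        converged = eta < config.gap_tol

    state = SolverState(
        z=z, mu=mu, lam=np.concatenate([lam1, lam2]), nu=nu, tau=float(tau),
        surrogate_gap=eta,
    )
    state.residual = kkt_residual(state, Amat, b, float(tau))
    if not converged:
        warnings.warn(
            f"L1 solver stopped at gap {eta:.3g} after {iterations} iterations "
            f"(tolerance {config.gap_tol:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return L1Result(
        z=z,
        iterations=iterations,
        surrogate_gap=eta,
        converged=converged,
        objective=float(np.abs(z).sum()),
        state=state,
    )


def solve_l1_linprog(A: SensingMatrix | np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact basis-pursuit reference via linear programming.

    Splits z = zp - zn with zp, zn >= 0 and solves
    min 1'(zp + zn) s.t. [A, -A][zp; zn] = b with the HiGHS simplex/IPM.
    Independent of the in-package interior-point solver; used as an oracle.
    """
    Amat = _entries(A)
    M, N = Amat.shape
    res = linprog(
        c=np.ones(2 * N),
        A_eq=np.hstack([Amat, -Amat]),
        b_eq=np.asarray(b, float),
        bounds=[(0, None)] * (2 * N),
        method="highs",
    )
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"LP reference failed: {res.message}")
    return res.x[:N] - res.x[N:]


def reconstruct_frame(
    samples: SampleSet,
    config: SolverConfig | None = None,
    cleanup: bool = False,
    cleanup_fraction: float = 0.01,
) -> ReconstructionResult:
    """Recover a full frame from sub-sampled voltages by basis pursuit + 2D-IDCT.

    With ``cleanup`` on, cells below ``cleanup_fraction * max(frame)`` and
    negative cells are zeroed, suppressing the faint speckle basis pursuit
    leaves in unloaded regions of the mat (use for display; metrics are
    computed on raw reconstructions).
    """
    plan = samples.plan
    A = build_sensing_matrix(plan)
    result = solve_l1(A, samples.values, config)
    coeffs = CoefficientMatrix(result.z.reshape(plan.P, plan.Q))
    frame = idct2(coeffs)
    if cleanup:
        values = frame.values.copy()
        values[values < 0] = 0.0
        peak = values.max()
        if peak > 0:
            values[values < cleanup_fraction * peak] = 0.0
        frame = PressureFrame(values, v_max=frame.v_max, validate=False)
    return ReconstructionResult(
        coeffs=coeffs,
        frame=frame,
        method="cs",
        iterations=result.iterations,
        final_gap=result.surrogate_gap,
        objective=result.objective,
        converged=result.converged,
        samples=samples,
    )


def interpolate_frame(samples: SampleSet) -> ReconstructionResult:
    """Baseline: triangulated linear interpolation of the sampled cells.

    Values inside the convex hull of the sample addresses come from
    barycentric interpolation on a Delaunay triangulation; cells outside
    the hull take the nearest sampled value.  Exact at sampled cells.
    """
    plan = samples.plan
    if plan.M < 3:
        raise DegenerateGeometryError("triangulation needs at least 3 samples")
    pts = plan.addresses.astype(float)
    gx, gy = np.meshgrid(
        np.arange(1, plan.P + 1), np.arange(1, plan.Q + 1), indexing="ij"
    )
    try:
        values = griddata(pts, samples.values, (gx, gy), method="linear")
    except QhullError as exc:
        raise DegenerateGeometryError(
            "sample addresses are collinear; cannot triangulate"
        ) from exc
    if np.isnan(values).all():
        raise DegenerateGeometryError(
            "sample addresses are collinear; cannot triangulate"
        )
    hole = np.isnan(values)
    if hole.any():
        nearest = NearestNDInterpolator(pts, samples.values)
        values[hole] = nearest(gx[hole], gy[hole])
    frame = PressureFrame(values, validate=False)
    from .sparse_transform import dct2  # local: avoid import-order clutter

    return ReconstructionResult(
        coeffs=dct2(frame),
        frame=frame,
        method="interpolation",
        samples=samples,
    )
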