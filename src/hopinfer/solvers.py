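"""Iterative mean-field solvers for Hopfield magnetizations.

Three update schemes for the local magnetizations m_i of a Hopfield model
with coupling J at inverse temperature beta and load alpha (number of
rank-1 components per site: alpha = P/N in the direct problem, alpha = M/N
when solving the dual/posterior problem where the M samples act as
patterns):

* naive-parallel TAP:
    m_i^{t+1} = tanh( beta sum_j J_ij m_j^t
                      - alpha beta / (1 - beta (1 - q^t)) * m_i^t ),
  with N q^t = sum_i (m_i^t)^2, all sites updated simultaneously.

* parallel AMP (time indices from belief propagation):
    H_i^{t+1} = (1-u^t)^{-1} [ sum_{j!=i} J_ij m_j^t - u^t H_i^t
                               - alpha u^t / (1-u^{t-1}) m_i^{t-1} ],
    m_i^t = tanh(beta H_i^t),  u^t = beta (1 - q^t),
  also available sequentially with damping d (m <- (1-d) tanh(beta H) + d m).

* dynamical-TAP (single-instance dynamical mean-field scheme):
    z_i^t = A_t (sum_j J_ij m_j^t - m_i^t) + alpha (1-q^t) A_t z_i^{t-1},
    m_i^{t+1} = tanh(z_i^t + A_t m_i^t),     A_t = beta / (1 + alpha u_t).

Linearizing around the paramagnet m = 0 gives the growth factor beta*lambda
per eigenmode of J for TAP (and dynamical-TAP), hence instability at
beta = 1/lambda_max, while AMP's factor beta(lambda-1)/(1-beta) makes the
*bulk* (lambda = 0) modes — orthogonal to the patterns — unstable first, at
beta = 1/2 for a Hebbian coupling in the small-load limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import CouplingMatrix, as_rng, _coupling_array

__all__ = [
    "NumericalSingularityError",
    "TAPState",
    "AMPState",
    "DMFTState",
    "SolverResult",
    "tap_parallel_step",
    "amp_parallel_step",
    "amp_init",
    "amp_sequential_damped",
    "dmft_step",
    "dmft_init",
    "random_init",
    "iterate",
    "tap_iterate_batch",
    "linear_stability_threshold",
    "convergence_probability",
]

_SING_TOL = 1e-8


class NumericalSingularityError(ArithmeticError):
    """An Onsager/AMP denominator came within 1e-8 of zero."""


def _self_overlap(m: np.ndarray) -> float:
    return float(np.mean(m * m))


@dataclass(frozen=True)
class TAPState:
    m: np.ndarray
    q: float
    t: int = 0

    @classmethod
    def from_m(cls, m: np.ndarray, t: int = 0) -> "TAPState":
        m = np.asarray(m, dtype=np.float64)
        return cls(m=m, q=_self_overlap(m), t=t)


@dataclass(frozen=True)
class AMPState:
    H: np.ndarray
    m: np.ndarray
    u_curr: float
    u_prev: float
    m_prev: np.ndarray
    t: int = 0


@dataclass(frozen=True)
class DMFTState:
    m: np.ndarray
    z_prev: np.ndarray
    A: float
    t: int = 0


@dataclass(frozen=True)
class SolverResult:
    m_final: np.ndarray
    converged: bool
    iterations: int
    residual: float


def tap_parallel_step(
    state: TAPState, J: CouplingMatrix | np.ndarray, beta: float, alpha: float
) -> TAPState:
    """One synchronous TAP update (sum over all j, Hebbian diagonal kept)."""
    Jm = _coupling_array(J)
    den = 1.0 - beta * (1.0 - state.q)
    if abs(den) < _SING_TOL:
        raise NumericalSingularityError(
            f"Onsager denominator 1 - beta(1-q) = {den:.3e} at t={state.t}")
    m_new = np.tanh(beta * (Jm @ state.m) - (alpha * beta / den) * state.m)
    return TAPState(m=m_new, q=_self_overlap(m_new), t=state.t + 1)


def amp_init(m0: np.ndarray, beta: float) -> AMPState:
    """Bootstrap at t=0: m^{-1} = 0, u^{-1} = beta (i.e. q^{-1} = 0).

    H^0 is fixed by m^0 = tanh(beta H^0); |m0| is clipped to 1 - 1e-12 so
    magnitude-1 initial conditions are well-defined.
    """
    m0 = np.clip(np.asarray(m0, dtype=np.float64), -1 + 1e-12, 1 - 1e-12)
    q0 = _self_overlap(m0)
    return AMPState(
        H=np.arctanh(m0) / beta,
        m=m0,
        u_curr=beta * (1.0 - q0),
        u_prev=beta,
        m_prev=np.zeros_like(m0),
        t=0,
    )


def amp_parallel_step(
    state: AMPState, J: CouplingMatrix | np.ndarray, beta: float, alpha: float
) -> AMPState:
    """One synchronous AMP update (the j = i term is excluded)."""
    Jm = _coupling_array(J)
    u, u_prev = state.u_curr, state.u_prev
    if abs(1.0 - u) < _SING_TOL or abs(1.0 - u_prev) < _SING_TOL:
        raise NumericalSingularityError(f"1 - u = {1.0 - u:.3e} at t={state.t}")
    cavity = Jm @ state.m - np.diag(Jm) * state.m
    H_new = (cavity - u * state.H - (alpha * u / (1.0 - u_prev)) * state.m_prev) / (
        1.0 - u)
    m_new = np.tanh(beta * H_new)
    u_new = beta * (1.0 - _self_overlap(m_new))
    return AMPState(H=H_new, m=m_new, u_curr=u_new, u_prev=u,
                    m_prev=state.m, t=state.t + 1)


def amp_sequential_damped(
    J: CouplingMatrix | np.ndarray,
    beta: float,
    alpha: float,
    d: float = 0.95,
    init: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 2000,
    rng: int | np.random.Generator | None = None,
    onsager_clamp: float = 10.0,
) -> SolverResult:
    """Sequential damped solver of the AMP fixed-point equations.

    At an AMP fixed point the time-index memory resolves to the cavity
    field H_i = sum_{j!=i} J_ij m_j - [alpha u/(1-u)] m_i with
    u = beta(1-q).  Spins are visited one at a time in index order with
    the damped mixing rule m_i <- (1-d) tanh(beta H_i) + d m_i, and u is
    refreshed once per sweep.  Sequential trajectories cross the singular
    shell u = 1 quasi-statically, so the (transient) Onsager ratio
    u/(1-u) is clamped to ``onsager_clamp`` in magnitude; at any fixed
    point the ratio is small and the clamp inactive.

    The stopping rule is mean |tanh(beta H^{t+1}) - tanh(beta H^t)| < tol.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError("damping must be in [0, 1)")
    Jm = _coupling_array(J)
    N = Jm.shape[0]
    if init is None:
        init = random_init(N, 1.0, 1.0, as_rng(rng))
    m = np.clip(np.asarray(init, dtype=np.float64), -1 + 1e-12, 1 - 1e-12).copy()
    diag = np.diag(Jm)
    H = np.arctanh(m) / beta
    th_old = np.tanh(beta * H)
    residual = np.inf
    for it in range(1, max_iter + 1):
        u = beta * (1.0 - _self_overlap(m))
        ratio = u / (1.0 - u) if abs(1.0 - u) > 1e-12 else np.inf
        onsager = alpha * float(np.clip(ratio, -onsager_clamp, onsager_clamp))
        for i in range(N):
            H[i] = Jm[i] @ m - diag[i] * m[i] - onsager * m[i]
            m[i] = (1.0 - d) * np.tanh(beta * H[i]) + d * m[i]
        th_new = np.tanh(beta * H)
        residual = float(np.mean(np.abs(th_new - th_old)))
        th_old = th_new
        if residual < tol:
            return SolverResult(m_final=m, converged=True, iterations=it,
                                residual=residual)
    return SolverResult(m_final=m, converged=False, iterations=max_iter,
                        residual=residual)


def dmft_init(m0: np.ndarray, beta: float, alpha: float) -> DMFTState:
    m0 = np.asarray(m0, dtype=np.float64)
    u0 = beta * (1.0 - _self_overlap(m0))
    return DMFTState(m=m0, z_prev=np.zeros_like(m0),
                     A=beta / (1.0 + alpha * u0), t=0)


def dmft_step(
    state: DMFTState, J: CouplingMatrix | np.ndarray, beta: float, alpha: float
) -> DMFTState:
    """One dynamical-TAP update with memory field z."""
    Jm = _coupling_array(J)
    m = state.m
    q = _self_overlap(m)
    u = beta * (1.0 - q)
    A = beta / (1.0 + alpha * u)
    z = A * (Jm @ m - m) + alpha * (1.0 - q) * A * state.z_prev
    m_new = np.tanh(z + A * m)
    return DMFTState(m=m_new, z_prev=z, A=A, t=state.t + 1)


def random_init(
    N: int,
    magnitude_low: float = 0.1,
    magnitude_high: float = 1.0,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """m_i = +-u with random sign, |m_i| uniform in [low, high]."""
    if not (0.0 < magnitude_low <= magnitude_high <= 1.0):
        raise ValueError("need 0 < low <= high <= 1")
    rng = as_rng(rng)
    mags = rng.uniform(magnitude_low, magnitude_high, size=N)
    signs = rng.choice([-1.0, 1.0], size=N)
    return mags * signs


def iterate(
    scheme: str,
    J: CouplingMatrix | np.ndarray,
    beta: float,
    alpha: float,
    init: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 2000,
    d: float = 0.95,
    rng: int | np.random.Generator | None = None,
) -> SolverResult:
    """Iterate a scheme until the mean |m^{t+1} - m^t| drops below tol.

    scheme is one of "tap", "amp" (parallel), "amp_seq" (sequential,
    damped) or "dmft".  Non-convergence returns the last state flagged,
    it never raises.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    if scheme == "amp_seq":
        return amp_sequential_damped(J, beta, alpha, d=d, init=init, tol=tol,
                                     max_iter=max_iter, rng=rng)
    init = np.asarray(init, dtype=np.float64)
    if scheme == "tap":
        state = TAPState.from_m(init)
        step = tap_parallel_step
    elif scheme == "amp":
        state = amp_init(init, beta)
        step = amp_parallel_step
    elif scheme == "dmft":
        state = dmft_init(init, beta, alpha)
        step = dmft_step
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    m_old = state.m
    residual = np.inf
    for it in range(1, max_iter + 1):
        state = step(state, J, beta, alpha)
        residual = float(np.mean(np.abs(state.m - m_old)))
        m_old = state.m
        if residual < tol:
            return SolverResult(m_final=state.m, converged=True, iterations=it,
                                residual=residual)
    return SolverResult(m_final=state.m, converged=False, iterations=max_iter,
                        residual=residual)


def tap_iterate_batch(
    J: CouplingMatrix | np.ndarray,
    beta: float,
    alpha: float,
    inits: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run K independent parallel-TAP iterations as one matrix recursion.

    Numerically identical to calling ``iterate("tap", ...)`` per row
    (each row has its own q and is frozen once its residual drops below
    tol), but a single dgemm per step instead of K dgemv's.

    Returns (finals (K,N), converged (K,), iterations (K,)).
    """
    Jm = _coupling_array(J)
    M = np.array(inits, dtype=np.float64, copy=True)
    K = M.shape[0]
    active = np.ones(K, dtype=bool)
    iters = np.full(K, max_iter, dtype=np.int64)
    converged = np.zeros(K, dtype=bool)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        sub = M[idx]
        q = np.mean(sub * sub, axis=1)
        den = 1.0 - beta * (1.0 - q)
        if np.any(np.abs(den) < _SING_TOL):
            raise NumericalSingularityError("Onsager denominator ~ 0 in batch")
        new = np.tanh(beta * (sub @ Jm) - (alpha * beta / den)[:, None] * sub)
        res = np.mean(np.abs(new - sub), axis=1)
        M[idx] = new
        done = res < tol
        for k, fin in zip(idx[done], [it] * int(done.sum())):
            iters[k] = fin
        converged[idx[done]] = True
        active[idx[done]] = False
    return M, converged, iters


def linear_stability_threshold(
    J: CouplingMatrix | np.ndarray, scheme: str = "tap"
) -> float:
    """Smallest beta at which the parallel update linearized at m=0 has
    spectral radius 1.

    TAP / dynamical-TAP: growth factor beta*lambda, threshold 1/lambda_max
    (infinity if lambda_max <= 0).  AMP: factor |beta(lambda-1)/(1-beta)|,
    threshold 1/(1 + max_lambda |lambda - 1|).
    """
    eigs = np.linalg.eigvalsh(_coupling_array(J))
    if scheme in ("tap", "dmft"):
        lam_max = float(eigs[-1])
        if lam_max <= 0:
            return np.inf
        return 1.0 / lam_max
    if scheme == "amp":
        spread = float(np.max(np.abs(eigs - 1.0)))
        if spread == 0.0:
            return np.inf
        return 1.0 / (1.0 + spread)
    raise ValueError(f"unknown scheme {scheme!r}")


def convergence_probability(
    scheme: str,
    N: int,
    P: int,
    beta: float,
    n_trials: int = 1000,
    overlap_threshold: float = 0.7,
    rng: int | np.random.Generator | None = None,
    alpha: float | None = None,
    init_magnitude: tuple[float, float] | None = None,
    tol: float = 1e-3,
    max_iter: int = 2000,
    d: float = 0.95,
) -> float:
    """Fraction of (pattern-set, init) trials converging to a pattern.

    Direct problem: fresh Hebbian coupling per trial, random initial
    magnetizations (magnitude 1 for TAP/AMP, 0.1 for dynamical-TAP which
    needs small inits at low temperature), success when the converged m
    has a unique max |overlap| with a pattern above the threshold (ties —
    mixture states — count as failure).
    """
    if n_trials < 1:
        raise ValueError("need n_trials >= 1")
    from .model import generate_teacher  # local import to avoid cycle noise

    rng = as_rng(rng)
    if alpha is None:
        alpha = P / N
    if init_magnitude is None:
        init_magnitude = (0.1, 0.1) if scheme == "dmft" else (1.0, 1.0)
    hits = 0
    for _ in range(n_trials):
        teacher = generate_teacher(N, P, beta, rng)
        J = teacher.coupling()
        init = random_init(N, *init_magnitude, rng)
        try:
            res = iterate(scheme, J, beta, alpha, init, tol=tol,
                          max_iter=max_iter, d=d, rng=rng)
        except NumericalSingularityError:
            continue
        if not res.converged:
            continue
        overlaps = np.abs(teacher.patterns @ res.m_final) / N
        top = np.max(overlaps)
        if top > overlap_threshold and np.sum(overlaps > top - 1e-9) == 1:
            hits += 1
    return hits / n_trials
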