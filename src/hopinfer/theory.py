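"""Closed-form diagnostics: Curie-Weiss thermodynamics, the pattern
orthogonality penalty phi(q), and spectral summaries of Hebbian couplings.

For P = 2 the intractable partition-function term of the pattern posterior
factorizes over the sites where the two patterns agree/disagree, each block
being a Curie-Weiss model at rescaled inverse temperature beta(1 +- q),
where Nq = sum_i xi^1_i xi^2_i is the mutual overlap.  The resulting
per-spin, per-sample penalty added to the negative log-posterior,

    phi(q) = (1+q)/2 * a(beta(1+q)) + (1-q)/2 * a(beta(1-q)),

with a(beta) the Curie-Weiss per-spin log-partition, is convex with its
minimum at q = 0: the term acts as a soft orthogonality regularizer on the
inferred patterns.

Sign convention: phi is built from the log-partition a(beta) = log Z / N
(so that larger phi means a larger penalty e^{-M N phi}).  Plugging in the
conventional free energy f = -a/beta instead flips/warps the curve and
moves the minimum away from q = 0, so the convex convention is the
operative one; ``curie_weiss_free_energy`` is still exposed separately
with the standard normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import CouplingMatrix, _coupling_array

__all__ = [
    "curie_weiss_magnetization",
    "curie_weiss_log_partition",
    "curie_weiss_free_energy",
    "phi",
    "phi_curve",
    "TheoryCurve",
    "spectral_summary",
]


def curie_weiss_magnetization(beta: float) -> float:
    """Positive root of m = tanh(beta m); 0 in the paramagnet (beta <= 1)."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    if beta <= 1.0:
        return 0.0
    # m - tanh(beta m) is negative just above 0 and positive at 1 for beta > 1
    return float(brentq(lambda m: m - np.tanh(beta * m), 1e-12, 1.0, xtol=1e-14))


def curie_weiss_log_partition(beta: float) -> float:
    """a(beta) = lim N^{-1} log Z = max_m [log 2cosh(beta m) - beta m^2 / 2]."""
    m = curie_weiss_magnetization(beta)
    bm = beta * m
    # log(2 cosh x) computed stably
    return float(np.logaddexp(bm, -bm) - beta * m * m / 2.0)


def curie_weiss_free_energy(beta: float) -> float:
    """Standard per-spin free energy f(beta) = -a(beta)/beta.

    Equals -log(2)/beta for beta <= 1 and tends to -1/2 as beta -> inf.
    """
    return -curie_weiss_log_partition(beta) / beta


def phi(q: float, beta: float) -> float:
    """Orthogonality penalty phi(q) for a pair of patterns at overlap q."""
    if not abs(q) < 1.0:
        raise ValueError("need |q| < 1")
    if not beta > 0:
        raise ValueError("beta must be positive")
    return float(
        0.5 * (1.0 + q) * curie_weiss_log_partition(beta * (1.0 + q))
        + 0.5 * (1.0 - q) * curie_weiss_log_partition(beta * (1.0 - q))
    )


@dataclass(frozen=True)
class TheoryCurve:
    q_grid: np.ndarray
    phi_values: np.ndarray
    beta: float

    def argmin(self) -> float:
        return float(self.q_grid[int(np.argmin(self.phi_values))])


def phi_curve(
    beta: float, q_max: float = 0.9, step: float = 0.01
) -> TheoryCurve:
    """Evaluate phi on the symmetric grid [-q_max, q_max] with given step."""
    n = int(round(q_max / step))
    grid = np.arange(-n, n + 1) * step
    values = np.array([phi(q, beta) for q in grid])
    return TheoryCurve(q_grid=grid, phi_values=values, beta=beta)


def spectral_summary(
    J: CouplingMatrix | np.ndarray, P: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split the spectrum into the P largest eigenvalues and the bulk.

    For a Hebbian coupling built from P near-orthogonal patterns the top
    block sits at 1 + O(sqrt(P/N)) and the bulk is exactly zero.
    """
    eigs = np.linalg.eigvalsh(_coupling_array(J))[::-1]
    return eigs[:P].copy(), eigs[P:].copy()
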