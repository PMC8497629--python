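"""Equilibrium sampling of the teacher's Boltzmann distribution.

Sequential heat-bath (Glauber) dynamics: one sweep visits the spins in
index order and resamples each from its conditional

    P(s_i = +1 | s_{-i}) = 1 / (1 + exp(-2 beta h_i)),   h_i = sum_{j!=i} J_ij s_j.

Datasets emulate the study conditions of the retrieval-phase experiments:
each recorded configuration comes from a fresh chain initialized at one of
the teacher's patterns (patterns cycled so states are equally represented)
and equilibrated for a fixed number of full sweeps, giving i.i.d. samples
with equal state weights.

The inner sweep loop is numba-compiled with incremental local-field
updates; all randomness is drawn from a numpy Generator outside the kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import CouplingMatrix, SpinDataset, TeacherModel, as_rng, _coupling_array

__all__ = ["SamplerConfig", "glauber_sweep", "sample_dataset"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Protocol knobs for dataset generation.

    sweeps_equilibration: full sequential sweeps before a chain is recorded
    (default 100; fresh chain per sample, so samples are independent).
    """

    sweeps_equilibration: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sweeps_equilibration < 1:
            raise ValueError("need at least one equilibration sweep")


@njit(cache=True)
def _run_sweeps(J, s, beta, uniforms):  # pragma: no cover - compiled
    N = s.shape[0]
    h = np.empty(N)
    for i in range(N):
        acc = 0.0
        for j in range(N):
            acc += J[i, j] * s[j]
        h[i] = acc - J[i, i] * s[i]
    for t in range(uniforms.shape[0]):
        for i in range(N):
            p = 1.0 / (1.0 + np.exp(-2.0 * beta * h[i]))
            new = 1.0 if uniforms[t, i] < p else -1.0
            if new != s[i]:
                ds = new - s[i]
                s[i] = new
                for j in range(N):
                    h[j] += J[j, i] * ds
                h[i] -= J[i, i] * ds


def glauber_sweep(
    s: np.ndarray,
    J: CouplingMatrix | np.ndarray,
    beta: float,
    rng: int | np.random.Generator,
    n_sweeps: int = 1,
) -> np.ndarray:
    """Run ``n_sweeps`` full sequential heat-bath sweeps; returns a new array.

    The self-coupling J_ii is excluded from the local field (it would only
    shift both spin states equally).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    Jm = np.ascontiguousarray(_coupling_array(J))
    s = np.asarray(s, dtype=np.float64).copy()
    if s.shape != (Jm.shape[0],):
        raise ValueError("configuration length does not match coupling size")
    rng = as_rng(rng)
    uniforms = rng.random((n_sweeps, s.shape[0]))
    _run_sweeps(Jm, s, float(beta), uniforms)
    return s


def sample_dataset(
    teacher: TeacherModel,
    M: int,
    config: SamplerConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> SpinDataset:
    """Draw M equilibrium configurations, states equally sampled.

    Chains are initialized at the teacher's patterns in round-robin order
    (sample a starts at pattern a mod P), so per-state counts differ by at
    most one when P does not divide M.
    """
    if M < 1:
        raise ValueError("need M >= 1")
    config = config or SamplerConfig()
    rng = as_rng(config.seed if rng is None else rng)
    J = np.ascontiguousarray(teacher.coupling().J)
    N, P = teacher.N, teacher.P
    if M % P != 0:
        log.warning("M=%d not divisible by P=%d; distributing remainder round-robin",
                    M, P)
    samples = np.empty((M, N))
    labels = np.empty(M, dtype=np.int64)
    for a in range(M):
        state = a % P
        s = teacher.patterns[state].copy()
        uniforms = rng.random((config.sweeps_equilibration, N))
        _run_sweeps(J, s, float(teacher.beta), uniforms)
        samples[a] = s
        labels[a] = state
    return SpinDataset(samples=samples, state_labels=labels)
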