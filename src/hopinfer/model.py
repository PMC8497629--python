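"""Hopfield teacher models, couplings and spin datasets.

The teacher is a Hopfield model over N binary spins built from P random
patterns zeta^mu in {-1,+1}^N through the Hebbian rule

    J_ij = N^{-1} sum_mu zeta^mu_i zeta^mu_j,

with Hamiltonian H(s) = -1/2 sum_ij J_ij s_i s_j and Boltzmann weight
exp(-beta H).  The student only ever sees equilibrium configurations of
this model; everything downstream (TAP students, deflation, RBM) consumes
the containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TeacherModel",
    "CouplingMatrix",
    "SpinDataset",
    "as_rng",
    "generate_teacher",
    "hebbian_coupling",
    "empirical_coupling",
    "hamiltonian",
    "deflate",
]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator (no global RNG state)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_pm1(a: np.ndarray, what: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if not np.all(np.abs(a) == 1.0):
        raise ValueError(f"{what} entries must be +1 or -1")
    return a


@dataclass(frozen=True)
class TeacherModel:
    """Ground truth of every synthetic experiment: P patterns and beta."""

    patterns: np.ndarray  # (P, N), entries +-1
    beta: float

    def __post_init__(self) -> None:
        pats = _check_pm1(self.patterns, "pattern")
        if pats.ndim != 2:
            raise ValueError("patterns must be a P x N matrix")
        P, N = pats.shape
        if P < 1 or N < 2:
            raise ValueError("need P >= 1 and N >= 2")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        object.__setattr__(self, "patterns", pats)

    @property
    def N(self) -> int:
        return self.patterns.shape[1]

    @property
    def P(self) -> int:
        return self.patterns.shape[0]

    def coupling(self) -> "CouplingMatrix":
        return hebbian_coupling(self.patterns)


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric N x N coupling.

    ``diagonal_included`` records whether J_ii carries the Hebbian
    self-term P/N (couplings built here keep it; each solver decides
    whether its update sums over j = i).
    """

    J: np.ndarray
    diagonal_included: bool = True

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=np.float64)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("coupling must be a square matrix")
        if not np.all(np.isfinite(J)):
            raise ValueError("coupling entries must be finite")
        if not np.array_equal(J, J.T):
            raise ValueError("coupling must be exactly symmetric")
        object.__setattr__(self, "J", J)

    @property
    def n(self) -> int:
        return self.J.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues in descending order."""
        return np.linalg.eigvalsh(self.J)[::-1]


def _coupling_array(J: "CouplingMatrix | np.ndarray") -> np.ndarray:
    if isinstance(J, CouplingMatrix):
        return J.J
    return CouplingMatrix(np.asarray(J, dtype=np.float64)).J


@dataclass(frozen=True)
class SpinDataset:
    """M sampled configurations, the only observable handed to students."""

    samples: np.ndarray  # (M, N), entries +-1
    state_labels: np.ndarray | None = None  # which teacher state seeded each chain

    def __post_init__(self) -> None:
        s = _check_pm1(self.samples, "sample")
        if s.ndim != 2 or s.shape[0] < 1:
            raise ValueError("samples must be an M x N matrix with M >= 1")
        object.__setattr__(self, "samples", s)
        if self.state_labels is not None:
            labels = np.asarray(self.state_labels, dtype=np.int64)
            if labels.shape != (s.shape[0],):
                raise ValueError("state_labels must have one entry per sample")
            object.__setattr__(self, "state_labels", labels)

    @property
    def M(self) -> int:
        return self.samples.shape[0]

    @property
    def N(self) -> int:
        return self.samples.shape[1]


def generate_teacher(
    N: int, P: int, beta: float, seed: int | np.random.Generator
) -> TeacherModel:
    """Draw P independent uniform +-1 patterns of length N."""
    if N < 2 or P < 1:
        raise ValueError("need N >= 2 and P >= 1")
    if not beta > 0:
        raise ValueError("beta must be positive")
    rng = as_rng(seed)
    patterns = rng.choice([-1.0, 1.0], size=(P, N))
    return TeacherModel(patterns=patterns, beta=float(beta))


def hebbian_coupling(patterns: np.ndarray | TeacherModel) -> CouplingMatrix:
    """J = zeta^T zeta / N; rank <= P, trace = P, diagonal P/N kept."""
    if isinstance(patterns, TeacherModel):
        patterns = patterns.patterns
    pats = _check_pm1(patterns, "pattern")
    if pats.ndim == 1:
        pats = pats[None, :]
    if pats.size == 0:
        raise ValueError("empty pattern set")
    N = pats.shape[1]
    J = pats.T @ pats / N
    return CouplingMatrix(J=(J + J.T) / 2.0, diagonal_included=True)


def empirical_coupling(dataset: SpinDataset | np.ndarray) -> CouplingMatrix:
    """Data matrix J_ij = N^{-1} sum_a s^a_i s^a_j (normalized by N, not M).

    This is the initial condition J^{tau=0} of the deflation loop: on the
    dual problem the M samples play the role of patterns.
    """
    samples = dataset.samples if isinstance(dataset, SpinDataset) else np.asarray(dataset)
    samples = _check_pm1(samples, "sample")
    if samples.ndim == 1:
        samples = samples[None, :]
    N = samples.shape[1]
    J = samples.T @ samples / N
    return CouplingMatrix(J=(J + J.T) / 2.0, diagonal_included=True)


def hamiltonian(J: CouplingMatrix | np.ndarray, s: np.ndarray) -> float:
    """H(s) = -1/2 sum_ij J_ij s_i s_j (full double sum, diagonal included)."""
    Jm = _coupling_array(J)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (Jm.shape[0],):
        raise ValueError("configuration length does not match coupling size")
    return float(-0.5 * s @ Jm @ s)


def deflate(
    J: CouplingMatrix | np.ndarray, m: np.ndarray, gamma: float
) -> CouplingMatrix:
    """Remove a retrieved state's rank-1 part: J' = J - gamma/N * m m^T.

    gamma = M/P when states are uniformly represented in the data.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    Jm = _coupling_array(J)
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (Jm.shape[0],):
        raise ValueError("magnetization length does not match coupling size")
    if np.max(np.abs(m)) > 1.0 + 1e-9:
        raise ValueError("magnetizations must satisfy |m_i| <= 1")
    out = Jm - (gamma / Jm.shape[0]) * np.outer(m, m)
    diag = isinstance(J, CouplingMatrix) and J.diagonal_included
    return CouplingMatrix(J=(out + out.T) / 2.0, diagonal_included=diag)
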