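"""Restricted Boltzmann machine with binary visible and Gaussian hidden units.

Marginalizing standard-normal hidden units lambda_mu out of the energy
E = -sum_{i,mu} W_i^mu s_i lambda_mu reproduces the Hopfield Boltzmann
weight with W_i^mu = sqrt(beta/N) xi^mu_i, so training this RBM on spin
data is pattern inference up to a rotation in pattern space: the machine
can learn the subspace spanned by the teacher's patterns (its weight
matrix develops exactly P outlier singular values), but not the patterns
themselves.

Training is persistent contrastive divergence (PCD-k): stochastic gradient
ascent on the log-likelihood with the positive phase in closed form
(E[lambda|s] = W s, the Gaussian conditional mean) and the negative phase
estimated from persistent alternating-Gibbs chains advanced k steps per
update.  Learning is monitored by the pseudo-likelihood (the sum of
single-site conditional log-likelihoods, estimated with one hidden sample
per data point), the reconstruction error of beta^{-1} W^T W against the
teacher coupling when available, and the singular-value history of W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CouplingMatrix, SpinDataset, as_rng, _coupling_array
from .deflation import reconstruction_error

__all__ = [
    "RBMModel",
    "TrainConfig",
    "TrainMonitor",
    "SVDDiagnostics",
    "TrainingDivergedError",
    "sample_hidden",
    "sample_visible",
    "pcd_update",
    "train",
    "pseudo_likelihood",
    "coupling_from_weights",
    "svd_diagnostics",
    "count_emerged_modes",
]


class TrainingDivergedError(RuntimeError):
    """Weights exceeded the divergence guard; the monitor so far is attached."""

    def __init__(self, msg: str, monitor: "TrainMonitor"):
        super().__init__(msg)
        self.monitor = monitor


@dataclass(frozen=True)
class RBMModel:
    W: np.ndarray  # (N_h, N_v)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] < 1:
            raise ValueError("W must be an N_h x N_v matrix with N_h >= 1")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "W", W)

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 500
    minibatch: int = 100
    n_chains: int = 100
    cd_steps: int = 10
    seed: int | None = None
    # flattening stop: gain of the trailing `flat_window`-epoch mean of the
    # pseudo-likelihood over the previous window, relative to the total
    # improvement since epoch 0
    flat_window: int = 20
    flat_rtol: float = 0.002

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.cd_steps < 1 or self.minibatch < 1:
            raise ValueError("invalid training configuration")


@dataclass(frozen=True)
class TrainMonitor:
    pseudo_likelihood: np.ndarray  # per recorded epoch
    eps_vs_teacher: np.ndarray | None
    sigma_history: np.ndarray  # (epochs, N_h), singular values of W
    stopped_epoch: int


@dataclass(frozen=True)
class SVDDiagnostics:
    sigma: np.ndarray  # singular values of W, descending
    coeffs: np.ndarray  # (N_h, N) projections c_mu^alpha
    t_alpha: np.ndarray  # per-data-mode residual errors


def sample_hidden(
    model: RBMModel, s: np.ndarray, rng: int | np.random.Generator
) -> np.ndarray:
    """lambda_mu ~ Normal(sum_i W_i^mu s_i, 1), the exact conditional.

    Accepts a single configuration (N_v,) or a batch (B, N_v).
    """
    rng = as_rng(rng)
    s = np.asarray(s, dtype=np.float64)
    mean = s @ model.W.T
    return mean + rng.standard_normal(mean.shape)


def sample_visible(
    model: RBMModel, lam: np.ndarray, rng: int | np.random.Generator
) -> np.ndarray:
    """s_i = +1 with probability e^{h_i} / (2 cosh h_i), h = W^T lambda."""
    rng = as_rng(rng)
    lam = np.asarray(lam, dtype=np.float64)
    h = lam @ model.W
    p_up = 1.0 / (1.0 + np.exp(-2.0 * h))
    return np.where(rng.random(h.shape) < p_up, 1.0, -1.0)


def _gibbs(model: RBMModel, chains: np.ndarray, steps: int,
           rng: np.random.Generator) -> np.ndarray:
    for _ in range(steps):
        lam = sample_hidden(model, chains, rng)
        chains = sample_visible(model, lam, rng)
    return chains


def pcd_update(
    model: RBMModel,
    batch: np.ndarray,
    chains: np.ndarray,
    config: TrainConfig,
    rng: int | np.random.Generator,
) -> tuple[RBMModel, np.ndarray]:
    """One stochastic-gradient step W += lr (positive - negative).

    Positive phase <lambda_mu s_i>_D in closed form (batch mean of
    (W s) s^T); negative phase from the persistent chains advanced
    cd_steps alternating-Gibbs sweeps, with the hidden factor replaced by
    its conditional mean W s (same expectation, lower variance).
    """
    rng = as_rng(rng)
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2 or batch.shape[0] < 1:
        raise ValueError("batch must be non-empty")
    if chains.shape[0] != config.n_chains:
        raise ValueError("chain count does not match configuration")
    pos = (batch @ model.W.T).T @ batch / batch.shape[0]
    chains = _gibbs(model, chains, config.cd_steps, rng)
    neg = (chains @ model.W.T).T @ chains / chains.shape[0]
    W_new = model.W + config.learning_rate * (pos - neg)
    return RBMModel(W=W_new), chains


def pseudo_likelihood(
    model: RBMModel, dataset: SpinDataset | np.ndarray,
    rng: int | np.random.Generator,
) -> float:
    """S = sum_r M^{-1} sum_a log[ e^{s_r^a h_r} / (2 cosh h_r) ].

    h = W^T lambda with one hidden draw lambda ~ P(lambda | s^a, W) per
    sample.  Always <= 0; exactly -N_v log 2 at W = 0.
    """
    rng = as_rng(rng)
    S = dataset.samples if isinstance(dataset, SpinDataset) else np.asarray(dataset)
    lam = sample_hidden(model, S, rng)
    h = lam @ model.W
    # log(2 cosh h) = logaddexp(h, -h), stable for large |h|
    per_site = S * h - np.logaddexp(h, -h)
    return float(np.sum(np.mean(per_site, axis=0)))


def coupling_from_weights(model: RBMModel, beta: float) -> CouplingMatrix:
    """J^r = beta^{-1} W^T W, invariant under hidden-space rotations of W."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    J = model.W.T @ model.W / beta
    return CouplingMatrix(J=(J + J.T) / 2.0, diagonal_included=True)


def svd_diagnostics(model: RBMModel, dataset: SpinDataset) -> SVDDiagnostics:
    """Project every data mode onto the span of W's singular vectors.

    D (N x M, one sample per column) and W^T are decomposed by SVD;
    c_mu^alpha = <u^(mu),W , u^(alpha),D> and t_alpha = sum_i |e^alpha_i| /
    sum_i |u^(alpha),D_i| measures what the weight subspace misses of data
    mode alpha.  Degenerate singular values follow LAPACK's ordering
    convention.
    """
    if model.n_visible != dataset.N:
        raise ValueError("visible layer size does not match dataset")
    D = dataset.samples.T  # (N, M)
    U_D, _, _ = np.linalg.svd(D, full_matrices=False)  # (N, min(N, M))
    U_W, sigma, _ = np.linalg.svd(model.W.T, full_matrices=False)  # (N, N_h)
    coeffs = U_W.T @ U_D  # (N_h, n_modes)
    resid = U_D - U_W @ coeffs
    t_alpha = np.sum(np.abs(resid), axis=0) / np.sum(np.abs(U_D), axis=0)
    return SVDDiagnostics(sigma=sigma, coeffs=coeffs, t_alpha=t_alpha)


def count_emerged_modes(
    sigma: np.ndarray, n_bulk: int | None = None, factor: float = 3.0
) -> int:
    """Singular values separated from the bulk.

    The bulk scale is the median of the trailing ``n_bulk`` singular
    values (default max(2, N_h // 3)); a mode has emerged when it exceeds
    ``factor`` times that scale.
    """
    sigma = np.sort(np.asarray(sigma, dtype=np.float64))[::-1]
    if n_bulk is None:
        n_bulk = max(2, sigma.size // 3)
    bulk = float(np.median(sigma[-n_bulk:]))
    return int(np.sum(sigma > factor * bulk))


def train(
    dataset: SpinDataset,
    n_hidden: int,
    config: TrainConfig | None = None,
    teacher_J: CouplingMatrix | np.ndarray | None = None,
    beta: float | None = None,
    rng: int | np.random.Generator | None = None,
) -> tuple[RBMModel, TrainMonitor]:
    """Minibatch PCD training with per-epoch monitors.

    Stops early once the pseudo-likelihood flattens (window-mean gain
    below flat_rtol x total improvement) or after config.epochs.  Passing
    teacher_J (with beta) also records the reconstruction error of
    beta^{-1} W^T W per epoch.  Raises TrainingDivergedError if any
    |W| > 1e3.
    """
    config = config or TrainConfig()
    rng = as_rng(config.seed if rng is None else rng)
    S = dataset.samples
    M, N = S.shape
    if config.minibatch > M:
        raise ValueError("minibatch larger than dataset")
    if teacher_J is not None and beta is None:
        raise ValueError("beta is required to compare against a teacher coupling")

    W = rng.normal(0.0, 0.01 / np.sqrt(N), size=(n_hidden, N))
    model = RBMModel(W=W)
    chains = rng.choice([-1.0, 1.0], size=(config.n_chains, N))

    pl_hist: list[float] = []
    eps_hist: list[float] = []
    sig_hist: list[np.ndarray] = []
    w = config.flat_window
    epoch = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(M)
        for start in range(0, M - config.minibatch + 1, config.minibatch):
            batch = S[order[start:start + config.minibatch]]
            model, chains = pcd_update(model, batch, chains, config, rng)
        if np.max(np.abs(model.W)) > 1e3:
            monitor = TrainMonitor(np.array(pl_hist),
                                   np.array(eps_hist) if teacher_J is not None else None,
                                   np.array(sig_hist), epoch)
            raise TrainingDivergedError("weights diverged", monitor)
        pl_hist.append(pseudo_likelihood(model, dataset, rng))
        sig_hist.append(np.linalg.svd(model.W, compute_uv=False))
        if teacher_J is not None:
            eps_hist.append(
                reconstruction_error(coupling_from_weights(model, beta), teacher_J))
        if len(pl_hist) >= 2 * w:
            gain = float(np.mean(pl_hist[-w:]) - np.mean(pl_hist[-2 * w:-w]))
            total = float(max(pl_hist) - pl_hist[0])
            if total > 0 and gain < config.flat_rtol * total:
                break
    monitor = TrainMonitor(
        pseudo_likelihood=np.array(pl_hist),
        eps_vs_teacher=np.array(eps_hist) if teacher_J is not None else None,
        sigma_history=np.array(sig_hist) if sig_hist else np.empty((0, n_hidden)),
        stopped_epoch=epoch,
    )
    return model, monitor
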