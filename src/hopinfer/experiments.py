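"""Reproducible experiment recipes.

Each recipe regenerates one of the package's standard teacher-student
experiments end to end (teacher -> Glauber data -> inference -> metrics)
and writes plain TSV tables plus a JSON summary of every parameter used.
Recipe defaults are the full study conditions; ``scale`` shrinks N, M and
trial counts proportionally for quick runs (system sizes are floored at
values where the phases are still recognizable).

Recipes
-------
single_pattern_overlap   teacher-student overlap vs M at several beta (P=1, dual TAP)
retrieval_overlaps       per-round best-student overlaps vs all teacher patterns
deflation_traces         (tau, score, L_hat, eps) traces for several M
error_vs_load            mean stopped-round eps vs M/P on a beta grid
rbm_monitors             RBM pseudo-likelihood/error/singular-value history
trajectory_dump          TAP vs parallel-AMP magnetization trajectories
convergence_map          P_c(beta) for the three schemes
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .model import as_rng, empirical_coupling, generate_teacher, hebbian_coupling
from .sampler import SamplerConfig, sample_dataset
from .solvers import (
    TAPState,
    amp_init,
    amp_parallel_step,
    convergence_probability,
    iterate,
    random_init,
    tap_parallel_step,
)
from .deflation import match_to_teacher, retrieve_patterns
from .rbm import TrainConfig, train

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_recipe", "RECIPES"]


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    parameters: dict = field(default_factory=dict)
    output_dir: str | Path = "."
    seed: int = 0
    scale: float = 1.0


def _outdir(config: ExperimentConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.10g}" if isinstance(v, float) else str(v)
                              for v in row) + "\n")


def _summary(config: ExperimentConfig, params: dict, outputs: list[str]) -> dict:
    rec = {
        "recipe": config.name,
        "seed": config.seed,
        "scale": config.scale,
        "parameters": params,
        "outputs": outputs,
    }
    with open(_outdir(config) / f"{config.name}_summary.json", "w") as fh:
        json.dump(rec, fh, indent=2, default=str)
    return rec


def _scaled(value: int, scale: float, floor: int) -> int:
    return max(floor, int(round(value * scale)))


def single_pattern_overlap(config: ExperimentConfig) -> dict:
    """Overlap of the dual-TAP solution with the teacher pattern vs M.

    P = 1: below beta = 1 reconstruction needs an extensive number of
    samples, above it a handful suffices.
    """
    p = dict(N=1000, betas=(0.5, 0.8, 1.5, 2.0), M_grid=(1, 10, 50, 100, 500),
             trials=10, sweeps=100)
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 50)
    trials = _scaled(p["trials"], config.scale, 1)
    rng = as_rng(config.seed)
    rows = []
    for beta in p["betas"]:
        for M in p["M_grid"]:
            acc = []
            for _ in range(trials):
                teacher = generate_teacher(N, 1, beta, rng)
                ds = sample_dataset(teacher, M, SamplerConfig(p["sweeps"]), rng)
                J0 = empirical_coupling(ds)
                res = iterate("tap", J0, beta, M / N,
                              random_init(N, 0.1, 1.0, rng), tol=1e-3)
                acc.append(abs(res.m_final @ teacher.patterns[0]) / N)
            rows.append([beta, M, float(np.mean(acc)), float(np.std(acc))])
    out = _outdir(config) / "single_pattern_overlap.tsv"
    _write_tsv(out, ["beta", "M", "mean_overlap", "sd_overlap"], rows)
    return _summary(config, {**p, "N_used": N, "trials_used": trials}, [out.name])


def retrieval_overlaps(config: ExperimentConfig) -> dict:
    """Best-student overlap with every teacher pattern, round by round."""
    p = dict(N=1000, P=20, M=200, beta=2.0, n_students=25, sweeps=100)
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 100)
    M = _scaled(p["M"], config.scale, 4 * p["P"])
    rng = as_rng(config.seed)
    teacher = generate_teacher(N, p["P"], p["beta"], rng)
    ds = sample_dataset(teacher, M, SamplerConfig(p["sweeps"]), rng)
    trace = retrieve_patterns(ds, p["beta"], gamma=M / p["P"],
                              n_students=p["n_students"], rng=rng)
    rows = []
    for tau, m in enumerate(trace.retrieved, start=1):
        ov = np.abs(m @ teacher.patterns.T) / N
        rows.append([tau] + [float(o) for o in ov])
    out = _outdir(config) / "retrieval_overlaps.tsv"
    _write_tsv(out, ["tau"] + [f"q_pattern{mu}" for mu in range(p["P"])], rows)
    report = match_to_teacher(trace, teacher)
    return _summary(config, {**p, "N_used": N, "M_used": M,
                             "n_recovered": report.n_recovered}, [out.name])


def deflation_traces(config: ExperimentConfig) -> dict:
    """Score / simplified-likelihood / error traces for several M."""
    p = dict(N=1000, P=20, beta=2.0, M_list=(100, 200, 500, 1000),
             n_students=25, sweeps=100)
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 100)
    rng = as_rng(config.seed)
    teacher = generate_teacher(N, p["P"], p["beta"], rng)
    J_star = hebbian_coupling(teacher)
    outputs = []
    for M in p["M_list"]:
        M = _scaled(M, config.scale, 4 * p["P"])
        ds = sample_dataset(teacher, M, SamplerConfig(p["sweeps"]), rng)
        trace = retrieve_patterns(ds, p["beta"], gamma=M / p["P"],
                                  n_students=p["n_students"], rng=rng,
                                  teacher_J=J_star)
        rows = [[tau + 1, float(trace.scores[tau]), float(trace.L_hat[tau]),
                 float(trace.eps[tau])] for tau in range(len(trace.retrieved))]
        out = _outdir(config) / f"deflation_trace_M{M}.tsv"
        _write_tsv(out, ["tau", "best_score", "L_hat", "eps"], rows)
        outputs.append(out.name)
    return _summary(config, {**p, "N_used": N}, outputs)


def error_vs_load(config: ExperimentConfig) -> dict:
    """Mean stopped-round reconstruction error vs M/P at several beta."""
    p = dict(N=1000, P=10, betas=(0.5, 1.0, 2.0), M_over_P=(5, 10, 20, 50),
             trials=100, sweeps=100)
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 100)
    trials = _scaled(p["trials"], config.scale, 2)
    P = p["P"]
    rng = as_rng(config.seed)
    rows = []
    for beta in p["betas"]:
        for ratio in p["M_over_P"]:
            M = int(ratio * P)
            errs = []
            for _ in range(trials):
                teacher = generate_teacher(N, P, beta, rng)
                ds = sample_dataset(teacher, M, SamplerConfig(p["sweeps"]), rng)
                trace = retrieve_patterns(ds, beta, gamma=M / P,
                                          n_students=2 * P, rng=rng,
                                          teacher_J=hebbian_coupling(teacher))
                if len(trace.retrieved) == 0:
                    errs.append(1.0)  # nothing retrieved: J_rec = 0
                else:
                    errs.append(float(trace.eps[trace.tau_stop - 1]))
            rows.append([beta, ratio, float(np.mean(errs)), float(np.std(errs))])
    out = _outdir(config) / "error_vs_load.tsv"
    _write_tsv(out, ["beta", "M_over_P", "mean_eps", "sd_eps"], rows)
    return _summary(config, {**p, "N_used": N, "trials_used": trials}, [out.name])


def rbm_monitors(config: ExperimentConfig) -> dict:
    """RBM training monitors at the 15-hidden-unit setting."""
    p = dict(N=1000, P=10, M=1000, beta=2.0, n_hidden=15, sweeps=100)
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 100)
    M = _scaled(p["M"], config.scale, 100)
    rng = as_rng(config.seed)
    teacher = generate_teacher(N, p["P"], p["beta"], rng)
    ds = sample_dataset(teacher, M, SamplerConfig(p["sweeps"]), rng)
    cfg = TrainConfig(minibatch=min(100, M), n_chains=min(100, M))
    model, mon = train(ds, p["n_hidden"], cfg, teacher_J=hebbian_coupling(teacher),
                       beta=p["beta"], rng=rng)
    rows = []
    for e in range(len(mon.pseudo_likelihood)):
        rows.append([e + 1, float(mon.pseudo_likelihood[e]),
                     float(mon.eps_vs_teacher[e])]
                    + [float(s) for s in np.sort(mon.sigma_history[e])[::-1]])
    out = _outdir(config) / "rbm_monitors.tsv"
    _write_tsv(out, ["epoch", "pseudo_likelihood", "eps"]
               + [f"sigma{k+1}" for k in range(p["n_hidden"])], rows)
    wout = _outdir(config) / "rbm_weights.tsv"
    hio.write_matrix(wout, model.W, meta={"N_h": model.n_hidden,
                                          "N_v": model.n_visible}, fmt="%.10g")
    return _summary(config, {**p, "N_used": N, "M_used": M,
                             "stopped_epoch": mon.stopped_epoch},
                    [out.name, wout.name])


def trajectory_dump(config: ExperimentConfig) -> dict:
    """Magnetization trajectories of parallel TAP vs parallel AMP.

    Direct problem, P=1: near the paramagnet TAP escapes only for
    beta > 1 and moves toward the pattern, while AMP leaves it already for
    beta > 1/2 along bulk (non-pattern) directions.
    """
    p = dict(N=1000, P=1, betas=(0.3, 0.7, 1.5), steps=60, n_sites=50)
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 50)
    rng = as_rng(config.seed)
    outputs = []
    for beta in p["betas"]:
        teacher = generate_teacher(N, p["P"], max(beta, 1e-6), rng)
        J = teacher.coupling()
        init = random_init(N, 1.0, 1.0, rng)
        alpha = p["P"] / N
        for scheme in ("tap", "amp"):
            if scheme == "tap":
                state = TAPState.from_m(init)
                step = lambda s: tap_parallel_step(s, J, beta, alpha)
            else:
                state = amp_init(init, beta)
                step = lambda s: amp_parallel_step(s, J, beta, alpha)
            rows = [[0] + [float(x) for x in state.m[:p["n_sites"]]]]
            for t in range(1, p["steps"] + 1):
                state = step(state)
                rows.append([t] + [float(x) for x in state.m[:p["n_sites"]]])
            out = _outdir(config) / f"trajectories_{scheme}_beta{beta}.tsv"
            _write_tsv(out, ["t"] + [f"m{i}" for i in range(p["n_sites"])], rows)
            outputs.append(out.name)
    return _summary(config, {**p, "N_used": N}, outputs)


def convergence_map(config: ExperimentConfig) -> dict:
    """P_c(beta): probability of converging to a pattern, three schemes."""
    p = dict(N=500, P=2, betas=(0.25, 0.5, 0.8, 1.25, 2.0, 4.0), trials=1000,
             threshold=0.7, damping=0.95, schemes=("tap", "amp_seq", "dmft"))
    p.update(config.parameters)
    N = _scaled(p["N"], config.scale, 50)
    trials = _scaled(p["trials"], config.scale, 2)
    rng = as_rng(config.seed)
    rows = []
    for scheme in p["schemes"]:
        for beta in p["betas"]:
            pc = convergence_probability(scheme, N, p["P"], beta, trials,
                                         p["threshold"], rng, d=p["damping"])
            rows.append([scheme, N, beta, pc])
    out = _outdir(config) / "convergence_map.tsv"
    _write_tsv(out, ["scheme", "N", "beta", "P_c"], rows)
    return _summary(config, {**p, "N_used": N, "trials_used": trials}, [out.name])


RECIPES = {
    "single_pattern_overlap": single_pattern_overlap,
    "retrieval_overlaps": retrieval_overlaps,
    "deflation_traces": deflation_traces,
    "error_vs_load": error_vs_load,
    "rbm_monitors": rbm_monitors,
    "trajectory_dump": trajectory_dump,
    "convergence_map": convergence_map,
}


def run_recipe(config: ExperimentConfig) -> dict:
    """Dispatch a named recipe; identical config + seed => identical files."""
    if config.name not in RECIPES:
        raise ValueError(f"unknown recipe {config.name!r}; "
                         f"known: {sorted(RECIPES)}")
    log.info("running recipe %s (seed=%d, scale=%g)", config.name, config.seed,
             config.scale)
    return RECIPES[config.name](config)
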