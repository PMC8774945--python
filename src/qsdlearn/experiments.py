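"""Experiment driver: model dispatch, error metric, trace files, summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np

from . import __version__
from .actor_critic import ACConfig, LearningRateSchedule, RunTrace, run_actor_critic
from .baselines import (
    polyak_average,
    run_fleming_viot,
    run_projection,
    run_vanilla,
)
from .chain_core import Distribution, SubMarkovKernel, exact_qsd
from .model_zoo import (
    QueueSpec,
    linear_drift_rho,
    loopy_chain,
    mm1_queue,
    random_submarkov,
    sis_extinction_chain,
)

__all__ = ["ExperimentConfig", "l2_error", "build_model", "run_experiment",
           "ramp_logits"]

ALGORITHMS = ("ac", "vanilla", "projection", "polyak", "fv")


def l2_error(est: Distribution, ref: Distribution) -> float:
    """Euclidean norm of the difference of two probability vectors."""
    if est.n_states != ref.n_states:
        raise ValueError(f"length mismatch: {est.n_states} vs {ref.n_states}")
    return float(np.linalg.norm(est.probs - ref.probs))


def build_model(model: dict[str, Any]) -> SubMarkovKernel:
    """Construct a kernel from a model spec mapping.

    Recognised ``name`` values: ``loopy``, ``mm1``, ``sis``, ``random``,
    ``file`` (with ``path`` pointing at a delimited matrix).
    """
    spec = dict(model)
    name = spec.pop("name", None)
    if name == "loopy":
        return loopy_chain(eps=spec["eps"], m=int(spec.get("m", 3)))
    if name == "mm1":
        N = int(spec["N"])
        rho = spec.get("rho")
        if spec.get("rho_preset") == "linear-drift":
            rho = linear_drift_rho(N)
        if rho is None:
            raise ValueError("mm1 model needs rho or rho_preset")
        return mm1_queue(QueueSpec(capacity=N, rho=rho))
    if name == "sis":
        return sis_extinction_chain(N=int(spec["N"]), beta=spec["beta"],
                                    gamma=spec["gamma"])
    if name == "random":
        return random_submarkov(n=int(spec["n"]), leak_states=int(spec["leak"]),
                                density=spec.get("density", 0.5),
                                seed=int(spec.get("seed", 0)))
    if name == "file":
        return SubMarkovKernel.load(spec["path"])
    raise ValueError(
        f"unknown model {name!r}; expected one of loopy, mm1, sis, random, file")


def ramp_logits(n_free: int, peak_index: int, low: float, high: float,
                tail: float) -> np.ndarray:
    """Piecewise-linear initial logits rising to ``high`` at ``peak_index``
    (0-based) and falling to ``tail`` at the last free index."""
    theta = np.empty(n_free)
    up = np.linspace(low, high, peak_index + 1)
    theta[: peak_index + 1] = up
    if peak_index < n_free - 1:
        theta[peak_index:] = np.linspace(high, tail, n_free - peak_index)
    return theta


@dataclass
class ExperimentConfig:
    """A fully serialisable description of one experiment."""

    model: dict[str, Any]
    algorithm: str
    params: dict[str, Any] = field(default_factory=dict)
    seeds: tuple[int, ...] = (0,)
    out_dir: Optional[Union[str, Path]] = None
    eval_every: int = 100

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"expected one of {ALGORITHMS}")
        self.seeds = tuple(int(s) for s in self.seeds)

    def to_json(self) -> str:
        return json.dumps(
            {"model": self.model, "algorithm": self.algorithm,
             "params": self.params, "seeds": list(self.seeds),
             "eval_every": self.eval_every}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, out_dir=None) -> "ExperimentConfig":
        d = json.loads(text)
        return cls(model=d["model"], algorithm=d["algorithm"],
                   params=d.get("params", {}),
                   seeds=tuple(d.get("seeds", [0])), out_dir=out_dir,
                   eval_every=int(d.get("eval_every", 100)))


def _run_one(K: SubMarkovKernel, cfg: ExperimentConfig, seed: int,
             reference: Distribution) -> RunTrace:
    p = dict(cfg.params)
    if cfg.algorithm == "ac":
        theta0 = p.pop("theta0", None)
        ac_cfg = ACConfig(
            lr_theta=LearningRateSchedule.parse(p.pop("lr_theta", "const:0.01")),
            lr_psi=LearningRateSchedule.parse(p.pop("lr_psi", "const:0.0001")),
            lr_r=LearningRateSchedule.parse(p.pop("lr_r", "const:0.0001")),
            batch_size=int(p.pop("batch_size", 1)),
            n_iterations=int(p.pop("n_iterations", 1000)),
            source_state=p.pop("source_state", None),
            theta0=None if theta0 is None else np.asarray(theta0, dtype=float),
            seed=seed, eval_every=cfg.eval_every,
            track_kl=bool(p.pop("track_kl", False)),
            burn_in_steps=int(p.pop("burn_in_steps", 1)),
        )
        _, trace = run_actor_critic(K, ac_cfg, reference=reference)
    elif cfg.algorithm == "vanilla":
        _, trace = run_vanilla(K, int(p["n_episodes"]), seed,
                               reference=reference, eval_every=cfg.eval_every)
    elif cfg.algorithm == "projection":
        _, trace, _ = run_projection(K, p.get("eps_n", "pow:0.99"),
                                     int(p["n_episodes"]), seed,
                                     reference=reference,
                                     eval_every=cfg.eval_every,
                                     normalized=bool(p.get("normalized", False)))
    elif cfg.algorithm == "polyak":
        _, _, iterates = run_projection(K, p.get("eps_n", "pow:0.99"),
                                        int(p["n_episodes"]), seed,
                                        reference=reference,
                                        eval_every=cfg.eval_every,
                                        collect_iterates=True)
        _, trace = polyak_average(iterates, reference=reference,
                                  eval_every=cfg.eval_every)
    elif cfg.algorithm == "fv":
        _, _, trace = run_fleming_viot(K, int(p["n_particles"]),
                                       int(p["n_steps"]), seed,
                                       reference=reference,
                                       eval_every=cfg.eval_every)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(cfg.algorithm)
    return trace


def run_experiment(cfg: ExperimentConfig) -> dict[str, Any]:
    """Run every seed, write one trace CSV per seed plus a summary.

    Returns a summary mapping with per-seed final errors and their median.
    """
    K = build_model(cfg.model)
    reference, lam = exact_qsd(K)
    header = [f"qsdlearn {__version__} | numpy {np.__version__}",
              f"config {cfg.to_json()}"]
    finals = {}
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for seed in cfg.seeds:
        trace = _run_one(K, cfg, seed, reference)
        finals[seed] = trace.final_error
        if out_dir is not None:
            trace.to_csv(out_dir / f"trace_seed{seed}.csv",
                         header_lines=header + [f"seed {seed}"])
    summary = {
        "algorithm": cfg.algorithm,
        "model": cfg.model,
        "survival_eigenvalue": lam,
        "final_errors": finals,
        "median_final_error": float(np.median(list(finals.values()))),
    }
    if out_dir is not None:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump({**summary,
                       "final_errors": {str(k): v for k, v in finals.items()},
                       "config": json.loads(cfg.to_json())}, fh, indent=2)
    return summary
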