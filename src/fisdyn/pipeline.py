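"""End-to-end runs from a single config: enumerate, propagate, export.

A :class:`RunConfig` bundles the model parameters, analysis options and
output location.  :func:`run_pipeline` executes either the exact path
(enumerate states, build the transition matrix, propagate the requested
start states, summarise F_IS per generation) or the Monte Carlo path
(forward-simulate loci), and writes plottable CSVs plus a JSON summary.
Every output carries a commented header with version, parameters and
seed, and the resolved config is written next to the outputs so a rerun
of an identical config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from .chain import AnalysisConfig, propagate, steady_state, trajectory_table
from .kernel import build_transition_matrix
from .sampling import simulate
from .state_space import (
    DEFAULT_STATE_CAP,
    ModelParams,
    StartFis,
    count_states,
    enumerate_states,
    preset_start,
)
from .tableio import write_csv
from .timescales import default_epsilon, t_c, t_mu

logger = logging.getLogger("fisdyn")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one run.

    ``mode`` is ``'exact'`` (full transition-matrix propagation; requires
    the state space to fit under ``state_cap``) or ``'mc'`` (Monte Carlo
    forward simulation of ``n_loci`` loci).  ``starts`` are preset labels
    (``fis-1``, ``fis0``, ``fis+1``).
    """

    N: int
    n: int = 2
    c: float = 0.0
    mu: float = 0.0
    mode: str = "exact"
    t_max: int = 200
    starts: tuple[str, ...] = ("fis-1", "fis0", "fis+1")
    n_loci: int = 10_000
    seed: int = 0
    epsilon: float | None = None
    state_cap: int = DEFAULT_STATE_CAP
    exclude: str = "fixed"
    outdir: str = "fisdyn_out"

    def params(self) -> ModelParams:
        return ModelParams(N=self.N, n=self.n, c=self.c, mu=self.mu)

    def to_toml(self) -> str:
        lines = ["[run]"]
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, tuple):
                inner = ", ".join(f'"{v}"' for v in value)
                lines.append(f"{key} = [{inner}]")
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path: "str | Path") -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        section = data.get("run", data)
        if "starts" in section:
            section["starts"] = tuple(section["starts"])
        return cls(**section)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


def _meta(cfg: RunConfig) -> dict:
    meta = {k: v for k, v in asdict(cfg).items() if v is not None}
    meta["starts"] = ",".join(cfg.starts)
    return meta


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run and write its artifact bundle.

    Returns a manifest dict (also written as ``summary.json``) listing the
    produced files and headline numbers.  Fails fast with
    :class:`PipelineError` naming the stage; files written before the
    failure are left in place.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.toml").write_text(cfg.to_toml(), encoding="utf-8")
    params = cfg.params()
    eps = cfg.epsilon if cfg.epsilon is not None else default_epsilon(cfg.N)
    manifest: dict = {
        "mode": cfg.mode,
        "params": {"N": cfg.N, "n": cfg.n, "c": cfg.c, "mu": cfg.mu},
        "epsilon": eps,
        "seed": cfg.seed,
        "files": ["resolved_config.toml"],
        "timescales": {
            "t_c": t_c(cfg.c, eps),
            "t_mu": t_mu(cfg.mu, cfg.n, eps) if cfg.mu > 0 else None,
        },
    }
    if cfg.mode == "exact":
        n_states = count_states(cfg.N, cfg.n)
        if n_states > cfg.state_cap:
            raise PipelineError(
                "enumerate",
                f"state space has {n_states} states, above the cap of "
                f"{cfg.state_cap}; switch mode to 'mc'",
            )
        logger.info("enumerating %d states", n_states)
        space = enumerate_states(params, cap=cfg.state_cap)
        logger.info("building %dx%d transition matrix", n_states, n_states)
        tm = build_transition_matrix(params, space=space)
        for label in cfg.starts:
            start = preset_start(params, StartFis(label))
            logger.info("propagating start %s for %d generations", label, cfg.t_max)
            traj = propagate(start, tm, cfg.t_max)
            table = trajectory_table(traj, space, exclude=cfg.exclude)
            fname = f"trajectory_{label.replace('+', 'p').replace('-', 'm')}.csv"
            write_csv(table, outdir / fname, {**_meta(cfg), "start": label})
            manifest["files"].append(fname)
        if params.mu > 0:
            from .chain import fis_summary

            pi = steady_state(tm, AnalysisConfig(epsilon=cfg.epsilon))
            s = fis_summary(pi, space, exclude=cfg.exclude)
            manifest["steady_state"] = {
                "mean_fis": s.mean,
                "var_fis": s.variance,
                "p_fix": s.p_fix,
                "p_near_fix": s.p_near_fix,
            }
    elif cfg.mode == "mc":
        for label in cfg.starts:
            start = preset_start(params, StartFis(label))
            logger.info("simulating %d loci, start %s", cfg.n_loci, label)
            run = simulate(params, start, cfg.t_max, cfg.n_loci, seed=cfg.seed)
            table = run.summary_table()
            fname = f"mc_summary_{label.replace('+', 'p').replace('-', 'm')}.csv"
            write_csv(table, outdir / fname, {**_meta(cfg), "start": label})
            manifest["files"].append(fname)
    else:
        raise PipelineError("config", f"unknown mode {cfg.mode!r}")
    manifest["files"].append("summary.json")
    (outdir / "summary.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
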