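"""End-to-end orchestration: config -> string -> umbrella -> FES -> report.

A :class:`RunConfig` fully determines a run (system, surface choice,
engine, schedules, seeds); re-running the same config and seed reproduces
identical sample files, which the emitted manifest of SHA-256 checksums
makes checkable.  Every stage writes the plain-text formats of its module,
so stages can be re-run and re-analyzed independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import yaml

from . import fes, kinetics, pimd, sampling, stringmethod
from .constants import ROOM_T
from .coords import CartesianComponent, ReactionCoordinateSet
from .modelsys import (
    ModelSystem,
    Surface,
    build_gt_toy,
    double_well_system,
    gt_reaction_coordinates,
    muller_brown_system,
    system_to_yaml,
)

__all__ = ["RunConfig", "run_pipeline", "build_system", "PipelineError"]

_KNOWN_KEYS = {
    "system", "surface", "engine", "n_beads", "reaction", "n_windows",
    "string_iterations", "string_time_per_window", "equil_time", "prod_time",
    "dt", "stride", "temperature", "gamma", "k_umbrella", "trials",
    "bandwidth", "n_blocks", "seed", "outdir", "min_prominence",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Schema-validated end-to-end run configuration.

    Times in fs, temperatures in K, force constants kcal/mol/Å².
    ``surface`` is one of base | reference (the corrected surface is built
    by the Δ-learning workflow, not by this config); ``engine`` classical |
    pimd (with ``n_beads``).
    """

    system: str = "double_well_1d"
    surface: str = "reference"
    engine: str = "classical"
    n_beads: int = 16
    reaction: tuple[str, str] = ("L", "R")
    n_windows: int = 8
    string_iterations: int = 0
    string_time_per_window: float = 400.0
    equil_time: float = 500.0
    prod_time: float = 2000.0
    dt: float = 0.5
    stride: float = 10.0
    temperature: float = ROOM_T
    gamma: float = 0.005
    k_umbrella: float = 200.0
    trials: int = 2
    bandwidth: float = 0.05
    n_blocks: int = 0
    seed: int = 0
    outdir: str = "run"
    min_prominence: float = 0.25

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reaction" in doc:
            doc["reaction"] = tuple(doc["reaction"])
        return cls(**doc)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["reaction"] = list(d["reaction"])
        return yaml.safe_dump(d, sort_keys=False)


def build_system(cfg: RunConfig) -> tuple[ModelSystem, Surface, ReactionCoordinateSet]:
    """Instantiate the configured system, surface and coordinate set."""
    if cfg.system == "gt_toy":
        system, reference, base = build_gt_toy()
        surface = {"reference": reference, "base": base}[cfg.surface]
        rc = gt_reaction_coordinates()
    elif cfg.system == "double_well_1d":
        system, surface = double_well_system()
        rc = ReactionCoordinateSet([CartesianComponent("X", 0)], system.labels)
    elif cfg.system == "muller_brown":
        system, surface = muller_brown_system()
        rc = ReactionCoordinateSet(
            [CartesianComponent("X", 0), CartesianComponent("X", 1)], system.labels
        )
    else:
        raise ValueError(f"unknown system {cfg.system!r}")
    if cfg.system != "gt_toy" and cfg.surface != "reference":
        raise ValueError(f"system {cfg.system!r} has no {cfg.surface!r} surface")
    return system, surface, rc


def _schedule(cfg: RunConfig, prod_time: float | None = None, equil_time: float | None = None):
    return sampling.Schedule(
        equil_time=cfg.equil_time if equil_time is None else equil_time,
        prod_time=cfg.prod_time if prod_time is None else prod_time,
        dt=cfg.dt,
        stride=cfg.stride,
        temperature=cfg.temperature,
        gamma=cfg.gamma,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stages: build system -> (optional) string optimization -> production
    umbrella sampling (classical or PIMD, ``cfg.trials`` independent
    trials) -> MBAR profile (+ optional block analysis) -> stationary-point
    report.  Any stage failure raises :class:`PipelineError` naming the
    stage; artifacts written so far are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())
    artifacts: list[Path] = [out / "config.yaml"]

    stage = "build-system"
    try:
        system, surface, rc = build_system(cfg)
        (out / "system.yaml").write_text(system_to_yaml(system))
        artifacts.append(out / "system.yaml")
        for name in system.named_states:
            p = out / f"state_{name.replace('*', 'star')}.xyz"
            p.write_text(system.state_xyz(name))
            artifacts.append(p)

        stage = "string"
        ra, pb = cfg.reaction
        xi_r = rc.values(system.named_states[ra])
        xi_p = rc.values(system.named_states[pb])
        path = stringmethod.init_linear(xi_r, xi_p, cfg.n_windows)
        if cfg.string_iterations > 0:
            sched = sampling.Schedule(
                equil_time=100.0, prod_time=cfg.string_time_per_window,
                dt=cfg.dt, stride=max(cfg.dt, 5.0), temperature=cfg.temperature,
                gamma=cfg.gamma,
            )
            res = stringmethod.run_string(
                system, surface, rc, path, iterations=cfg.string_iterations,
                schedule=sched, k_umbrella=cfg.k_umbrella, seed=cfg.seed,
            )
            path = res.path
            log = "\n".join(
                f"iter {i+1}: rms_displacement {r:.6f} A"
                for i, r in enumerate(res.rms_displacement)
            )
            (out / "string_convergence.log").write_text(log + "\n")
            artifacts.append(out / "string_convergence.log")
        (out / "path.txt").write_text(path.to_table())
        artifacts.append(out / "path.txt")

        stage = "production"
        windows = [
            sampling.UmbrellaWindow(tuple(img), cfg.k_umbrella, window_id=i)
            for i, img in enumerate(path.images)
        ]
        x0 = sampling.prepare_window_positions(system, surface, rc, windows)
        sched = _schedule(cfg)
        trials = []
        for t in range(cfg.trials):
            if cfg.engine == "pimd":
                samp = pimd.run_pimd_windows(
                    system, surface, rc, windows, sched, cfg.n_beads,
                    seed=cfg.seed, trial=t, x0=x0,
                )
            elif cfg.engine == "classical":
                samp = sampling.run_windows(
                    system, surface, rc, windows, sched,
                    seed=cfg.seed, trial=t, x0=x0,
                )
            else:
                raise ValueError(f"unknown engine {cfg.engine!r}")
            trials.append(samp)
            for s in samp:
                p = out / f"window_{s.window.window_id:03d}_trial{t}.dat"
                p.write_text(s.to_table())
                artifacts.append(p)

        stage = "fes"
        profile = fes.pooled_profile(trials, path, cfg.temperature, cfg.bandwidth)
        profile.metadata["engine"] = cfg.engine
        (out / "profile.txt").write_text(profile.to_table())
        artifacts.append(out / "profile.txt")
        if cfg.n_blocks > 1:
            profiles, spread = fes.block_analysis(trials, path, cfg.n_blocks,
                                                  cfg.temperature, cfg.bandwidth)
            for b, p_ in enumerate(profiles):
                pth = out / f"profile_block{b:02d}.txt"
                pth.write_text(p_.to_table())
                artifacts.append(pth)
            (out / "block_spread.json").write_text(
                json.dumps({"n_blocks": cfg.n_blocks, "barrier_spread": spread}))
            artifacts.append(out / "block_spread.json")

        stage = "report"
        rep = kinetics.extract_stationary_points(
            profile, cfg.min_prominence, label=f"{ra}->{pb}")
        doc = {
            "reaction": rep.label,
            "delta_A": rep.delta_A,
            "delta_A_err": rep.delta_A_err,
            "forward_barrier": rep.forward_barrier,
            "reverse_barrier": rep.reverse_barrier,
            "ts_progress": rep.ts_progress,
            "n_transition_states": len(rep.transition_states),
            "n_intermediates": len(rep.intermediates),
        }
        (out / "report.json").write_text(json.dumps(doc, indent=1))
        artifacts.append(out / "report.json")
    except Exception as e:  # noqa: BLE001 - single failure funnel
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    manifest = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in artifacts
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
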