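"""Run configuration, hierarchical seeding, and the end-to-end pipeline.

The pipeline chains the stages: synthetic riverscape → Latin-hypercube
scenario table → per-scenario simulations and the success metric → BRT
surrogate.  Every random draw descends from one global seed: the seed is
expanded with ``numpy.random.SeedSequence.spawn`` into one child per stage
(riverscape, scenario sampling, surrogate), and the scenario sampler in
turn derives one child seed per simulated scenario.  A manifest records
the configuration hash and all stage seeds, so a rerun with the same
configuration is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .engine import ScenarioParameters
from .life_history import LifeHistoryParams
from .movement import MovementConfig
from .riverscape import generate_riverscape, read_riverscape, write_riverscape
from .sensitivity import TABLE1_RANGES, lhs_scenarios, run_sensitivity
from .surrogate import SneakerSuccessBRT, SurrogateConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "scenario_from_dict"]

log = logging.getLogger("amsriver")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RiverscapeSpec:
    n_natal: int = 12
    n_migratory: int = 8
    area_min: float = 5_000.0
    area_max: float = 50_000.0
    branching_factor: int = 2
    patch_table: str | None = None     # read instead of generate when set
    distance_matrix: str | None = None


@dataclass
class EngineSpec:
    years: int = 300
    burn_in: int = 50
    snapshot_interval: int = 10
    iterations: int = 1
    mates_per_female: int = 2
    stray_probability: float = 0.02
    migration_survival: float = 0.97
    egg_survival: float = 2e-4


@dataclass
class SensitivitySpec:
    n_scenarios: int = 100
    ranges: dict = field(default_factory=lambda: dict(TABLE1_RANGES))

    def __post_init__(self) -> None:
        # normalize tuples to lists so the YAML round trip is exact
        self.ranges = {k: [float(v[0]), float(v[1])] for k, v in self.ranges.items()}


@dataclass
class SurrogateSpec:
    n_bootstrap: int = 1000
    max_trees: int = 800
    cv_folds: int = 4


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    out_dir: str = "runs"
    riverscape: RiverscapeSpec = field(default_factory=RiverscapeSpec)
    engine: EngineSpec = field(default_factory=EngineSpec)
    sensitivity: SensitivitySpec = field(default_factory=SensitivitySpec)
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a global seed is mandatory for pipeline runs")
        unknown = set(self.sensitivity.ranges) - set(TABLE1_RANGES)
        if unknown:
            raise ValueError(f"unknown sensitivity parameters: {sorted(unknown)}")
        missing = set(TABLE1_RANGES) - set(self.sensitivity.ranges)
        if missing:
            raise ValueError(f"sensitivity ranges missing: {sorted(missing)}")

    @classmethod
    def demo(cls, seed: int, out_dir: str = "runs") -> "RunConfig":
        """A desk-scale profile: small riverscape, short horizon, 20 scenarios."""
        return cls(
            seed=seed,
            out_dir=out_dir,
            riverscape=RiverscapeSpec(n_natal=8, n_migratory=4,
                                      area_min=5_000, area_max=30_000),
            engine=EngineSpec(years=100, burn_in=20),
            sensitivity=SensitivitySpec(n_scenarios=20),
            surrogate=SurrogateSpec(n_bootstrap=100, max_trees=400),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=raw.get("seed"),
            out_dir=raw.get("out_dir", "runs"),
            riverscape=RiverscapeSpec(**raw.get("riverscape", {})),
            engine=EngineSpec(**raw.get("engine", {})),
            sensitivity=SensitivitySpec(**raw.get("sensitivity", {})),
            surrogate=SurrogateSpec(**raw.get("surrogate", {})),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def scenario_from_dict(raw: dict) -> ScenarioParameters:
    """Build a ScenarioParameters from a flat YAML/JSON mapping."""
    lh = LifeHistoryParams(**raw.pop("life_history", {}))
    mv = MovementConfig(**raw.pop("movement", {}))
    return ScenarioParameters(life_history=lh, movement=mv, **raw)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages and persist every artifact under ``out_dir``.

    Layout: ``riverscape/patches.csv`` + ``distances.csv``,
    ``scenarios.csv``, ``results.csv``, ``surrogate/report.json`` +
    per-predictor partial-dependence CSVs, and ``manifest.json``.
    Stage failures raise :class:`PipelineError` naming the stage; artifacts
    from completed stages stay on disk.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["riverscape", "scenarios", "surrogate"])
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "stages": {},
    }
    t_start = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - annotate and halt
                raise PipelineError(f"pipeline stage {name!r} failed: {exc}") from exc
            dt = time.time() - t0
            manifest["stages"][name] = {"seconds": round(dt, 2)}
            log.info("stage %s done in %.1fs", name, dt)
            return result
        return deco

    @stage("riverscape")
    def riverscape():
        rs_dir = os.path.join(out, "riverscape")
        os.makedirs(rs_dir, exist_ok=True)
        spec = config.riverscape
        if spec.patch_table:
            rs = read_riverscape(spec.patch_table, spec.distance_matrix)
        else:
            rs = generate_riverscape(
                spec.n_natal, spec.n_migratory,
                area_range=(spec.area_min, spec.area_max),
                branching_factor=spec.branching_factor,
                seed=seeds["riverscape"],
            )
        write_riverscape(rs, os.path.join(rs_dir, "patches.csv"),
                         os.path.join(rs_dir, "distances.csv"))
        return rs

    @stage("scenarios")
    def scenarios():
        table = lhs_scenarios(config.sensitivity.n_scenarios,
                              config.sensitivity.ranges, seed=seeds["scenarios"])
        table.to_csv(os.path.join(out, "scenarios.csv"), index=False)
        return table

    @stage("simulate")
    def results():
        e = config.engine
        base = ScenarioParameters(
            years=e.years, burn_in=e.burn_in, snapshot_interval=e.snapshot_interval,
            mates_per_female=e.mates_per_female,
            life_history=LifeHistoryParams(egg_survival=e.egg_survival),
            movement=MovementConfig(stray_probability=e.stray_probability,
                                    migration_survival=e.migration_survival),
        )
        res = run_sensitivity(
            riverscape, scenarios, base_scenario=base,
            progress_path=os.path.join(out, "results_progress.csv"),
        )
        res.to_csv(os.path.join(out, "results.csv"), index=False)
        return res

    @stage("surrogate")
    def surrogate_results():
        s = config.surrogate
        cfg = SurrogateConfig(n_bootstrap=s.n_bootstrap, max_trees=s.max_trees,
                              cv_folds=s.cv_folds, seed=seeds["surrogate"])
        fit = SneakerSuccessBRT(results, config=cfg).fit()
        rep_dir = os.path.join(out, "surrogate")
        os.makedirs(rep_dir, exist_ok=True)
        fit.to_json(os.path.join(rep_dir, "report.json"))
        fit.write_partial_dependence(rep_dir)
        return fit

    manifest["total_seconds"] = round(time.time() - t_start, 2)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
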