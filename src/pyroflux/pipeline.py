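"""Stage orchestration: load/build -> augment -> calibrate -> analyses.

Every stage writes its outputs into the run directory together with a
``.meta.json`` sidecar (package version, seed, stage parameters, SHA-256
digests of the stage inputs), so any numeric output is reconstructible
from its sidecar plus the inputs.  Reruns with an identical config and
seed reproduce all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import maximize, perturbation_sweep, yield_sweep
from .bottleneck import DEFAULT_THRESHOLD, histogram, scan
from .calibration import (
    DEFAULT_EXCHANGE_MAP,
    CalibrationPolicy,
    MeasurementSet,
    apply_culture_mode,
    calibrate_exchanges,
    read_measurements,
)
from .carbon import carbon_ledger
from .model import load_model, validate_model, write_model
from .pathway import (
    PROPANOL_EXCHANGE_ID,
    add_free_energy_reaction,
    augment,
    build_propanol_pathway,
    load_pathway,
)
from .sampling import median_fluxes, sample_fluxes
from .synth import (
    CoreModelParams,
    SyntheticMeasurementParams,
    build_core_model,
    mean_measurements,
    simulate_measurements,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger("pyroflux.pipeline")

#: reactions shown in the target-range comparison when present in the model
SWEEP_ROSTER = [
    "ATPS", "MBH", "NFN1", "SHI", "GAPOR", "POR", "AOR_acetate",
    "E1", "ACS_acetate", "AdhF", "ALS",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat, file-loadable pipeline configuration (keys mirror CLI flags)."""

    out_dir: str = "pyroflux_run"
    seed: int = 0
    # model source: a file path, or a synthetic regime when path is None
    model_path: str | None = None
    synth_regime: str = "substrate-limited"
    # pathway: None -> default 1-propanol pathway; else a YAML fragment
    pathway_path: str | None = None
    culture_mode: str = "closed"
    # measurements: a CSV path, or synthetic replicates when None
    measurements_path: str | None = None
    target: str = PROPANOL_EXCHANGE_ID
    sample_n: int = 1000
    sample_thinning: int = 25
    sample_chains: int = 4
    sampling_enabled: bool = True
    bottleneck_threshold: float = DEFAULT_THRESHOLD
    sweep_steps: int = 40
    perturb_grid_max: float = 10.0
    perturb_grid_points: int = 11

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate_files(self) -> None:
        for label, p in (("model_path", self.model_path),
                         ("pathway_path", self.pathway_path),
                         ("measurements_path", self.measurements_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")
        if self.sampling_enabled and self.seed is None:
            raise ValueError("seed is mandatory when sampling is enabled")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config

    def sidecar(self, name: str, stage: str, params: dict,
                inputs: list[Path] = ()) -> None:
        meta = {
            "pyroflux_version": __version__,
            "stage": stage,
            "seed": self.config.seed,
            "parameters": params,
            "input_digests": {str(p): _sha256(Path(p)) for p in inputs},
        }
        (self.dir / f"{name}.meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")

    def write_json(self, name: str, payload: dict, stage: str,
                   params: dict, inputs=()) -> Path:
        path = self.dir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        self.sidecar(name, stage, params, inputs)
        return path

    def write_csv(self, name: str, frame: pd.DataFrame, stage: str,
                  params: dict, inputs=()) -> Path:
        path = self.dir / name
        frame.to_csv(path, index=False, lineterminator="\n")
        self.sidecar(name, stage, params, inputs)
        return path


def _stage(run: _Run, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Ctx()


def _load_measurements(config: PipelineConfig) -> MeasurementSet:
    if config.measurements_path:
        sets = read_measurements(config.measurements_path)
        if not sets:
            raise ValueError(f"no measurements in {config.measurements_path}")
        return sets[0] if len(sets) == 1 else mean_measurements(sets)
    reps = simulate_measurements(SyntheticMeasurementParams(seed=config.seed))
    return mean_measurements(reps)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate_files()
    run = _Run(Path(config.out_dir), config)
    inputs = [Path(p) for p in (config.model_path, config.pathway_path,
                                config.measurements_path) if p]

    with _stage(run, "load"):
        if config.model_path:
            model = load_model(config.model_path)
        else:
            model = build_core_model(CoreModelParams(regime=config.synth_regime))
        report = validate_model(model)
        (run.dir / "validation.txt").write_text(report.to_text())
        run.sidecar("validation.txt", "load", {"clean": report.is_clean}, inputs)

    with _stage(run, "augment"):
        pathway = (load_pathway(config.pathway_path)
                   if config.pathway_path else build_propanol_pathway())
        model = augment(model, pathway)
        write_model(model, run.dir / "model_augmented.yaml")
        run.sidecar("model_augmented.yaml", "augment",
                    {"pathway": config.pathway_path or "default-propanol"},
                    inputs)

    with _stage(run, "calibrate"):
        model = apply_culture_mode(model, config.culture_mode)
        meas = _load_measurements(config)
        policy = CalibrationPolicy()
        target_compound = [
            c for c, ex in DEFAULT_EXCHANGE_MAP.items() if ex == config.target
        ]
        phys = calibrate_exchanges(model, meas, policy)
        scan_model = calibrate_exchanges(
            model, meas, policy, exclude=tuple(target_compound))
        write_model(phys, run.dir / "model_calibrated.yaml")
        run.sidecar("model_calibrated.yaml", "calibrate",
                    {"mode": config.culture_mode, "strain": meas.strain},
                    inputs)

    with _stage(run, "fba"):
        optimum, fluxes = maximize(scan_model, config.target)
        run.write_json("fba.json", {
            "target": config.target, "optimum": optimum,
            "fluxes": {k: float(v) for k, v in fluxes.items()},
        }, "fba", {"target": config.target}, inputs)

    medians = None
    if config.sampling_enabled:
        with _stage(run, "sample"):
            sample = sample_fluxes(
                phys, n=config.sample_n, seed=config.seed,
                thinning=config.sample_thinning, chains=config.sample_chains)
            run.write_csv("sample.csv", sample.samples, "sample",
                          sample.metadata(), inputs)
            medians = median_fluxes(sample)
            run.write_csv(
                "medians.csv",
                medians.rename("median").rename_axis("reaction").reset_index(),
                "sample", sample.metadata(), inputs)

        with _stage(run, "bottleneck"):
            missing = [r.id for r in scan_model.reactions
                       if r.id not in medians.index]
            med = pd.concat([medians, pd.Series(0.0, index=missing)])
            result = scan(scan_model, med, config.target,
                          threshold=config.bottleneck_threshold)
            run.write_csv("bottleneck.csv", result.to_frame(), "bottleneck",
                          {"threshold": config.bottleneck_threshold,
                           "baseline": result.baseline}, inputs)
            counts, edges = histogram(result)
            run.write_csv("bottleneck_histogram.csv", pd.DataFrame({
                "bin_left": edges[:-1], "bin_right": edges[1:],
                "count": counts,
            }), "bottleneck", {"bin_width": 0.25}, inputs)

    with _stage(run, "sweep"):
        roster = [r for r in SWEEP_ROSTER if r in scan_model.reactions]
        sweep = yield_sweep(scan_model, config.target, roster,
                            n_steps=config.sweep_steps)
        run.write_csv("sweep.csv", sweep.to_tidy(), "sweep",
                      {"n_steps": config.sweep_steps, "reactions": roster},
                      inputs)

    with _stage(run, "perturb"):
        grid = np.linspace(0.0, config.perturb_grid_max,
                           config.perturb_grid_points)
        frames = []
        for kind in ("ATP", "NADPH"):
            m = add_free_energy_reaction(scan_model, kind)
            curve = perturbation_sweep(m, kind, grid, target=config.target)
            frame = curve.to_frame()
            frame.insert(0, "kind", kind)
            frames.append(frame)
        run.write_csv("perturb.csv", pd.concat(frames, ignore_index=True),
                      "perturb", {"grid_max": config.perturb_grid_max,
                                  "points": config.perturb_grid_points},
                      inputs)

    with _stage(run, "carbon-balance"):
        meas = _load_measurements(config)
        ledger = carbon_ledger(meas)
        run.write_csv("carbon_ledger.csv", ledger.to_frame(), "carbon-balance",
                      {"strain": meas.strain}, inputs)
        (run.dir / "carbon_ledger.json").write_text(ledger.to_json() + "\n")
        run.sidecar("carbon_ledger.json", "carbon-balance",
                    {"strain": meas.strain}, inputs)

    run.write_json("run_config.json", dataclasses.asdict(config), "config",
                   {}, inputs)
    return run.dir
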