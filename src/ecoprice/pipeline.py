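"""Config-driven pipeline: simulate -> vectors -> pairs -> partition -> infer
-> diagnose, with per-stage seeds, CSV artifacts and a run manifest.

A run configuration is a YAML/JSON mapping:

.. code-block:: yaml

    seed: 1
    design_mode: experiment          # experiment | real_world
    synthetic: {n_plots: 20, n_species: 100}   # omit to use paths: instead
    paths: {observations: obs.csv, covariates: cov.csv, allometry: allo.csv}
    analysis:
      scheme: restricted_moving_average
      biomass_mode: total_biomass
      guild: null                    # herbivore | predator | null
      baseline_window: 5
      min_replicates: 2
      include_controls: true
      occupancy_threshold: null
      n_models: 200
      horizons: [2, 7]
      covariate_levels: null         # default: PSR 1/60 or LUI 0.5/3.5

The global seed spawns independent per-stage streams, so a stage rerun in
isolation reproduces its output bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomass import build_function_vectors, vectors_to_frame
from .data_model import (
    AllometricTable,
    read_lui_covariates,
    read_observations,
    read_psr_covariates,
)
from .design import CovariateScaling
from .diagnostics import coverage_table
from .model import CommunityTrendModel
from .synthetic import SyntheticConfig, default_allometry, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "vectors", "pairs", "partition", "infer", "diagnose")

_ANALYSIS_DEFAULTS = {
    "scheme": "restricted_moving_average",
    "biomass_mode": "total_biomass",
    "guild": None,
    "baseline_window": 5,
    "min_replicates": 2,
    "include_controls": True,
    "occupancy_threshold": None,
    "n_models": 200,
    "horizons": [2, 7],
    "covariate_levels": None,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(source) -> dict:
    """Load a YAML/JSON config from a path or pass a mapping through."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_rng(seed: int | None, stage: str) -> np.random.Generator:
    # stable per-stage stream regardless of which stages actually run
    idx = STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(seed or 0).spawn(len(STAGES))[idx])


def run_pipeline(config, outdir, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the manifest mapping.

    Artifacts (all CSV/JSON) are written under ``outdir``.  Any stage error
    aborts with the stage name; the manifest is then marked incomplete.
    """
    config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    design_mode = config.get("design_mode", "experiment")
    analysis = {**_ANALYSIS_DEFAULTS, **config.get("analysis", {})}

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "design_mode": design_mode,
        "versions": {
            "ecoprice": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "outputs": [],
        "complete": False,
    }

    def emit(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.12g")
        manifest["outputs"].append(name)
        return path

    state: dict = {}
    current = "setup"
    try:
        if "simulate" in stages and "synthetic" in config:
            current = "simulate"
            syn = dict(config.get("synthetic") or {})
            syn.setdefault("mode", design_mode)
            n_plots = syn.pop("n_plots", None)
            cfg = SyntheticConfig(**syn)
            if n_plots is not None:
                cfg = cfg.with_plots(n_plots)
            result = simulate(cfg, rng=_stage_rng(seed, "simulate"))
            state["observations"] = result.observations
            state["covariates"] = result.covariates
            state["allometry"] = default_allometry()
            emit("observations.csv", result.observations)
            emit("covariates.csv", result.covariates)
            emit("truth.csv", result.truth)
            state["allometry"].to_csv(outdir / "allometry.csv")
            manifest["outputs"].append("allometry.csv")
            manifest["stages"]["simulate"] = {
                "rows": len(result.observations),
                "config": asdict(cfg),
            }
        else:
            current = "load"
            paths = config.get("paths") or {}
            for key in ("observations", "covariates"):
                if key not in paths:
                    raise PipelineError(current, f"missing input path {key!r}")
                if not Path(paths[key]).exists():
                    raise PipelineError(current, f"file not found: {paths[key]}")
            allo_path = paths.get("allometry")
            state["allometry"] = (
                AllometricTable.read_csv(allo_path) if allo_path else default_allometry()
            )
            state["observations"] = read_observations(
                paths["observations"], allometry=state["allometry"]
            )
            reader = read_psr_covariates if design_mode == "experiment" else read_lui_covariates
            state["covariates"] = reader(paths["covariates"])

        guild = analysis["guild"]
        current = "partition"
        model = CommunityTrendModel.from_observations(
            state["observations"],
            state["covariates"],
            state["allometry"],
            design_mode=design_mode,
            scheme=analysis["scheme"],
            biomass_mode=analysis["biomass_mode"],
            guild_filter={guild} if guild else None,
            baseline_window=analysis["baseline_window"],
            min_replicates=analysis["min_replicates"],
            include_controls=analysis["include_controls"],
            occupancy_threshold=analysis["occupancy_threshold"],
        )
        if "vectors" in stages:
            current = "vectors"
            vectors = build_function_vectors(
                state["observations"],
                state["allometry"],
                mode=analysis["biomass_mode"],
                guild_filter={guild} if guild else None,
            )
            frame = vectors_to_frame(vectors)
            emit("function_vectors.csv", frame)
            manifest["stages"]["vectors"] = {"rows": len(frame)}
        if "pairs" in stages or "partition" in stages:
            emit("partitions.csv", model.partitions)
            manifest["stages"]["partition"] = {
                "rows": len(model.partitions),
                "covariate_scaling": asdict(model.scaling),
                "baseline_mean": model.baseline_mean,
            }

        if "infer" in stages:
            current = "infer"
            results = model.fit(
                n_models=analysis["n_models"],
                seed=_stage_rng(seed, "infer"),
                covariate_levels=analysis["covariate_levels"],
            )
            emit("trend_estimates.csv", results.trend_estimates())
            emit("predictions.csv", results.predictions())
            contrib = pd.concat(
                [
                    results.contributions(h)
                    for h in analysis["horizons"]
                    if h in results.spans
                ],
                ignore_index=True,
            )
            emit("contributions.csv", contrib)
            if model.baseline_mean and model.baseline_mean > 0:
                emit("decline.csv", results.percent_decline())
            vif = model.design_vif()
            manifest["stages"]["infer"] = {
                "n_models": results.n_fits,
                "failed_fits": results.n_failures,
                "vif": {k: (None if not np.isfinite(v) else float(v)) for k, v in vif.items()},
            }
            state["results"] = results

        if "diagnose" in stages:
            current = "diagnose"
            cov = coverage_table(state["observations"])
            emit("coverage.csv", cov)
            manifest["stages"]["diagnose"] = {"rows": len(cov)}

        manifest["complete"] = True
    except PipelineError:
        raise
    except Exception as err:  # annotate with the failing stage
        _write_manifest(outdir, manifest)
        raise PipelineError(current, str(err)) from err

    _write_manifest(outdir, manifest)
    state["manifest"] = manifest
    return state


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
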