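"""Pipeline stages, configuration and artifact I/O.

Stages run in the fixed order generate -> reduce -> stats -> pse -> fit, each
reading the previous stage's CSV artifacts from the output directory and
writing its own, plus a ``manifest.json`` recording the configuration, the
per-stage seeds and completion status.  All randomness derives from one base
seed through named ``numpy`` seed sequences, so reruns with the same seed
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, psychophysics, reduction, stats, synthetic
from .model import ModelParams, simulate, trial_protocol

__all__ = ["RunConfig", "run_pipeline", "STAGE_ORDER", "load_flat_config", "simulate_to_csv"]

STAGE_ORDER = ("generate", "reduce", "stats", "pse", "fit")

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected at load time."""

    out: Path = Path("svvkit_out")
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    n_subjects: int = 10
    n_subjects_2afc: int = 8
    sessions: int = 4
    reps_per_direction: int = 4
    tracking_error_sd: float = 2.0
    responsiveness_sd: float = 0.4
    preset: str = "table1"
    fit_n_starts: int = 10
    fit_free: tuple[str, ...] = ("ko", "go", "t_s")
    verbosity: int = 1

    def __post_init__(self) -> None:
        self.out = Path(self.out)
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid stages: {list(STAGE_ORDER)}")
        # canonical execution order regardless of how stages were listed
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)

    def grid(self) -> synthetic.DesignGrid:
        return synthetic.DesignGrid(
            sessions=self.sessions, reps_per_direction=self.reps_per_direction
        )


def load_flat_config(path: str | Path) -> dict:
    """Read a flat key-value YAML/JSON configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("config file must hold a flat key-value mapping")
    return data


def _rng(config: RunConfig, stage: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(h,)))


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{producer}' stage first"
        )
    return path


def _stage_generate(config: RunConfig) -> list[str]:
    grid = config.grid()
    rng = _rng(config, "generate")
    profiles = synthetic.make_cohort(
        n_subjects=config.n_subjects, rng=rng, preset=config.preset,
        tracking_error_sd=config.tracking_error_sd,
        responsiveness_sd=config.responsiveness_sd, grid=grid,
    )
    traces = synthetic.generate_cohort_trials(profiles, rng=rng, grid=grid)
    trials_df = synthetic.traces_to_frame(traces)
    trials_df.to_csv(config.out / "trials.csv", index=False, float_format=_CSV_FLOAT)

    afc = synthetic.generate_2afc_dataset(
        n_subjects=config.n_subjects_2afc, rng=_rng(config, "generate-2afc")
    )
    afc.to_csv(config.out / "twoafc.csv", index=False, float_format=_CSV_FLOAT)

    sidecar = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_subjects_2afc": config.n_subjects_2afc,
        "preset": config.preset,
        "profiles": [
            {k: v for k, v in dataclasses.asdict(p).items() if k != "plateaus"}
            for p in profiles
        ],
    }
    (config.out / "generate_meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return ["trials.csv", "twoafc.csv", "generate_meta.json"]


def _stage_reduce(config: RunConfig) -> list[str]:
    trials_df = pd.read_csv(_need(config.out / "trials.csv", "generate"))
    traces = synthetic.frame_to_traces(trials_df)
    red = reduction.reduce_cohort(traces)
    red["summaries"].to_csv(config.out / "summaries.csv", index=False, float_format=_CSV_FLOAT)
    red["grand_means"].to_csv(config.out / "grand_means.csv", index=False, float_format=_CSV_FLOAT)

    parts = []
    for (v, p), (t, y) in sorted(red["grand_traces"].items()):
        parts.append(pd.DataFrame({"velocity": v, "noise": p, "time_s": t, "bias_deg": y}))
    pd.concat(parts, ignore_index=True).to_csv(
        config.out / "grand_traces.csv", index=False, float_format=_CSV_FLOAT
    )
    reduction.direction_test(red["per_trial"]).to_csv(
        config.out / "direction_tests.csv", index=False, float_format=_CSV_FLOAT
    )
    # group-level exponential of the fastest zero-noise condition
    vmax = max(v for v, p in red["grand_traces"] if p == 0.0)
    t, y = red["grand_traces"][(vmax, 0.0)]
    ef = reduction.fit_exponential(t, y)
    (config.out / "expfit.json").write_text(
        json.dumps(
            {"velocity": vmax, "noise": 0.0, "a": ef.a, "b": ef.b, "c": ef.c,
             "tau_s": ef.tau, "sse": ef.sse, "success": ef.success},
            indent=2, sort_keys=True,
        )
    )
    return ["summaries.csv", "grand_means.csv", "grand_traces.csv",
            "direction_tests.csv", "expfit.json"]


def _stage_stats(config: RunConfig) -> list[str]:
    summaries = pd.read_csv(_need(config.out / "summaries.csv", "reduce"))
    table = stats.lrt_table(summaries)
    table.to_csv(config.out / "lrt_tests.csv", index=False, float_format=_CSV_FLOAT)
    (config.out / "lrt_report.json").write_text(
        json.dumps(table.to_dict(orient="records"), indent=2, sort_keys=True)
    )
    return ["lrt_tests.csv", "lrt_report.json"]


def _stage_pse(config: RunConfig) -> list[str]:
    afc = pd.read_csv(_need(config.out / "twoafc.csv", "generate"))
    pse = psychophysics.pse_table(afc)
    pse.to_csv(config.out / "pse.csv", index=False, float_format=_CSV_FLOAT)
    slope = stats.fit_pse_slope(pse)
    (config.out / "pse_slope.json").write_text(
        json.dumps(
            {"slope_deg_s_per_noise": slope.slope, "se": slope.se, "t": slope.t,
             "df": slope.df, "p": slope.p, "ci95": list(slope.ci),
             "n_subjects": slope.n_subjects, "method": slope.method},
            indent=2, sort_keys=True,
        )
    )
    return ["pse.csv", "pse_slope.json"]


def _stage_fit(config: RunConfig) -> list[str]:
    df = pd.read_csv(_need(config.out / "grand_traces.csv", "reduce"))
    grid = config.grid()
    observed = {
        (float(v), float(p)): (sub["time_s"].to_numpy(), sub["bias_deg"].to_numpy())
        for (v, p), sub in df.groupby(["velocity", "noise"])
    }
    spec = fitting.FitSpec(free=tuple(config.fit_free), n_starts=config.fit_n_starts)
    result = fitting.fit(observed, spec, grid=grid)
    (config.out / "model_fit.json").write_text(
        json.dumps(
            {
                "params": dataclasses.asdict(result.params),
                "free": list(config.fit_free),
                "sse": result.sse,
                "r2_by_condition": {f"{v}|{p}": r for (v, p), r in result.r2_by_condition.items()},
                "n_starts": result.n_starts,
                "n_converged": result.n_converged,
                "warnings": result.warnings,
            },
            indent=2, sort_keys=True,
        )
    )
    pred = fitting.predict_all(result.params, grid=grid)
    parts = []
    for (v, p), (t, y) in sorted(pred.items()):
        parts.append(pd.DataFrame({"velocity": v, "noise": p, "time_s": t, "bias_deg": y}))
    pd.concat(parts, ignore_index=True).to_csv(
        config.out / "predicted_traces.csv", index=False, float_format=_CSV_FLOAT
    )
    return ["model_fit.json", "predicted_traces.csv"]


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "reduce": _stage_reduce,
    "stats": _stage_stats,
    "pse": _stage_pse,
    "fit": _stage_fit,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    config.out.mkdir(parents=True, exist_ok=True)
    cfg_dict = {k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()}
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stages": [],
    }
    for stage in config.stages:
        t0 = _time.time()
        artifacts = _STAGE_FUNCS[stage](config)
        manifest["stages"].append(
            {"name": stage, "status": "completed", "artifacts": artifacts,
             "elapsed_s": round(_time.time() - t0, 3),
             "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S")}
        )
    (config.out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def simulate_to_csv(
    out_path: str | Path,
    velocity_deg_s: float = 16.0,
    noise_fraction: float = 0.0,
    direction: str = "CCW",
    params: ModelParams | None = None,
    static_pre_s: float = 10.0,
    motion_s: float = 30.0,
    static_post_s: float = 10.0,
    dt: float = 1.0 / 30.0,
) -> pd.DataFrame:
    """Simulate one trial of the estimator and export the tidy trajectory CSV."""
    from .model import apply_noise_attenuation

    params = params or ModelParams()
    params = apply_noise_attenuation(params, noise_fraction)
    protocol = trial_protocol(velocity_deg_s, direction, static_pre_s, motion_s,
                              static_post_s, dt)
    res = simulate(protocol, params)
    df = pd.DataFrame(
        {
            "time_s": res.time,
            "gx": res.g[:, 0], "gy": res.g[:, 1], "gz": res.g[:, 2],
            "omega_deg_s": res.omega[:, 0],
            "bias_deg": res.bias,
        }
    )
    df.to_csv(out_path, index=False, float_format=_CSV_FLOAT)
    return df
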