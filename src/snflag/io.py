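"""File formats, run manifests, and the end-to-end pipeline.

CSV schemas
-----------
Incubation trace (one file per plant-day):
    ``time_s, ethylene_ppb, co2_ppm, h2o_frac, phase[, a0_ppm]``
    with phase in {background, acetylene, dark}; times in seconds since
    acetylene injection (background rows negative).

Measurement table (the regulation model's input):
    ``plant_id, species, symbiosis, biome, growth_temp, direction, day,
    snf_norm[, snf_ci_lo, snf_ci_hi], day0_respiration``

Every pipeline run writes a manifest (config hash, input checksums, seeds)
next to its outputs, and a JSON-lines log with one record per stage event.
All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence(root).spawn``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chamber import ChamberError, GasTimeSeries
from .groups import anova_tl, covariate_test
from .regulation import (
    ConvergenceError,
    GroupingSpec,
    LaggedSigmoidModel,
    RegulationError,
    exclude_nonfixing,
    model_selection,
)
from .simulate import simulate_cohort, study_cohort_spec

INCUBATION_COLUMNS = ("time_s", "ethylene_ppb", "co2_ppm", "h2o_frac", "phase")
MEASUREMENT_COLUMNS = ("plant_id", "day", "snf_norm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


def read_incubation_csv(path, a0_ppm: float | None = None) -> GasTimeSeries:
    """Parse and validate one incubation trace.

    Malformed (non-numeric / missing) rows are reported with their file line
    numbers; a0 may come from an ``a0_ppm`` column or the argument.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in INCUBATION_COLUMNS if c not in df.columns]
    if missing:
        raise ChamberError(f"{path}: missing columns {missing}")
    bad_lines = []
    for col in ("time_s", "ethylene_ppb", "co2_ppm", "h2o_frac"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 1-indexing
        df[col] = vals
    if bad_lines:
        raise ChamberError(f"{path}: malformed rows at lines {sorted(set(bad_lines))}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ChamberError(f"{path}: time_s is not strictly increasing")
    if a0_ppm is None:
        if "a0_ppm" in df.columns:
            a0_ppm = float(df["a0_ppm"].iloc[0])
        else:
            raise ChamberError(f"{path}: a0_ppm column absent and no a0 given")
    phases = set(df["phase"])
    if "acetylene" in phases and "background" not in phases:
        raise ChamberError(f"{path}: SNF incubation lacks a background phase")
    return GasTimeSeries(
        time_s=t,
        ethylene_ppb=df["ethylene_ppb"].to_numpy(dtype=float),
        co2_ppm=df["co2_ppm"].to_numpy(dtype=float),
        h2o_frac=df["h2o_frac"].to_numpy(dtype=float),
        a0_ppm=a0_ppm,
        phase=df["phase"].to_numpy(dtype=object),
    )


def write_incubation_csv(series: GasTimeSeries, path) -> None:
    df = pd.DataFrame({
        "time_s": series.time_s,
        "ethylene_ppb": series.ethylene_ppb,
        "co2_ppm": series.co2_ppm,
        "h2o_frac": series.h2o_frac,
        "phase": series.phase,
        "a0_ppm": series.a0_ppm,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurement_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise RegulationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise RegulationError(f"{path}: empty measurement table")
    return df


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    inputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    timestamp: float = field(default_factory=time.time)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def stage_seeds(root_seed: int, stages=("simulate", "flux", "fit", "bootstrap")) -> dict[str, int]:
    """Deterministic per-stage seeds: SeedSequence(root).spawn, folded to < 2^31."""
    children = np.random.SeedSequence(root_seed).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(stages, children)}


class _JsonLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("", encoding="utf-8")

    def write(self, **record) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record, default=str) + "\n")


def _candidate_specs(config: dict) -> list[GroupingSpec]:
    raw = config.get("candidates") or [{"r": "global"}, {"r": "by_symbiosis"}]
    specs = []
    for c in raw:
        specs.append(GroupingSpec(
            k=c.get("k", "per_plant"), tl=c.get("tl", "per_plant"),
            r=c.get("r", "global"), sigma=c.get("sigma", "shared"),
            name=c.get("name"),
        ))
    return specs


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Run measurement assembly -> exclusion -> fitting -> selection ->
    timescales -> group inference, writing all outputs and a manifest.

    ``config`` keys: ``seed``, ``direction``, one of ``input.measurements_csv``
    or ``simulate`` (cohort settings), plus optional ``exclusion_threshold``,
    ``candidates`` (grouping structures), ``n_starts``, ``anova`` (bool).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonLog(out / "log.jsonl")
    root_seed = int(config.get("seed", 0))
    seeds = stage_seeds(root_seed)
    direction = config.get("direction", "up")
    cfg_bytes = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = RunManifest(config_hash=_sha256(cfg_bytes), seed=root_seed, stage_seeds=seeds)

    # -- assemble the measurement table
    stage = "assembly"
    try:
        if "input" in config and config["input"].get("measurements_csv"):
            path = config["input"]["measurements_csv"]
            table = read_measurement_csv(path)
            manifest.inputs[str(path)] = _sha256(Path(path).read_bytes())
        elif "simulate" in config:
            sim = config["simulate"]
            spec = study_cohort_spec(
                direction=direction,
                n_plants=int(sim.get("n_plants", 4)),
                noise_frac=float(sim.get("noise_frac", 0.05)),
                n_nonfixing=int(sim.get("n_nonfixing", 0)),
            )
            table, truth = simulate_cohort(spec, seed=seeds["simulate"])
            truth.to_csv(out / "truth.csv", index=False)
        else:
            raise RegulationError("config needs 'input.measurements_csv' or 'simulate'")
        if len(table) == 0:
            raise RegulationError("empty measurement table")
        log.write(stage=stage, n_rows=len(table), n_plants=table["plant_id"].nunique())
    except (RegulationError, ChamberError, OSError) as exc:
        log.write(stage=stage, error=str(exc))
        raise PipelineError(stage, str(exc)) from exc

    # -- exclusion
    stage = "exclusion"
    threshold = float(config.get("exclusion_threshold", 0.0))
    table, exclusions = exclude_nonfixing(table, threshold)
    (out / "exclusions.json").write_text(json.dumps(exclusions, indent=2))
    log.write(stage=stage, threshold=threshold, n_excluded=len(exclusions))
    table.to_csv(out / "measurements.csv", index=False)

    # -- fit candidates and select
    stage = "fit"
    n_starts = int(config.get("n_starts", 20))
    fits = []
    try:
        for spec in _candidate_specs(config):
            model = LaggedSigmoidModel(table, direction=direction, grouping=spec)
            res = model.fit(n_starts=n_starts)
            log.write(stage=stage, model=spec.label, nll=res.nll,
                      converged=res.converged,
                      aicc=res.aicc if res.converged else None)
            fits.append(res)
        selection = model_selection(fits)
    except (RegulationError, ConvergenceError) as exc:
        log.write(stage=stage, error=str(exc))
        raise PipelineError(stage, str(exc)) from exc
    best = selection.best
    fits_out = {
        "direction": direction,
        "selected": best.model.grouping.label,
        "lrt_p": selection.lrt_p,
        "dropped": selection.dropped,
        "table": selection.table.to_dict(orient="records"),
        "params": best.params,
        "nll": best.nll,
        "aicc": best.aicc,
        "n_obs": best.nobs,
        "plant_params": best.plant_params().to_dict(orient="records"),
    }
    (out / "fits.json").write_text(json.dumps(fits_out, indent=2, default=float))

    # -- timescales
    stage = "timescales"
    try:
        ts = best.timescales(per="plant")
        ts_group = best.timescales(per="r_group")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        log.write(stage=stage, error=str(exc))
        raise PipelineError(stage, str(exc)) from exc
    ts.to_csv(out / "timescales.csv", index=False)
    ts_group.to_csv(out / "timescales_groups.csv", index=False)
    log.write(stage=stage, n_plants=len(ts))

    # -- group inference on per-plant tL (thin-curve fit family)
    stage = "group_inference"
    if config.get("anova", True):
        try:
            pp = best.plant_params().rename(columns={"tL": "tl"})
            factor_cols = [c for c in ("symbiosis", "growth_temp", "biome", "species")
                           if c in pp.columns and pp[c].nunique() >= 2]
            if factor_cols and len(pp) >= 4:
                result = anova_tl(pp)
                out_json = {
                    "best": result["best"],
                    "ranking": result["ranking"].to_dict(orient="records"),
                }
                cov_results = {}
                meta_cov = table.groupby("plant_id")["day0_respiration"].first() if (
                    "day0_respiration" in table.columns) else None
                if meta_cov is not None:
                    pp2 = pp.merge(meta_cov.rename("day0_respiration"), on="plant_id")
                    cov_results["day0_respiration"] = covariate_test(pp2, "day0_respiration")
                out_json["covariates"] = cov_results
                (out / "anova.json").write_text(json.dumps(out_json, indent=2, default=float))
                log.write(stage=stage, best=result["best"])
            else:
                log.write(stage=stage, skipped="not enough factor levels or plants")
        except RegulationError as exc:
            log.write(stage=stage, error=str(exc))
            raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
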