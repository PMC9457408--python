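"""End-to-end pipeline: simulate -> segment -> quantify -> correct -> gate
-> profile -> derivative.

All randomness flows from one root seed: the population draw uses the seed
itself, the noise realisation ``seed + NOISE_OFFSET``, and the matched
untagged control ``seed + CONTROL_OFFSET`` (population) /
``+ CONTROL_NOISE_OFFSET`` (noise), so a full run is reproducible
bit-for-bit from the config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CycleprofError, ValidationError
from .io import write_records
from .profiles import BinnedProfile, fold_change, profile_records
from .quantify import (GateSet, apply_gates, fit_background,
                       measure_population, subtract_background)
from .derivative import RidgeCurve, ridge_analysis
from .synthetic import (NoiseParams, PopulationParams, preset,
                        sample_population)

logger = logging.getLogger("cycleprof.pipeline")

NOISE_OFFSET = 500_000
CONTROL_OFFSET = 700_000
CONTROL_NOISE_OFFSET = 900_000

__all__ = ["PipelineConfig", "RunResult", "run_pipeline", "simulate_records",
           "default_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serialisable)."""

    preset: str = "cdc13"
    n_cells: int = 5000
    n_control: int = 5000
    seed: int = 1
    population: PopulationParams = field(default_factory=PopulationParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    gates: GateSet = field(default_factory=GateSet)
    top_p: float = 15.0
    erosion_radius: int = 3
    split_septated: bool = True
    bin_width: float = 0.33
    min_count: int = 500
    bimodality_method: str = "dip"
    bimodality_alpha: float = 0.05
    profile_value: str = "mean_intensity"
    ridge_value: str = "nuclear_mean_1"
    grid_size: int = 256
    bandwidth: str = "silverman"
    smooth_window: int = 7

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("population", PopulationParams),
                         ("noise", NoiseParams), ("gates", GateSet)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for f in dataclasses.fields(sub):
                    if f.name in sub_d and isinstance(sub_d[f.name], list):
                        sub_d[f.name] = tuple(sub_d[f.name])
                d[key] = sub(**sub_d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data or {})


def default_config() -> PipelineConfig:
    return PipelineConfig()


@dataclass
class RunResult:
    records: pd.DataFrame
    gated: pd.DataFrame
    profile: BinnedProfile
    ridge: RidgeCurve | None
    manifest: dict
    outdir: Path | None = None


def simulate_records(config: PipelineConfig, *, control: bool = False) -> pd.DataFrame:
    """Simulate and measure one population per the config (or its matched
    untagged control)."""
    model = preset("untagged") if control else preset(config.preset)
    n = config.n_control if control else config.n_cells
    pop_seed = config.seed + (CONTROL_OFFSET if control else 0)
    noise_seed = config.seed + (CONTROL_NOISE_OFFSET if control else NOISE_OFFSET)
    specs = sample_population(config.population, model, n, pop_seed)
    noise = dataclasses.replace(config.noise, seed=noise_seed)
    return measure_population(specs, config.population, noise,
                              top_p=config.top_p,
                              erosion_radius=config.erosion_radius,
                              split=config.split_septated)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CycleprofError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig, outdir=None) -> RunResult:
    """Run the full pipeline and (optionally) write the output bundle.

    Stages: simulate tagged strain and untagged control, measure per-cell
    records, fit and subtract the linear-in-length background, gate, bin
    into a length profile with bimodality stop, and run the density-ridge
    derivative analysis on the configured nuclear proxy.
    """
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "preset": config.preset, "started": time.time()}

    with _stage("simulate"):
        records = simulate_records(config)
        control = simulate_records(config, control=True)
    manifest["n_cells_simulated"] = config.n_cells
    manifest["n_records"] = int(len(records))
    manifest["n_control_records"] = int(len(control))
    logger.info("simulated %d cells -> %d records (+%d control)",
                config.n_cells, len(records), len(control))

    with _stage("background"):
        models = fit_background(control, bin_width=config.bin_width,
                                min_count=max(10, config.min_count // 10))
        corrected = subtract_background(records, models)
    manifest["background"] = {k: {"slope": m.slope, "intercept": m.intercept}
                              for k, m in models.items()}

    with _stage("gate"):
        passed, gate_counts = apply_gates(corrected, config.gates)
        gated = corrected.loc[passed].reset_index(drop=True)
    manifest["gates"] = gate_counts
    logger.info("gate attrition: %s", gate_counts)

    with _stage("profile"):
        prof = profile_records(gated, value_col=config.profile_value,
                               bin_width=config.bin_width,
                               min_count=config.min_count,
                               method=config.bimodality_method,
                               alpha=config.bimodality_alpha,
                               seed=config.seed)
    manifest["bins_retained"] = int(len(prof))
    manifest["stop_index"] = prof.stop_index
    manifest["septation_length_um"] = prof.septation_length_marker
    manifest["fold_change"] = fold_change(prof)
    logger.info("profile: %d bins retained, stop=%s, fold=%.4f",
                len(prof), prof.stop_index, manifest["fold_change"])

    ridge_curve = None
    if config.ridge_value:
        with _stage("derivative"):
            sub = gated.dropna(subset=[config.ridge_value])
            sub = sub[sub["n_nuclei"] == 1] if "n_nuclei" in sub else sub
            if len(sub) >= 50:
                ridge_curve = ridge_analysis(
                    sub["length_um"].to_numpy(),
                    sub[config.ridge_value].to_numpy(),
                    grid_size=config.grid_size, bandwidth=config.bandwidth,
                    smooth_window=config.smooth_window)

    manifest["finished"] = time.time()
    result = RunResult(records=corrected, gated=gated, profile=prof,
                       ridge=ridge_curve, manifest=manifest)
    if outdir is not None:
        result.outdir = _write_bundle(result, config, Path(outdir))
    return result


def _profile_frame(prof: BinnedProfile) -> pd.DataFrame:
    df = pd.DataFrame({
        "bin_center_um": prof.bin_centers,
        "bin_mean": prof.bin_means,
        "ci95_low": prof.ci95_low,
        "ci95_high": prof.ci95_high,
        "n": prof.n_per_bin,
    })
    if prof.normalized_means is not None:
        df["normalized_mean"] = prof.normalized_means
    df["pre_stop"] = (np.arange(len(df)) < prof.stop_index
                      if prof.stop_index is not None else True)
    return df


def _ridge_frame(curve: RidgeCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "length_um": curve.grid_lengths,
        "ridge_intensity": curve.ridge_intensity,
        "smoothed_intensity": curve.smoothed_intensity,
        "dIdL": curve.dIdL,
        "dIdL_over_L": curve.dIdL / curve.grid_lengths,
    })


def _write_bundle(result: RunResult, config: PipelineConfig, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    write_records(outdir / "records.csv", result.records)
    write_records(outdir / "records_gated.csv", result.gated)
    _profile_frame(result.profile).to_csv(outdir / "profile.csv", index=False)
    if result.ridge is not None:
        _ridge_frame(result.ridge).to_csv(outdir / "ridge.csv", index=False)
    (outdir / "config.yaml").write_text(config.to_yaml())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return outdir
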