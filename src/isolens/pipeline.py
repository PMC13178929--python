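"""End-to-end orchestration: simulate/load, validate, fit, compare, report.

A run either loads layer/fish/baseline CSVs or simulates them from the
named lake presets, then per lake: filters cores and outermost layers,
fits the hierarchical δ15N regression, and summarizes the posterior;
across lakes it builds the pairwise posterior-overlap tables, lifetime
isotope metrics, and baseline summaries, and writes everything plus a
JSON manifest (seed, config hash, maximum R-hat, counts) to the output
directory. Per-lake child seeds are derived from the master seed by a
stable hash of the lake name, so results do not depend on lake order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from isolens import lens_data
from isolens.hier_model import ModelSpec, PosteriorDraws, build_model_data, fit_population, summarize
from isolens.lens_data import BaselineSample, FishRecord, LayerRecord, filter_regression_layers
from isolens.overlap import pairwise_overlap_table
from isolens.synthetic import default_presets, generate_baselines, generate_lake
from isolens.trophic import TrophicConfig, baseline_summary, lifetime_delta_by_fish

__all__ = ["RunConfig", "run_all", "chronology_export", "lake_seed"]

log = logging.getLogger("isolens")

POPULATION_PARAMS = ["mu_alpha", "mu_beta", "sigma_alpha", "sigma_beta", "sigma_resid"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``presets`` (simulate) or ``layer_table`` (load) must
    be set. ``n_baseline`` controls how many baseline samples per
    habitat are simulated per lake in preset mode.
    """

    out_dir: str | Path = "isolens_out"
    seed: int = 0
    presets: list[str] | None = None
    layer_table: str | Path | None = None
    fish_table: str | Path | None = None
    baseline_table: str | Path | None = None
    n_baseline: int = 10
    model: ModelSpec = field(default_factory=ModelSpec)
    trophic: TrophicConfig = field(default_factory=TrophicConfig)

    def __post_init__(self) -> None:
        if (self.presets is None) == (self.layer_table is None):
            raise ValueError(
                "exactly one of presets or layer_table must be given"
            )


def lake_seed(master_seed: int, lake: str) -> int:
    """Stable per-lake child seed (independent of lake order)."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(lake.encode())) % (2**31)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), default=str, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, index=False, float_format=float_format)


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Output files (in ``config.out_dir``): ``layers.csv``,
    ``baselines.csv``, per-lake ``draws_<lake>.csv`` and the pooled
    ``summary.csv`` (posterior summary table), ``overlap.csv``,
    ``metrics.csv``, ``baseline_summary.csv``, ``chronologies.csv`` and
    ``manifest.json``. Any stage failure raises with the stage named;
    nothing is written until all stages have succeeded.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)

    # ---- stage: inputs -------------------------------------------------
    stage = "input"
    try:
        if config.presets is not None:
            presets = default_presets()
            unknown = [p for p in config.presets if p not in presets]
            if unknown:
                raise ValueError(f"unknown presets {unknown}")
            layers: list[LayerRecord] = []
            fishes: list[FishRecord] = []
            baselines: list[BaselineSample] = []
            truths = {}
            for name in config.presets:
                s = lake_seed(config.seed, name)
                ls, fs, truth = generate_lake(presets[name], seed=s)
                layers += ls
                fishes += fs
                baselines += generate_baselines(
                    presets[name], config.n_baseline, seed=s + 1
                )
                truths[name] = truth
            log.info("simulated %d lakes, %d layers", len(config.presets), len(layers))
        else:
            layers = lens_data.read_layer_table(config.layer_table)
            fishes = (
                lens_data.read_fish_table(config.fish_table)
                if config.fish_table
                else []
            )
            baselines = (
                lens_data.read_baseline_table(config.baseline_table)
                if config.baseline_table
                else []
            )
            truths = {}
            log.info("loaded %d layers from %s", len(layers), config.layer_table)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    lakes = sorted({r.lake for r in layers})

    # ---- stage: fit ----------------------------------------------------
    stage = "fit"
    draws_by_lake: dict[str, PosteriorDraws] = {}
    summaries = []
    try:
        for lake in lakes:
            lake_layers = [
                r
                for r in layers
                if r.lake == lake and r.sample_kind == "primary" and r.eye == "right"
            ]
            by_fish: dict[str, list[LayerRecord]] = {}
            for r in lake_layers:
                by_fish.setdefault(r.fish_id, []).append(r)
            kept: list[LayerRecord] = []
            for chron in by_fish.values():
                kept += filter_regression_layers(chron)
            data = build_model_data(kept)
            spec = dataclasses.replace(config.model, seed=lake_seed(config.seed, lake))
            t = time.time()
            draws = fit_population(data, spec)
            draws_by_lake[lake] = draws
            summaries.append(summarize(draws))
            log.info(
                "fitted %s: %d fish, %d layers, %.1fs",
                lake,
                data.n_fish,
                data.n_layers,
                time.time() - t,
            )
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    summary = pd.concat(summaries, ignore_index=True)
    rhat_max = float(summary["rhat"].max())

    # ---- stage: compare ------------------------------------------------
    stage = "compare"
    overlaps = []
    try:
        if len(lakes) >= 2:
            for parameter, pname in (("intercept", "mu_alpha"), ("slope", "mu_beta")):
                pooled = {
                    lake: draws_by_lake[lake].pooled(pname) for lake in lakes
                }
                overlaps.append(pairwise_overlap_table(pooled, parameter))
        overlap_df = (
            pd.concat(overlaps, ignore_index=True)
            if overlaps
            else pd.DataFrame(
                columns=["parameter", "lake_a", "lake_b", "overlap"]
            )
        )
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: metrics ------------------------------------------------
    stage = "metrics"
    try:
        metrics = pd.concat(
            [
                lifetime_delta_by_fish(layers, "d15N"),
                lifetime_delta_by_fish(layers, "d13C"),
            ],
            ignore_index=True,
        )
        base_df = (
            baseline_summary(baselines, config.trophic)
            if baselines
            else pd.DataFrame()
        )
        chron = chronology_export(layers, baselines)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: write --------------------------------------------------
    stage = "write"
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        lens_data.write_layer_table(layers, out_dir / "layers.csv")
        if fishes:
            lens_data.write_fish_table(fishes, out_dir / "fish.csv")
        if baselines:
            lens_data.write_baseline_table(baselines, out_dir / "baselines.csv")
        for lake, draws in draws_by_lake.items():
            pop = draws.to_frame()
            pop = pop[pop["parameter"].isin(POPULATION_PARAMS)]
            _write_csv(pop, out_dir / f"draws_{lake}.csv", "%.8g")
        _write_csv(summary, out_dir / "summary.csv")
        _write_csv(overlap_df.round({"overlap": 3}), out_dir / "overlap.csv")
        _write_csv(metrics, out_dir / "metrics.csv")
        if not base_df.empty:
            _write_csv(base_df, out_dir / "baseline_summary.csv")
        _write_csv(chron, out_dir / "chronologies.csv")
        for name, truth in truths.items():
            truth.to_json(out_dir / f"truth_{name}.json")

        import isolens

        manifest = {
            "package_version": isolens.__version__,
            "numpy_version": np.__version__,
            "seed": int(config.seed),
            "config_hash": _config_hash(config),
            "lakes": lakes,
            "n_layers_raw": len(layers),
            "n_layers_model": {
                lake: int(d.n_layers) for lake, d in draws_by_lake.items()
            },
            "n_fish": {lake: int(d.n_fish) for lake, d in draws_by_lake.items()},
            "rhat_max": rhat_max,
            "n_overlap_pairs": int(len(overlap_df)),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    log.info("run complete in %.1fs; rhat_max=%.4f", time.time() - t0, rhat_max)
    return manifest


def chronology_export(
    layers: Sequence[LayerRecord],
    baselines: Sequence[BaselineSample] = (),
) -> pd.DataFrame:
    """Per-fish ordered chronologies for plotting, with baseline bands.

    Unlike the model input this keeps core and outermost layers: rows are
    ordered by ascending diameter within fish (core first, i.e. earliest
    life), and each row carries the lake's littoral/pelagic baseline
    mean and SD for δ13C when baseline samples are available.
    """
    prim = [r for r in layers if r.sample_kind == "primary"]
    df = lens_data.layers_to_frame(prim)
    df = df.sort_values(["lake", "fish_id", "diameter_mm"]).reset_index(drop=True)
    if baselines:
        bs = baseline_summary(baselines)
        bands = bs[bs["isotope"] == "d13C"].pivot_table(
            index="lake", columns="habitat", values=["mean", "sd"]
        )
        for habitat in ("littoral", "pelagic"):
            if ("mean", habitat) in bands.columns:
                df[f"{habitat}_d13C_mean"] = df["lake"].map(bands[("mean", habitat)])
                df[f"{habitat}_d13C_sd"] = df["lake"].map(bands[("sd", habitat)])
    return df
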