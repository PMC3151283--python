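"""End-to-end pipeline: simulate -> analyze -> summarize, with a manifest.

A run executes the requested stages in order, writes every intermediate as
CSV/TIFF/JSON under the output directory, and records a manifest (config,
seed, package version, sha256 of every output) so identical config + seed
yields hash-identical results.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .assay import anova_one_way, anova_two_way, summarize
from .config import RunConfig, SimAssayConfig, SimFrapConfig, SimJunctionConfig
from .errors import ConfigurationError
from .frap import analyze_frap_experiment
from . import io
from .junctions import quantify_junction_image
from .synthetic import simulate_assay_table, simulate_frap_traces, simulate_junction_images

logger = logging.getLogger(__name__)


def demo_config(out_dir: str | Path = "frapquant_demo", seed: int = 0) -> RunConfig:
    """Canonical end-to-end example: simulate all three data kinds with the
    default study-like parameters, then run every analysis stage on them."""
    return RunConfig(
        stages=["simulate", "frap-fit", "junctions", "assay-stats"],
        seed=seed,
        out_dir=Path(out_dir),
        frap_sim=SimFrapConfig(mobile_fraction_true=0.5, noise_sd_frac=0.02, photofade_rate=0.002, n_traces=12),
        junction_sim=SimJunctionConfig(n_junctions_pos=15, n_junctions_neg=15, noise_sd=0.2),
        assay_sim=SimAssayConfig(noise_sd=10.0),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from one run seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("frapquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    outputs: dict[str, list[str]] = {}
    paths = {
        "traces_csv": config.traces_csv,
        "conditions_csv": config.conditions_csv,
        "protein_tiff": config.protein_tiff,
        "marker_tiff": config.marker_tiff,
        "mask_tiff": config.mask_tiff,
        "assay_csv": config.assay_csv,
    }
    try:
        for stage in config.stages:
            outputs[stage] = [str(p.relative_to(out)) for p in _run_stage(stage, config, out, paths)]
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "version": __version__,
        "outputs": {
            stage: {name: _sha256(out / name) for name in names} for stage, names in outputs.items()
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _require(paths: dict, key: str) -> Path:
    p = paths[key]
    if p is None:
        raise ConfigurationError(f"stage needs {key} but it was not configured and no simulate stage produced it")
    p = Path(p)
    if not p.exists():
        raise ConfigurationError(f"input path does not exist: {p}")
    return p


def _run_stage(stage: str, config: RunConfig, out: Path, paths: dict) -> list[Path]:
    if stage == "simulate":
        return _stage_simulate(config, out, paths)
    if stage == "frap-fit":
        traces = io.read_traces_csv(_require(paths, "traces_csv"))
        conditions = io.read_conditions_csv(paths["conditions_csv"]) if paths["conditions_csv"] else None
        fits, summaries = analyze_frap_experiment(
            traces, conditions, convention=config.fraction_convention, plateau_mode=config.plateau_mode
        )
        written = [
            fits.to_csv(out / "frap_fits.csv", index=False) or out / "frap_fits.csv",
            io.write_json(io.summaries_to_json_obj(summaries), out / "frap_summary.json"),
        ]
        return written
    if stage == "junctions":
        table = quantify_junction_image(
            io.read_image(_require(paths, "protein_tiff")),
            io.read_image(_require(paths, "marker_tiff")),
            io.read_mask(_require(paths, "mask_tiff")),
            threshold=config.marker_threshold,
        )
        table.to_csv(out / "junction_records.csv", index=False)
        return [out / "junction_records.csv"]
    if stage == "assay-stats":
        import pandas as pd

        table = pd.read_csv(_require(paths, "assay_csv"))
        if config.assay_design == "twoway":
            result = anova_two_way(table)
        else:
            groups = [g["value"].to_numpy() for _, g in table.groupby("factor_a", sort=False)]
            result = anova_one_way(groups)
        group_summaries = {
            f"{a}/{b}": summarize(g["value"].to_numpy())
            for (a, b), g in table.groupby(["factor_a", "factor_b"], sort=False)
        }
        return [
            io.write_json(
                {"anova": result.to_frame().to_dict(orient="records"), "groups": group_summaries},
                out / "assay_stats.json",
            )
        ]
    raise ConfigurationError(f"unknown stage {stage!r}")


def _stage_simulate(config: RunConfig, out: Path, paths: dict) -> list[Path]:
    written: list[Path] = []
    frap_seed, junc_seed, assay_seed = _spawn_seeds(config.seed, 3)
    if config.frap_sim is not None:
        cfg = config.frap_sim.model_copy(update={"seed": frap_seed})
        traces, truth = simulate_frap_traces(cfg)
        written.append(io.write_traces_csv(traces, out / "frap_traces.csv"))
        written.append(io.write_json(truth.to_dict(orient="records"), out / "frap_truth.json"))
        paths["traces_csv"] = out / "frap_traces.csv"
    if config.junction_sim is not None:
        cfg = config.junction_sim.model_copy(update={"seed": junc_seed})
        imgset = simulate_junction_images(cfg)
        written.append(io.write_image(imgset.protein, out / "protein.tiff"))
        written.append(io.write_image(imgset.marker, out / "marker.tiff"))
        written.append(io.write_image(imgset.mask, out / "mask.tiff"))
        imgset.truth.to_csv(out / "junction_truth.csv", index=False)
        written.append(out / "junction_truth.csv")
        paths.update(
            protein_tiff=out / "protein.tiff", marker_tiff=out / "marker.tiff", mask_tiff=out / "mask.tiff"
        )
    if config.assay_sim is not None:
        cfg = config.assay_sim.model_copy(update={"seed": assay_seed})
        table, truth = simulate_assay_table(cfg)
        table.to_csv(out / "assay_table.csv", index=False)
        truth.to_csv(out / "assay_truth.csv", index=False)
        written += [out / "assay_table.csv", out / "assay_truth.csv"]
        paths["assay_csv"] = out / "assay_table.csv"
    if not written:
        raise ConfigurationError("simulate stage enabled but no simulation config given")
    return written
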