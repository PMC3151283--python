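"""Configuration models for the synthetic generators and the pipeline.

All stochastic components are driven by an explicit integer seed, so any
configuration replayed with the same seed reproduces its outputs bit for bit.
Configs are pydantic models and round-trip losslessly through JSON/YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

PREBLEACH = "prebleach"
POSTBLEACH = "postbleach"

#: Default acquisition schedule: three pre-bleach frames 10 s apart, then a
#: post-bleach frame immediately after the bleach (t = 0), one at 5 s, and one
#: every 15 s out to 5 minutes.
DEFAULT_SCHEDULE: Tuple[Tuple[float, str], ...] = tuple(
    [(-30.0, PREBLEACH), (-20.0, PREBLEACH), (-10.0, PREBLEACH), (0.0, POSTBLEACH), (5.0, POSTBLEACH)]
    + [(float(t), POSTBLEACH) for t in range(15, 301, 15)]
)


class SimFrapConfig(BaseModel):
    """Ground truth for simulated FRAP traces.

    The bleached-region signal recovers as a single exponential towards a
    plateau set by the mobile fraction; the whole-cell signal decays by
    acquisition photofading, and the same relative fading multiplies the
    bleached-region signal.
    """

    prebleach_mean: float = Field(1000.0, gt=0, description="pre-bleach ROI intensity (AU)")
    bleach_depth: float = Field(0.2, ge=0, lt=1, description="fraction of pre-bleach intensity left at t=0")
    mobile_fraction_true: float = Field(0.5, ge=0, le=1)
    tau_true: float = Field(0.05, gt=0, description="recovery rate constant (1/s)")
    photofade_rate: float = Field(0.0, ge=0, description="whole-cell fading rate (1/s)")
    noise_sd_frac: float = Field(0.0, ge=0, description="multiplicative noise sd as a fraction of the ideal value")
    schedule: Sequence[Tuple[float, str]] = DEFAULT_SCHEDULE
    n_traces: int = Field(1, ge=1)
    seed: int = 0

    @field_validator("schedule")
    @classmethod
    def _check_schedule(cls, sched):
        sched = tuple((float(t), str(p)) for t, p in sched)
        phases = {p for _, p in sched}
        if not phases <= {PREBLEACH, POSTBLEACH}:
            raise ValueError(f"unknown phase labels: {phases - {PREBLEACH, POSTBLEACH}}")
        pre = [t for t, p in sched if p == PREBLEACH]
        post = [t for t, p in sched if p == POSTBLEACH]
        if len(pre) < 3:
            raise ValueError("schedule needs >=3 prebleach frames")
        if len(post) < 5:
            raise ValueError("schedule needs >=5 postbleach frames")
        for seq in (pre, post):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError("schedule times must be strictly increasing within phase")
        if post[0] != 0.0:
            raise ValueError("first postbleach frame defines t=0")
        return sched


class SimJunctionConfig(BaseModel):
    """Ground truth for a synthetic two-channel junction image.

    Emulates a mixed culture in which only one population carries the marker:
    junctions are thin line segments with a configured per-pixel mean in the
    junction-protein channel, and the marker channel is elevated only on
    marker-positive junctions.
    """

    image_size: Tuple[int, int] = (256, 256)
    n_junctions_pos: int = Field(10, ge=0)
    n_junctions_neg: int = Field(10, ge=1, description="reference population; must exist")
    junction_intensity_pos: float = Field(4.0, ge=0)
    junction_intensity_neg: float = Field(8.0, ge=0)
    marker_intensity_pos: float = Field(50.0, ge=0)
    background: float = Field(1.0, ge=0)
    noise_sd: float = Field(0.0, ge=0, description="additive Gaussian noise sd (AU)")
    seed: int = 0

    @field_validator("image_size")
    @classmethod
    def _check_size(cls, size):
        if size[0] < 16 or size[1] < 16:
            raise ValueError("image_size must be at least 16x16")
        return size


class SimAssayConfig(BaseModel):
    """Ground truth for a balanced two-factor replicate table."""

    cell_means: dict[str, dict[str, float]] = Field(
        default={"MCF7": {"basal": 100.0, "Ad5": 150.0}, "FLCARMCF7": {"basal": 100.0, "Ad5": 200.0}},
        description="factorA level -> factorB level -> true cell mean (AU)",
    )
    n_replicates: int = Field(4, ge=2)
    noise_sd: float = Field(0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_balanced(self):
        b_levels = [tuple(sorted(v)) for v in self.cell_means.values()]
        if len(set(b_levels)) != 1:
            raise ValueError("cell_means must define the same factorB levels for every factorA level")
        return self


class RunConfig(BaseModel):
    """Full pipeline run: which stages to execute, on what, with what seed."""

    stages: list[Literal["simulate", "frap-fit", "junctions", "assay-stats"]]
    seed: int = 0
    out_dir: Path = Path("frapquant_run")
    # simulate stage
    frap_sim: Optional[SimFrapConfig] = None
    junction_sim: Optional[SimJunctionConfig] = None
    assay_sim: Optional[SimAssayConfig] = None
    # analysis inputs (defaulted to the simulate stage outputs when present)
    traces_csv: Optional[Path] = None
    conditions_csv: Optional[Path] = None
    protein_tiff: Optional[Path] = None
    marker_tiff: Optional[Path] = None
    mask_tiff: Optional[Path] = None
    assay_csv: Optional[Path] = None
    assay_design: Literal["oneway", "twoway"] = "twoway"
    # convention flags
    fraction_convention: Literal["full_scale", "percent_of_prebleach"] = "full_scale"
    plateau_mode: Literal["fitted", "empirical"] = "fitted"
    marker_threshold: Optional[float] = None
    pool_images: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.model_validate(yaml.safe_load(text))

    def to_yaml(self) -> str:
        import json

        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)


def load_config(path: str | Path, model: type[BaseModel]):
    """Load a JSON or YAML config file into the given model (YAML is a JSON
    superset, so one loader covers both)."""
    return model.model_validate(yaml.safe_load(Path(path).read_text()))
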