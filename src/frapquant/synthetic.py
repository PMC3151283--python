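"""Synthetic data with known ground truth for every analysis stage.

Three generators emulate the three experimental designs the analysis modules
quantify: FRAP time series at cell junctions, two-channel confocal images of
a mixed marker-positive/negative culture, and balanced two-factor replicate
tables. Each takes an explicit seed and is bit-reproducible, so parameter
recovery can be asserted against the configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import POSTBLEACH, PREBLEACH, SimAssayConfig, SimFrapConfig, SimJunctionConfig
from .errors import ConfigurationError
from .frap import FrapTrace


def ideal_frap_signal(config: SimFrapConfig, times: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Noise-free, fading-free bleach-ROI signal at the scheduled frames.

    Pre-bleach frames sit at the pre-bleach mean; from the first post-bleach
    frame (t = 0) the signal recovers as
    I(t) = I_post + M * (I_pre - I_post) * (1 - exp(-tau * t)),
    where I_post = bleach_depth * I_pre and M is the mobile fraction.
    """
    i_pre = config.prebleach_mean
    i_post = config.bleach_depth * i_pre
    ideal = np.full(times.shape, i_pre, dtype=float)
    post = phases == POSTBLEACH
    t = times[post]
    ideal[post] = i_post + config.mobile_fraction_true * (i_pre - i_post) * (1.0 - np.exp(-config.tau_true * t))
    return ideal


def simulate_frap_traces(config: SimFrapConfig) -> tuple[list[FrapTrace], pd.DataFrame]:
    """Simulate FRAP traces and return them with their ground-truth table.

    Both channels fade with the same multiplicative exponential
    exp(-photofade_rate * (t - t_first)) and carry independent multiplicative
    Gaussian noise with sd = noise_sd_frac * ideal value.
    """
    rng = np.random.default_rng(config.seed)
    times = np.array([t for t, _ in config.schedule], dtype=float)
    phases = np.array([p for _, p in config.schedule], dtype=object)
    if not (phases == PREBLEACH).any():
        raise ConfigurationError("schedule has no prebleach frames")

    fade = np.exp(-config.photofade_rate * (times - times[0]))
    ideal_roi = ideal_frap_signal(config, times, phases)
    ideal_cell = config.prebleach_mean * fade

    traces, truth = [], []
    for i in range(config.n_traces):
        trace_id = f"trace_{i:03d}"
        roi = ideal_roi * fade
        cell = ideal_cell.copy()
        if config.noise_sd_frac > 0:
            roi = roi * (1.0 + config.noise_sd_frac * rng.standard_normal(roi.shape))
            cell = cell * (1.0 + config.noise_sd_frac * rng.standard_normal(cell.shape))
        traces.append(FrapTrace(trace_id=trace_id, times=times, roi_values=roi, cell_values=cell, phase=phases))
        truth.append(
            {
                "trace_id": trace_id,
                "tau_true": config.tau_true,
                "mobile_fraction_true": config.mobile_fraction_true,
                "bleach_depth_true": config.bleach_depth,
                "photofade_rate": config.photofade_rate,
            }
        )
    return traces, pd.DataFrame(truth)


@dataclass
class JunctionImageSet:
    """A simulated two-channel image with its junction label mask and truth."""

    protein: np.ndarray  # junction-protein channel, float AU
    marker: np.ndarray  # marker channel (elevated on marker-positive junctions)
    mask: np.ndarray  # integer labels, 0 = background
    truth: pd.DataFrame  # junction_id, marker_status, true per-pixel means, pixel_count


def _segment_pixels(rng: np.random.Generator, tile: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel offsets of one junction segment placed inside a tile.

    Segments are 1-3 px wide lines, 10-20 px long, axis-aligned or diagonal;
    the analysis only uses per-pixel means, so no curvature is modelled.
    """
    length = int(rng.integers(10, 21))
    width = int(rng.integers(1, 4))
    orient = rng.choice(["h", "v", "d"])
    if orient == "h":
        rr, cc = np.meshgrid(np.arange(width), np.arange(length), indexing="ij")
    elif orient == "v":
        rr, cc = np.meshgrid(np.arange(length), np.arange(width), indexing="ij")
    else:  # diagonal: widen along rows
        idx = np.arange(length)
        rr = (idx[None, :] + np.arange(width)[:, None])
        cc = np.broadcast_to(idx[None, :], rr.shape)
    rr, cc = rr.ravel(), cc.ravel()
    r_extent, c_extent = rr.max() + 1, cc.max() + 1
    r0 = int(rng.integers(0, tile - r_extent + 1))
    c0 = int(rng.integers(0, tile - c_extent + 1))
    return rr + r0, cc + c0


def simulate_junction_images(config: SimJunctionConfig) -> JunctionImageSet:
    """Render non-overlapping junction segments into a two-channel image.

    Each junction occupies its own tile of a regular grid (one px gutter), so
    labels can never touch or overlap; marker status is assigned to junctions
    at random. Additive Gaussian noise (sd = noise_sd) is applied per channel.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_size
    tile = 24  # fits the longest segment (20 px + width margin)
    capacity = (rows // (tile + 1)) * (cols // (tile + 1))
    n_total = config.n_junctions_pos + config.n_junctions_neg
    if n_total > capacity:
        raise ConfigurationError(
            f"{n_total} junctions do not fit a {rows}x{cols} image without overlap (capacity {capacity})"
        )

    protein = np.full((rows, cols), config.background, dtype=float)
    marker = np.full((rows, cols), config.background, dtype=float)
    mask = np.zeros((rows, cols), dtype=np.int32)

    tiles = [(r, c) for r in range(rows // (tile + 1)) for c in range(cols // (tile + 1))]
    chosen = [tiles[i] for i in rng.choice(len(tiles), size=n_total, replace=False)]
    status = np.array(["positive"] * config.n_junctions_pos + ["negative"] * config.n_junctions_neg)
    rng.shuffle(status)

    truth = []
    for label, ((tr, tc), st) in enumerate(zip(chosen, status), start=1):
        rr, cc = _segment_pixels(rng, tile)
        rr, cc = rr + tr * (tile + 1), cc + tc * (tile + 1)
        intensity = config.junction_intensity_pos if st == "positive" else config.junction_intensity_neg
        protein[rr, cc] = intensity
        if st == "positive":
            marker[rr, cc] = config.marker_intensity_pos
        mask[rr, cc] = label
        truth.append(
            {
                "junction_id": label,
                "marker_status": st,
                "protein_mean_true": float(intensity),
                "marker_mean_true": float(config.marker_intensity_pos if st == "positive" else config.background),
                "pixel_count": int(len(rr)),
            }
        )

    if config.noise_sd > 0:
        protein = protein + config.noise_sd * rng.standard_normal(protein.shape)
        marker = marker + config.noise_sd * rng.standard_normal(marker.shape)
    return JunctionImageSet(protein=protein, marker=marker, mask=mask, truth=pd.DataFrame(truth))


def simulate_assay_table(config: SimAssayConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced two-factor replicate table: value = cell mean + N(0, noise_sd)."""
    rng = np.random.default_rng(config.seed)
    rows, truth = [], []
    for a_level, b_means in config.cell_means.items():
        for b_level, mean in b_means.items():
            values = mean + config.noise_sd * rng.standard_normal(config.n_replicates)
            rows.extend(
                {"factor_a": a_level, "factor_b": b_level, "replicate": r + 1, "value": float(v)}
                for r, v in enumerate(values)
            )
            truth.append({"factor_a": a_level, "factor_b": b_level, "mean_true": mean})
    return pd.DataFrame(rows), pd.DataFrame(truth)
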