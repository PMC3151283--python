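"""Per-pixel junctional intensity quantification.

Intensity is measured per junction as the mean over that junction's pixels
(the per-pixel calibration that makes junctions of different size/area
comparable), junctions are classified by their marker-channel mean, and the
marker-negative population serves as the reference whose mean normalized
intensity is 1 by construction. A densitometry helper applies the analogous
loading-control / percent-of-control normalization to gel band values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from .errors import DataError


@dataclass
class JunctionRecord:
    """Per-pixel mean intensity of one labelled junction."""

    junction_id: int
    pixel_count: int
    mean_intensity: float  # per-pixel mean, AU
    marker_status: str = "unset"  # positive | negative | unset
    image_id: str = ""
    relative_intensity: float = float("nan")


def measure_junctions(channel: np.ndarray, mask: np.ndarray, image_id: str = "") -> list[JunctionRecord]:
    """Per-pixel mean of the channel over each labelled junction.

    ``mask`` is an integer label image (0 = background); one record is
    returned per label, with mean_intensity = sum over the label's pixels /
    pixel count. Size-independent by construction.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask)
    if channel.shape != mask.shape:
        raise DataError(f"channel shape {channel.shape} != mask shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise DataError("mask must be an integer label image")
    if mask.max() <= 0:
        raise DataError("mask contains no junction labels")
    props = regionprops_table(mask, intensity_image=channel, properties=("label", "num_pixels", "intensity_mean"))
    return [
        JunctionRecord(
            junction_id=int(lab),
            pixel_count=int(n),
            mean_intensity=float(mu),
            image_id=image_id,
        )
        for lab, n, mu in zip(props["label"], props["num_pixels"], props["intensity_mean"])
    ]


def suggest_marker_threshold(marker: np.ndarray, mask: np.ndarray, n_sd: float = 5.0) -> float:
    """Background mean + n_sd * background sd of the marker channel.

    Background pixels are those outside every junction label. Convenience
    default for classification when no explicit threshold is configured.
    """
    marker = np.asarray(marker, dtype=float)
    bg = marker[np.asarray(mask) == 0]
    if bg.size == 0:
        raise DataError("mask leaves no background pixels to estimate the threshold from")
    return float(bg.mean() + n_sd * bg.std(ddof=0))


def classify_by_marker(
    records: Sequence[JunctionRecord],
    marker_means: Sequence[float] | dict[int, float],
    threshold: float,
) -> list[JunctionRecord]:
    """Set marker_status from each junction's marker-channel mean.

    positive iff marker mean > threshold; a mean exactly equal to the
    threshold is negative (deterministic tie rule). ``marker_means`` is a
    parallel sequence or a junction_id -> mean mapping.
    """
    if isinstance(marker_means, dict):
        try:
            means = [marker_means[r.junction_id] for r in records]
        except KeyError as exc:
            raise DataError(f"missing marker value for junction {exc.args[0]}") from exc
    else:
        means = list(marker_means)
        if len(means) != len(records):
            raise DataError("one marker mean per record required")
    out = []
    for rec, mu in zip(records, means):
        if mu is None or np.isnan(mu):
            raise DataError(f"missing marker value for junction {rec.junction_id}")
        status = "positive" if mu > threshold else "negative"
        out.append(JunctionRecord(**{**rec.__dict__, "marker_status": status}))
    return out


def normalize_relative(records: Sequence[JunctionRecord]) -> list[JunctionRecord]:
    """Normalize intensities to the marker-negative reference population.

    relative_intensity = mean_intensity / (mean over negative junctions), so
    the negative population's mean relative intensity is 1 and positives are
    expressed relative to it. Scale-invariant under global rescaling.
    """
    neg = [r.mean_intensity for r in records if r.marker_status == "negative"]
    if not neg:
        raise DataError("no marker-negative junctions; the reference population is required")
    ref = float(np.mean(neg))
    if ref == 0:
        raise DataError("marker-negative population mean is 0; cannot normalize")
    return [
        JunctionRecord(**{**r.__dict__, "relative_intensity": r.mean_intensity / ref})
        for r in records
    ]


def records_to_frame(records: Iterable[JunctionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def quantify_junction_image(
    protein: np.ndarray,
    marker: np.ndarray,
    mask: np.ndarray,
    threshold: Optional[float] = None,
    image_id: str = "",
) -> pd.DataFrame:
    """measure -> classify -> normalize for one image; returns a record table."""
    records = measure_junctions(protein, mask, image_id=image_id)
    marker_means = {r.junction_id: r.mean_intensity for r in measure_junctions(marker, mask, image_id=image_id)}
    if threshold is None:
        threshold = suggest_marker_threshold(marker, mask)
    records = normalize_relative(classify_by_marker(records, marker_means, threshold))
    return records_to_frame(records)


@dataclass
class DensitometryRecord:
    """One Western-blot band normalized to its loading control."""

    condition: str
    band_value: float
    loading_value: float
    ratio: float
    percent_of_control: float


def densitometry_relative(
    band_values: Sequence[float],
    loading_values: Sequence[float],
    conditions: Sequence[str],
    control_label: str,
) -> list[DensitometryRecord]:
    """Loading-control normalization and percent-of-control scaling.

    ratio = band / loading; percent_of_control = 100 * ratio / (mean ratio of
    the control condition), so the control condition averages 100%.
    """
    if not (len(band_values) == len(loading_values) == len(conditions)):
        raise DataError("band, loading and condition sequences must align")
    loading = np.asarray(loading_values, dtype=float)
    if np.any(loading <= 0):
        raise DataError("loading-control values must be positive")
    ratios = np.asarray(band_values, dtype=float) / loading
    control = ratios[np.asarray(conditions, dtype=object) == control_label]
    if control.size == 0:
        raise DataError(f"control condition {control_label!r} not present")
    ref = float(control.mean())
    if ref == 0:
        raise DataError("control ratio mean is 0; cannot express percent of control")
    return [
        DensitometryRecord(
            condition=str(c),
            band_value=float(b),
            loading_value=float(l),
            ratio=float(r),
            percent_of_control=float(100.0 * r / ref),
        )
        for c, b, l, r in zip(conditions, band_values, loading, ratios)
    ]
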