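"""Reading and writing the package's on-disk formats.

FRAP traces travel as long-format CSV (time_s, phase, roi_mean, cell_mean,
trace_id); images as single-plane TIFFs (one per channel, plus an integer
label-mask TIFF); ground truth as JSON/CSV sidecars; assay tables as
long-format CSV (factor_a, factor_b, value).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .frap import ConditionSummary, FrapTrace

TRACE_COLUMNS = ["trace_id", "time_s", "phase", "roi_mean", "cell_mean"]


def write_traces_csv(traces: Iterable[FrapTrace], path: str | Path) -> Path:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "time_s": tr.times,
                    "phase": tr.phase,
                    "roi_mean": tr.roi_values,
                    "cell_mean": tr.cell_values,
                }
            )
        )
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path) -> list[FrapTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"traces CSV {path} missing columns {sorted(missing)}")
    traces = []
    for trace_id, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            FrapTrace(
                trace_id=str(trace_id),
                times=grp["time_s"].to_numpy(dtype=float),
                roi_values=grp["roi_mean"].to_numpy(dtype=float),
                cell_values=grp["cell_mean"].to_numpy(dtype=float),
                phase=grp["phase"].to_numpy(dtype=object),
            )
        )
    if not traces:
        raise DataError(f"traces CSV {path} is empty")
    return traces


def read_conditions_csv(path: str | Path) -> dict[str, str]:
    """trace_id -> condition label mapping from a two-column CSV."""
    df = pd.read_csv(path)
    if not {"trace_id", "condition"} <= set(df.columns):
        raise DataError(f"conditions CSV {path} needs trace_id and condition columns")
    return dict(zip(df["trace_id"].astype(str), df["condition"].astype(str)))


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        tifffile.imwrite(path, arr.astype(np.int32))
    else:
        tifffile.imwrite(path, arr.astype(np.float32))
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(Path(path))
    if not np.issubdtype(mask.dtype, np.integer):
        raise DataError(f"label mask {path} must be an integer TIFF, got {mask.dtype}")
    return mask


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summaries_to_json_obj(summaries: Sequence[ConditionSummary]) -> dict:
    return {s.condition: {"n_cells": s.n_cells, **s.metrics} for s in summaries}
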