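"""FRAP recovery-curve quantification.

The analysis chain mirrors standard junctional-FRAP practice: each trace is
corrected for acquisition photofading against its own whole-cell signal,
expressed as a percentage of its pre-bleach intensity, and the post-bleach
frames are fitted to a single-exponential recovery

    I(t) = P - (P - I0) * exp(-tau * t)

with free plateau ``P``, post-bleach level ``I0`` and rate ``tau``. The
recovery half-life is ``t_1/2 = ln 2 / tau`` and the mobile fraction is the
percentage recovery at plateau, with the immobile fraction its complement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import POSTBLEACH, PREBLEACH
from .errors import DataError

logger = logging.getLogger(__name__)

TAU_BOUNDS = (1e-5, 10.0)  # 1/s; a fit pinned at either bound is flagged
_MIN_AMPLITUDE_PCT = 1e-6  # below this the rate is unidentifiable


@dataclass(frozen=True)
class FrapTrace:
    """One cell's FRAP time series.

    Times are in seconds with the first post-bleach frame at t = 0 and
    pre-bleach frames at negative times. ``roi_values`` is the mean intensity
    of the bleached region, ``cell_values`` the whole-cell mean on the same
    frames.
    """

    trace_id: str
    times: np.ndarray
    roi_values: np.ndarray
    cell_values: np.ndarray
    phase: np.ndarray
    roi_um: float = 4.0  # bleach-square side length, metadata only

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        roi = np.asarray(self.roi_values, dtype=float)
        cell = np.asarray(self.cell_values, dtype=float)
        phase = np.asarray(self.phase, dtype=object)
        if not (len(times) == len(roi) == len(cell) == len(phase)):
            raise DataError(f"trace {self.trace_id}: unequal array lengths")
        if np.any(np.diff(times) <= 0):
            raise DataError(f"trace {self.trace_id}: times must be strictly increasing")
        unknown = set(phase) - {PREBLEACH, POSTBLEACH}
        if unknown:
            raise DataError(f"trace {self.trace_id}: unknown phase labels {unknown}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "roi_values", roi)
        object.__setattr__(self, "cell_values", cell)
        object.__setattr__(self, "phase", phase)

    @property
    def is_prebleach(self) -> np.ndarray:
        return self.phase == PREBLEACH

    @property
    def is_postbleach(self) -> np.ndarray:
        return self.phase == POSTBLEACH

    def n_frames(self, phase: str) -> int:
        return int(np.sum(self.phase == phase))


@dataclass
class FrapFit:
    """Fitted single-exponential kinetics for one normalized trace."""

    trace_id: str
    tau: float  # 1/s
    post_bleach_pct: float  # fitted I0, % of pre-bleach
    plateau_pct: float  # fitted asymptote P, % of pre-bleach
    rss: float
    converged: bool
    n_points: int
    t_half: float = math.nan  # s
    mobile_pct: float = math.nan
    immobile_pct: float = math.nan
    message: str = ""


@dataclass
class ConditionSummary:
    """Pooled per-condition statistics (mean +/- SEM over converged cells)."""

    condition: str
    n_cells: int
    metrics: dict = field(default_factory=dict)  # metric -> {"mean":..., "sem":...}


def _prebleach_mean(values: np.ndarray, pre_mask: np.ndarray, what: str) -> float:
    if not pre_mask.any():
        raise DataError(f"no prebleach frames to reference the {what} signal")
    return float(values[pre_mask].mean())


def correct_photofading(trace: FrapTrace) -> FrapTrace:
    """Divide the ROI signal by the whole-cell fading factor.

    The fading factor at each frame is the whole-cell mean divided by its
    pre-bleach mean, so a cell that faded to 80% has its ROI values divided
    by 0.8 at that frame. The output's whole-cell channel is set to the
    constant pre-bleach mean to record that fading has been removed.
    """
    if np.any(trace.cell_values <= 0):
        raise DataError(f"trace {trace.trace_id}: non-positive whole-cell values")
    ref = _prebleach_mean(trace.cell_values, trace.is_prebleach, "whole-cell")
    fade = trace.cell_values / ref
    return replace(
        trace,
        roi_values=trace.roi_values / fade,
        cell_values=np.full_like(trace.cell_values, ref),
    )


def normalize_to_prebleach(trace: FrapTrace) -> FrapTrace:
    """Express the ROI signal as a percentage of its pre-bleach mean."""
    ref = _prebleach_mean(trace.roi_values, trace.is_prebleach, "ROI")
    if ref <= 0:
        raise DataError(f"trace {trace.trace_id}: prebleach ROI mean must be positive")
    scale = 100.0 / ref
    return replace(trace, roi_values=trace.roi_values * scale, cell_values=trace.cell_values * scale)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    i0 = float(y[0])
    p = float(np.mean(y[-3:]))
    tau = 0.05
    half_level = 0.5 * (i0 + p)
    crossed = np.nonzero(y >= half_level)[0] if p >= i0 else np.nonzero(y <= half_level)[0]
    if crossed.size and t[crossed[0]] > 0:
        tau = math.log(2.0) / float(t[crossed[0]])
    return p, i0, min(max(tau, TAU_BOUNDS[0] * 10), TAU_BOUNDS[1] / 10)


def fit_single_exponential(trace: FrapTrace) -> FrapFit:
    """Least-squares single-exponential fit over the post-bleach frames.

    Requires a normalized trace (pre-bleach mean = 100). Pre-bleach frames do
    not enter the fit. A flat trace (no recovery amplitude) or a rate pinned
    at its bounds yields ``converged=False``; the fit is still returned.
    """
    post = trace.is_postbleach
    if post.sum() < 3:
        raise DataError(f"trace {trace.trace_id}: need >=3 postbleach frames, got {int(post.sum())}")
    t = trace.times[post]
    y = trace.roi_values[post]

    def residuals(params):
        p, i0, tau = params
        return (p - (p - i0) * np.exp(-tau * t)) - y

    p0 = _initial_guess(t, y)
    lower = [0.0, 0.0, TAU_BOUNDS[0]]
    upper = [200.0, 200.0, TAU_BOUNDS[1]]
    x0 = np.clip(p0, lower, upper)
    sol = least_squares(residuals, x0=x0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    p_hat, i0_hat, tau_hat = map(float, sol.x)
    rss = float(np.sum(sol.fun**2))

    converged = bool(sol.success)
    message = sol.message if not sol.success else ""
    if abs(p_hat - i0_hat) < _MIN_AMPLITUDE_PCT:
        converged = False
        message = "recovery amplitude ~ 0; tau unidentifiable"
    elif tau_hat <= TAU_BOUNDS[0] * (1 + 1e-6) or tau_hat >= TAU_BOUNDS[1] * (1 - 1e-6):
        converged = False
        message = f"tau at bound ({tau_hat:g}/s)"

    return FrapFit(
        trace_id=trace.trace_id,
        tau=tau_hat,
        post_bleach_pct=i0_hat,
        plateau_pct=p_hat,
        rss=rss,
        converged=converged,
        n_points=int(post.sum()),
        message=message,
    )


def compute_half_life(tau: float) -> float:
    """Recovery half-life t_1/2 = ln 0.5 / (-tau) = ln 2 / tau, in seconds."""
    if tau <= 0:
        raise DataError(f"tau must be positive, got {tau}")
    return math.log(0.5) / (-tau)


FractionConvention = Literal["full_scale", "percent_of_prebleach"]


def compute_fractions(fit: FrapFit, convention: FractionConvention = "full_scale") -> tuple[float, float]:
    """Mobile / immobile percentages from a converged fit.

    ``full_scale`` (default) expresses the plateau recovery as a fraction of
    the bleached (recoverable) range: mobile = 100*(P - I0)/(100 - I0).
    ``percent_of_prebleach`` reads the plateau percentage literally:
    mobile = P. In both conventions immobile = 100 - mobile.
    """
    if fit.post_bleach_pct >= 100.0:
        raise DataError(
            f"trace {fit.trace_id}: post-bleach level {fit.post_bleach_pct:.1f}% >= 100% (no bleach occurred)"
        )
    if convention == "full_scale":
        mobile = 100.0 * (fit.plateau_pct - fit.post_bleach_pct) / (100.0 - fit.post_bleach_pct)
    elif convention == "percent_of_prebleach":
        mobile = fit.plateau_pct
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return mobile, 100.0 - mobile


def process_trace(
    trace: FrapTrace,
    convention: FractionConvention = "full_scale",
    plateau_mode: Literal["fitted", "empirical"] = "fitted",
) -> FrapFit:
    """Correct, normalize and fit a single raw trace, filling all metrics."""
    normalized = normalize_to_prebleach(correct_photofading(trace))
    fit = fit_single_exponential(normalized)
    if plateau_mode == "empirical":
        post_vals = normalized.roi_values[normalized.is_postbleach]
        fit.plateau_pct = float(np.mean(post_vals[-3:]))
    if fit.converged:
        fit.t_half = compute_half_life(fit.tau)
        fit.mobile_pct, fit.immobile_pct = compute_fractions(fit, convention)
    return fit


_SUMMARY_METRICS = ("t_half", "mobile_pct", "immobile_pct", "tau", "plateau_pct", "post_bleach_pct")

#: Conditions pooled from fewer converged cells than this trigger a warning,
#: matching the study design of pooling from at least 12 cells per condition.
MIN_CELLS_PER_CONDITION = 12


def analyze_frap_experiment(
    traces: Iterable[FrapTrace],
    conditions: dict[str, str] | Sequence[str] | None = None,
    convention: FractionConvention = "full_scale",
    plateau_mode: Literal["fitted", "empirical"] = "fitted",
) -> tuple[pd.DataFrame, list[ConditionSummary]]:
    """Run the full per-trace chain and pool per condition.

    ``conditions`` maps trace_id -> condition label (or is a parallel list);
    omitted, all traces share the label "all". Returns a per-trace fit table
    (non-converged traces included, flagged) and mean +/- SEM summaries over
    converged traces per condition.
    """
    traces = list(traces)
    if isinstance(conditions, dict) or conditions is None:
        cond_of = conditions or {}
        labels = [cond_of.get(tr.trace_id, "all") for tr in traces]
    else:
        labels = list(conditions)
        if len(labels) != len(traces):
            raise DataError("one condition label per trace required")

    rows = []
    for trace, label in zip(traces, labels):
        fit = process_trace(trace, convention=convention, plateau_mode=plateau_mode)
        rows.append({"condition": label, **fit.__dict__})
    fits = pd.DataFrame(rows)
    if fits.empty:
        raise DataError("no traces supplied")

    summaries = []
    for label, grp in fits.groupby("condition", sort=False):
        ok = grp[grp["converged"]]
        if len(ok) == 0:
            raise DataError(f"condition {label!r}: no converged traces")
        if len(ok) < MIN_CELLS_PER_CONDITION:
            logger.warning(
                "condition %r pooled from only %d converged cells (<%d)",
                label, len(ok), MIN_CELLS_PER_CONDITION,
            )
        metrics = {}
        for m in _SUMMARY_METRICS:
            vals = ok[m].to_numpy(dtype=float)
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
            metrics[m] = {"mean": float(vals.mean()), "sem": sem}
        summaries.append(ConditionSummary(condition=str(label), n_cells=int(len(ok)), metrics=metrics))
    return fits, summaries
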