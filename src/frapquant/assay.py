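"""Replicate summaries and one-/two-way ANOVA for assay tables.

The ANOVA is computed directly from the sums-of-squares decomposition so
every number is auditable: between/within for one-way, and the balanced
two-factor decomposition (A, B, interaction, residual) for two-way. The only
special function involved is the F-distribution upper tail (a regularized
incomplete beta), taken from scipy. Unbalanced two-way layouts are rejected
rather than silently approximated by a Type-I/II/III choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UnsupportedDesignError


@dataclass
class EffectRow:
    """One line of an ANOVA table."""

    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class AnovaResult:
    effects: list[EffectRow] = field(default_factory=list)
    residual_ss: float = 0.0
    residual_df: int = 0
    total_ss: float = 0.0

    def __getitem__(self, name: str) -> EffectRow:
        for row in self.effects:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.__dict__ for r in self.effects]
        rows.append(
            {
                "name": "residual",
                "ss": self.residual_ss,
                "df": self.residual_df,
                "ms": self.residual_ss / self.residual_df if self.residual_df else math.nan,
                "f": math.nan,
                "p": math.nan,
            }
        )
        return pd.DataFrame(rows)


def permeability_index(lower: float, reference: float) -> float:
    """Fold change of lower-chamber tracer fluorescence over a reference.

    For transwell permeability, the reference is typically the mean basal
    (untreated) lower-chamber reading; 1.0 means no change.
    """
    if reference <= 0:
        raise DataError(f"reference fluorescence must be positive, got {reference}")
    return float(lower) / float(reference)


def permeability_fold_table(table: pd.DataFrame, basal_label: str, condition_col: str = "condition",
                            value_col: str = "value") -> pd.DataFrame:
    """Per-replicate fold-over-basal for a long-format condition table."""
    if basal_label not in set(table[condition_col]):
        raise DataError(f"basal condition {basal_label!r} not present")
    basal_mean = float(table.loc[table[condition_col] == basal_label, value_col].mean())
    out = table.copy()
    out["fold_over_basal"] = [permeability_index(v, basal_mean) for v in table[value_col]]
    return out


def summarize(values: Sequence[float]) -> dict:
    """Mean, sample sd (n-1), SEM and n; sd/SEM are NaN for a single value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DataError("cannot summarize an empty group")
    n = int(arr.size)
    sd = float(arr.std(ddof=1)) if n > 1 else math.nan
    return {"mean": float(arr.mean()), "sd": sd, "sem": sd / math.sqrt(n) if n > 1 else math.nan, "n": n}


def _f_p(f: float, df1: int, df2: int) -> float:
    return float(stats.f.sf(f, df1, df2))


def anova_one_way(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from the between/within sums-of-squares decomposition."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DataError("one-way ANOVA needs >=2 groups")
    if any(a.size < 2 for a in arrays):
        raise DataError("every group needs n >= 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw if msw > 0 else (0.0 if ssb == 0 else math.inf)
    p = 1.0 if f == 0 else _f_p(f, df_b, df_w)
    return AnovaResult(
        effects=[EffectRow("group", ssb, df_b, msb, f, p)],
        residual_ss=ssw,
        residual_df=df_w,
        total_ss=float(((all_vals - grand) ** 2).sum()),
    )


def anova_two_way(table: pd.DataFrame, factor_a: str = "factor_a", factor_b: str = "factor_b",
                  value: str = "value") -> AnovaResult:
    """Balanced two-way ANOVA with interaction.

    SS_A and SS_B come from the marginal means, SS_AB from the cell means'
    departure from additivity, and the residual from within-cell scatter; in
    a balanced design these sum exactly to the total SS. Unbalanced tables
    raise UnsupportedDesignError.
    """
    a_levels = list(dict.fromkeys(table[factor_a]))
    b_levels = list(dict.fromkeys(table[factor_b]))
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise DataError("two-way ANOVA needs >=2 levels per factor")
    counts = table.groupby([factor_a, factor_b], sort=False)[value].count()
    if len(counts) != len(a_levels) * len(b_levels):
        raise UnsupportedDesignError("missing factor-level combinations; design must be complete")
    if counts.nunique() != 1:
        raise UnsupportedDesignError(f"unbalanced design (cell sizes {sorted(set(counts))}); not supported")
    n = int(counts.iloc[0])
    if n < 2:
        raise DataError("every cell needs n >= 2 replicates")

    a, b = len(a_levels), len(b_levels)
    y = np.empty((a, b, n), dtype=float)
    grouped = table.groupby([factor_a, factor_b], sort=False)[value]
    for (i, al) in enumerate(a_levels):
        for (j, bl) in enumerate(b_levels):
            y[i, j, :] = grouped.get_group((al, bl)).to_numpy()

    grand = y.mean()
    cell = y.mean(axis=2)
    a_mean = y.mean(axis=(1, 2))
    b_mean = y.mean(axis=(0, 2))

    ss_a = float(b * n * ((a_mean - grand) ** 2).sum())
    ss_b = float(a * n * ((b_mean - grand) ** 2).sum())
    ss_ab = float(n * ((cell - a_mean[:, None] - b_mean[None, :] + grand) ** 2).sum())
    ss_res = float(((y - cell[:, :, None]) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())

    df_a, df_b_, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_res = a * b * (n - 1)
    ms_res = ss_res / df_res

    def row(name: str, ss: float, df: int) -> EffectRow:
        ms = ss / df
        f = ms / ms_res if ms_res > 0 else (0.0 if ss == 0 else math.inf)
        p = 1.0 if f == 0 else _f_p(f, df, df_res)
        return EffectRow(name, ss, df, ms, f, p)

    return AnovaResult(
        effects=[row("factor_a", ss_a, df_a), row("factor_b", ss_b, df_b_), row("interaction", ss_ab, df_ab)],
        residual_ss=ss_res,
        residual_df=df_res,
        total_ss=ss_tot,
    )
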