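"""Descriptive statistics for power-vector panels: marginal summaries,
device/time difference panels, and mean-power ratios.

The "95% confidence interval" reported alongside mean/SD/median in the
summary tables is the empirical 2.5th/97.5th percentile pair of the observed
values (linear-interpolation quantile rule), not a mean +/- 1.96 SD band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "AlignmentError",
    "component_summary",
    "summarize_panel",
    "difference_panel",
    "ratio_of_mean_powers",
]

_ROWS = ("mean", "sd", "median", "p2_5", "p97_5")


class AlignmentError(ValueError):
    """Two panels that must share an eye set do not."""


@dataclass(frozen=True)
class SummaryStats:
    """Mean / SD (n-1) / median / empirical 2.5 and 97.5 percentiles, with n."""

    mean: float
    sd: float
    median: float
    p2_5: float
    p97_5: float
    n: int


def component_summary(values: Sequence[float] | np.ndarray) -> SummaryStats:
    """Summarise one component across eyes.

    SD uses the n-1 denominator (NaN for n = 1); percentiles use linear
    interpolation.  Empty input raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty value set")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")
    lo, hi = np.percentile(x, [2.5, 97.5], method="linear")
    return SummaryStats(
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        p2_5=float(lo),
        p97_5=float(hi),
        n=int(x.size),
    )


def summarize_panel(frame: pd.DataFrame) -> pd.DataFrame:
    """Table-style summary (rows mean/sd/median/p2_5/p97_5) of every numeric column."""
    num = frame.select_dtypes(include=[np.number])
    data = {}
    for col in num.columns:
        s = component_summary(num[col].to_numpy())
        data[col] = [s.mean, s.sd, s.median, s.p2_5, s.p97_5]
    return pd.DataFrame(data, index=list(_ROWS))


def difference_panel(
    panel_a: pd.DataFrame, panel_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-eye componentwise differences A - B plus their summary table.

    Both frames must cover the same eyes (index) and components (columns);
    a mismatch raises :class:`AlignmentError` naming the offending ids.
    Differences are paired per eye, so the mean difference equals the
    difference of means exactly.
    """
    ids_a, ids_b = set(panel_a.index), set(panel_b.index)
    if ids_a != ids_b:
        raise AlignmentError(
            f"eye sets differ: only in A {sorted(ids_a - ids_b)}, only in B {sorted(ids_b - ids_a)}"
        )
    cols_a = [c for c in panel_a.columns if c in panel_b.columns]
    a = panel_a.loc[sorted(ids_a), cols_a].select_dtypes(include=[np.number])
    b = panel_b.loc[sorted(ids_a), a.columns]
    diff = a - b
    return diff, summarize_panel(diff)


def ratio_of_mean_powers(
    device_frame: pd.DataFrame, layer_a: str = "front", layer_b: str = "back"
) -> float:
    """Ratio of mean equivalent powers between two layers of one device.

    Expects a device sub-frame (columns ``<layer>_EQ`` etc., as produced by
    :meth:`cornvec.cohort_io.CohortPanel.device`).  The front/back ratio of a
    fixed-ratio schematic cornea is -0.376/0.040 * (R_back/R_front); measured
    cohorts deviate from it, which is what this diagnostic exposes.
    """
    mean_a = float(np.mean(device_frame[f"{layer_a}_EQ"]))
    mean_b = float(np.mean(device_frame[f"{layer_b}_EQ"]))
    if mean_b == 0.0:
        raise ZeroDivisionError(f"mean {layer_b} EQ is zero")
    return mean_a / mean_b
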