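"""Cohort-level metric phenotypes of lesion sizes.

Lesion cutting areas and projected diameters across an Early-AMD
cohort are strongly right-skewed and well described by a log-normal
distribution. This module provides the corresponding summaries: sample
statistics in pixel and metric units, log-normal fitting by the
moments of the log-values (the maximum-likelihood estimates), a
Shapiro–Wilk test of normality on the logs, and the Pearson
correlation between pixel-unit and metric-unit measurements that
justifies analysing metric values only.

By convention the single-lesion category "hyper-reflective material
only" is excluded from size statistics, since such lesions are not
deposits in the drusen/SDD sense; the exclusion list is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .mask_geometry import LesionGeometry
from .phenotyping import LesionType

__all__ = [
    "SizeSummary",
    "LogNormalFit",
    "summarize_sizes",
    "fit_lognormal",
    "test_lognormality",
    "unit_correlation",
    "size_histogram",
]

_METRICS = ("diameter_px", "diameter_um", "area_px", "area_um2")


@dataclass(frozen=True)
class SizeSummary:
    """Order statistics and moments of lesion sizes, per metric.

    ``stats[metric]`` maps ``{"minimum", "median", "mean", "st_dev",
    "maximum"}`` to floats for each of diameter (px, μm) and cutting
    area (px, μm²). ``st_dev`` is the sample standard deviation
    (ddof=1; 0 for a single observation).
    """

    n: int
    stats: Mapping[str, Mapping[str, float]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stats).T[
            ["minimum", "median", "mean", "st_dev", "maximum"]]


def summarize_sizes(
    geometries: Sequence[LesionGeometry],
    lesion_types: Optional[Sequence[LesionType]] = None,
    exclude: Iterable[LesionType] = (LesionType.HYPERREFLECTIVE_ONLY,),
) -> SizeSummary:
    """Sample statistics of diameters and cutting areas over a cohort.

    Parameters
    ----------
    geometries : sequence of LesionGeometry
        One entry per lesion, in pixel and metric units.
    lesion_types : sequence of LesionType, optional
        Parallel to ``geometries``; required for exclusions to apply.
    exclude : iterable of LesionType
        Types dropped before summarizing (default: hyper-reflective-only
        lesions).
    """
    exclude = frozenset(exclude)
    if lesion_types is not None:
        if len(lesion_types) != len(geometries):
            raise ValueError("lesion_types must parallel geometries")
        kept = [g for g, t in zip(geometries, lesion_types) if t not in exclude]
    else:
        kept = list(geometries)
    if not kept:
        raise ValueError("no lesions remain after exclusions")
    table: dict[str, dict[str, float]] = {}
    for metric in _METRICS:
        values = np.array([getattr(g, metric) for g in kept], dtype=float)
        table[metric] = {
            "minimum": float(values.min()),
            "median": float(np.median(values)),
            "mean": float(values.mean()),
            "st_dev": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            "maximum": float(values.max()),
        }
    return SizeSummary(n=len(kept), stats=table)


@dataclass(frozen=True)
class LogNormalFit:
    """Log-normal fit of a positive-valued sample.

    ``meanlog``/``sdlog`` are the sample mean and sample standard
    deviation of ``ln(values)`` — the maximum-likelihood location and
    scale of the log-normal. ``shapiro_w``/``shapiro_p`` test the
    normality of the log-values.
    """

    meanlog: float
    sdlog: float
    n: int
    shapiro_w: float
    shapiro_p: float


def _checked_logs(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"values must be positive and finite; offending index "
            f"{int(bad[0])} (value {arr[bad[0]]!r})")
    return np.log(arr)


def fit_lognormal(values: Sequence[float]) -> LogNormalFit:
    """Fit a log-normal by moments of logs and test log-normality.

    Requires at least 3 positive values. The Shapiro–Wilk statistic is
    computed on the natural-log values (the test is invariant under the
    base of the logarithm); beyond the supported range n > 5000 the test
    is skipped and ``shapiro_w``/``shapiro_p`` are NaN.
    """
    logs = _checked_logs(values)
    if logs.size < 3:
        raise ValueError(f"need at least 3 values, got {logs.size}")
    if logs.size > 5000:
        w, p = math.nan, math.nan
    else:
        w, p = stats.shapiro(logs)
    return LogNormalFit(
        meanlog=float(logs.mean()),
        sdlog=float(logs.std(ddof=1)),
        n=int(logs.size),
        shapiro_w=float(w),
        shapiro_p=float(p),
    )


def test_lognormality(values: Sequence[float],
                      alpha: float = 0.05) -> tuple[str, float, float]:
    """Shapiro–Wilk test of log-normality at level ``alpha``.

    Returns ``(decision, W, p)`` with decision ``"consistent with
    log-normal"`` iff ``p > alpha``, otherwise ``"log-normality
    rejected"``. Supported sample sizes: 3 ≤ n ≤ 5000.
    """
    logs = _checked_logs(values)
    if not 3 <= logs.size <= 5000:
        raise ValueError(
            f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={logs.size}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    w, p = stats.shapiro(logs)
    decision = ("consistent with log-normal" if p > alpha
                else "log-normality rejected")
    return decision, float(w), float(p)


def unit_correlation(values_px: Sequence[float],
                     values_um: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between pixel-unit and metric-unit sizes.

    Returns ``(r, p)`` with a two-sided p-value. Requires paired samples
    of equal length ≥ 3 with non-zero variance in both margins.
    """
    px = np.asarray(values_px, dtype=float)
    um = np.asarray(values_um, dtype=float)
    if px.shape != um.shape or px.ndim != 1:
        raise ValueError("paired one-dimensional samples of equal length required")
    if px.size < 3:
        raise ValueError(f"need at least 3 pairs, got {px.size}")
    if np.ptp(px) == 0 or np.ptp(um) == 0:
        raise ValueError("correlation undefined for a zero-variance margin")
    result = stats.pearsonr(px, um)
    return float(result.statistic), float(result.pvalue)


def size_histogram(values: Sequence[float], fit: Optional[LogNormalFit] = None,
                   title: str = "", path=None):
    """Histogram of sizes with the fitted log-normal density overlaid.

    Bin widths follow the Freedman–Diaconis rule. Purely presentational;
    returns the Matplotlib figure (and writes a PNG when ``path`` given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(arr, bins="fd", density=True, color="0.7", edgecolor="0.3")
    if fit is not None:
        grid = np.linspace(arr.min(), arr.max(), 400)
        density = stats.lognorm.pdf(grid, s=fit.sdlog,
                                    scale=math.exp(fit.meanlog))
        ax.plot(grid, density, color="purple", lw=2,
                label=f"log-normal (meanlog={fit.meanlog:.2f}, "
                      f"sdlog={fit.sdlog:.2f})")
        ax.legend(frameon=False)
    ax.set_title(title)
    ax.set_ylabel("density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
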