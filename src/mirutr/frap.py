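"""Protein-synthesis-rate quantification from FRAP build-up traces.

The assay: a cell expressing a destabilised GFP reporter (half-life ~2 h)
is photobleached, and the *build-up* of new fluorescence — i.e. fresh
protein synthesis — is recorded at fixed intervals (by default 21 frames
at 30 s).  Three summaries per cell/condition:

* **build-up curve** — cumulative fluorescence gain since the first
  post-bleach frame, as percent of the pre-bleach intensity;
* **slope** — ordinary least-squares slope of the build-up over the
  linear portion of the curve (frames 5-20 inclusive by default), in
  percent per frame — the per-cell synthesis-rate readout;
* **K_R50 crossing** — time at which a condition's mean build-up reaches
  half of the non-targeting control's maximal recovery, a model-free
  kinetic reference point.

Group comparison is one-way ANOVA over per-cell slopes with pairwise
two-sided Welch tests (Holm-adjusted by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FrapTrace",
    "FrapSummary",
    "normalize_buildup",
    "buildup_slope",
    "kr50",
    "crossing_time",
    "summarize_trace",
    "compare_slopes",
    "DEFAULT_SLOPE_WINDOW",
]

DEFAULT_SLOPE_WINDOW = (5, 20)


@dataclass
class FrapTrace:
    """One cell's post-bleach fluorescence time series."""

    cell_id: str
    condition: str
    times: np.ndarray       # seconds; frame 0 = first post-bleach frame
    intensities: np.ndarray
    pre_bleach: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError(f"trace {self.cell_id}: times/intensities mismatch")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"trace {self.cell_id}: times not strictly increasing")
        if self.pre_bleach <= 0:
            raise ValueError(f"trace {self.cell_id}: pre_bleach must be positive")
        if np.any(self.intensities < 0):
            raise ValueError(f"trace {self.cell_id}: negative intensity")


@dataclass
class FrapSummary:
    """Per-cell build-up curve and its kinetic summaries."""

    cell_id: str
    condition: str
    times: np.ndarray
    buildup: np.ndarray            # percent of pre-bleach
    slope_per_frame: float         # percent per frame
    slope_per_second: float        # percent per second


def normalize_buildup(trace: FrapTrace) -> np.ndarray:
    """Cumulative build-up in percent of pre-bleach intensity.

    ``buildup(t) = 100 * (F(t) - F(t0)) / pre_bleach`` with ``t0`` the
    first post-bleach frame, so the curve starts at exactly zero and is
    invariant to any common rescaling of camera gain.
    """
    f0 = trace.intensities[0]
    return 100.0 * (trace.intensities - f0) / trace.pre_bleach


def buildup_slope(
    buildup: np.ndarray,
    frame_window: tuple[int, int] = DEFAULT_SLOPE_WINDOW,
) -> float:
    """OLS slope (percent/frame) of the build-up over an inclusive window."""
    lo, hi = frame_window
    if hi >= len(buildup):
        raise ValueError(
            f"trace has {len(buildup)} frames; slope window {lo}-{hi} "
            f"requires at least {hi + 1}"
        )
    if hi - lo + 1 < 3:
        raise ValueError("slope window must contain at least 3 frames")
    frames = np.arange(lo, hi + 1, dtype=float)
    y = np.asarray(buildup, dtype=float)[lo : hi + 1]
    return float(np.polyfit(frames, y, 1)[0])


def kr50(control_buildups: list[np.ndarray]) -> float:
    """Half of the maximal mean recovery of the control condition.

    ``control_buildups`` are per-cell build-up curves (equal length) of the
    non-targeting control; the K_R50 level is 50 % of the maximum of their
    pointwise mean curve.
    """
    if not control_buildups:
        raise ValueError("kr50 requires at least one control trace")
    mean_curve = np.mean(np.vstack(control_buildups), axis=0)
    return float(0.5 * mean_curve.max())


def crossing_time(
    buildup: np.ndarray, times: np.ndarray, level: float
) -> float | None:
    """First time the curve reaches ``level``, linearly interpolated.

    Returns ``None`` when the curve never reaches the level.
    """
    y = np.asarray(buildup, dtype=float)
    t = np.asarray(times, dtype=float)
    above = y >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def summarize_trace(
    trace: FrapTrace,
    frame_window: tuple[int, int] = DEFAULT_SLOPE_WINDOW,
) -> FrapSummary:
    """Normalize one trace and extract its slope."""
    buildup = normalize_buildup(trace)
    slope = buildup_slope(buildup, frame_window)
    dt = float(np.median(np.diff(trace.times))) if trace.times.size > 1 else float("nan")
    return FrapSummary(
        cell_id=trace.cell_id,
        condition=trace.condition,
        times=trace.times,
        buildup=buildup,
        slope_per_frame=slope,
        slope_per_second=slope / dt,
    )


def compare_slopes(
    summaries: list[FrapSummary],
    adjust: str = "holm",
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA over per-cell slopes plus a pairwise p-value matrix.

    Conditions with fewer than two cells are excluded with a warning.
    Pairwise comparisons are two-sided Welch t-tests; ``adjust`` is any
    statsmodels ``multipletests`` method or ``"none"`` for raw p-values
    (the layout mirrors the descriptive pairwise tables of FRAP studies:
    symmetric, empty diagonal).
    """
    by_cond: dict[str, list[float]] = {}
    for s in summaries:
        by_cond.setdefault(s.condition, []).append(s.slope_per_frame)
    for cond in [c for c, v in by_cond.items() if len(v) < 2]:
        warnings.warn(f"condition {cond!r} has <2 cells; excluded from comparison")
        del by_cond[cond]
    if len(by_cond) < 2:
        raise ValueError("compare_slopes needs >=2 conditions with >=2 cells")
    conds = list(by_cond)
    groups = [np.asarray(by_cond[c]) for c in conds]
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, p_anova = 0.0, 1.0  # all observations identical
    else:
        res = stats.f_oneway(*groups)
        f_stat, p_anova = float(res.statistic), float(res.pvalue)
    pairs = list(combinations(range(len(conds)), 2))
    raw = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        if np.var(a) == 0 and np.var(b) == 0:
            raw.append(1.0 if np.mean(a) == np.mean(b) else 0.0)
        else:
            raw.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
    if adjust != "none" and raw:
        adj = multipletests(raw, method=adjust)[1]
    else:
        adj = raw
    mat = pd.DataFrame(np.nan, index=conds, columns=conds, dtype=float)
    for (i, j), p in zip(pairs, adj):
        mat.iloc[i, j] = mat.iloc[j, i] = float(p)
    return f_stat, p_anova, mat
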