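"""Growth-curve fitness metrics for plate-reader OD600 time series.

A well's growth curve is reduced to two complementary fitness readouts:

* the **inhibition ratio** ``W`` — the area under the (baseline-corrected)
  curve relative to a no-drug control, the quantity the checkerboard synergy
  analysis consumes; and
* the **average generation time** ``AvgG`` — minutes per doubling over the
  exponential phase, used for the isogenic drug–gene interaction assays.

Curves are smoothed (moving median then moving mean) before either metric is
extracted, so single mis-reads do not propagate into areas or slopes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GrowthCurve",
    "InhibitionRatio",
    "GenerationTime",
    "GrowthStatus",
    "smooth_curve",
    "auc",
    "inhibition_ratio",
    "avg_generation_time",
    "relative_fitness",
]

#: Minimum OD rise (max − first reading) required to call growth at all.
NO_GROWTH_RISE = 0.05

#: Floor applied inside the log2 transform so zero-rise points stay finite.
LOG_OD_FLOOR = 1e-3

#: Control areas at or below this (OD·min) cannot normalise anything.
DEGENERATE_AREA_FLOOR = 1e-6


class DegenerateControlError(ValueError):
    """The control curve has (numerically) zero area under it."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series.

    Parameters
    ----------
    times
        Measurement times in minutes, strictly increasing.
    ods
        OD600 readings, same length as ``times``, non-negative.
    well_id
        Opaque well label (e.g. ``"B7"``).
    condition
        Treatment descriptor: drug name(s) + doses, or ``"control"``.
    """

    times: np.ndarray
    ods: np.ndarray
    well_id: str = ""
    condition: str = "control"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.ods, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("times and ods must be 1-D and of equal length")
        if len(t) < 3:
            raise ValueError("a growth curve needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("ods must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ods", y)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class InhibitionRatio:
    """Relative growth W = AREA_drug / AREA_control on a common time span."""

    w: float
    area_drug: float
    area_control: float


class GrowthStatus(str, enum.Enum):
    OK = "ok"
    NO_GROWTH = "no_growth"
    CENSORED = "censored"


@dataclass(frozen=True)
class GenerationTime:
    """Average generation time (AvgG) over the exponential phase.

    ``avg_g`` is minutes per doubling; ``inflection_start``/``inflection_end``
    bound the span it was measured over. ``status`` is ``no_growth`` when the
    culture never rose, ``censored`` when no usable exponential span exists.
    """

    avg_g: float = float("nan")
    inflection_start: float = float("nan")
    inflection_end: float = float("nan")
    status: GrowthStatus = GrowthStatus.OK


def _moving_median(y: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(y[lo:hi])
    return out


def _moving_mean(y: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.mean(y[lo:hi])
    return out


def smooth_curve(curve: GrowthCurve, window: int = 5) -> GrowthCurve:
    """Smooth a curve with a centred moving median, then a moving mean.

    The median stage removes isolated read spikes; the mean stage removes the
    residual jitter. Edge windows are truncated, so the end points survive.

    Parameters
    ----------
    curve
        The raw curve.
    window
        Odd number of points per window, ``1 <= window <= len(curve)``.
    """
    if window < 1 or window > len(curve):
        raise ValueError(f"window {window} outside [1, {len(curve)}]")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    y = _moving_mean(_moving_median(curve.ods, window), window)
    return replace(curve, ods=np.maximum(y, 0.0))


def auc(curve: GrowthCurve, baseline: float | None = None) -> float:
    """Trapezoidal area (OD·min) above a baseline offset.

    ``baseline`` defaults to the first OD reading, removing the inoculum /
    blank contribution; readings below the baseline clip to zero.
    """
    if baseline is None:
        baseline = float(curve.ods[0])
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    y = np.maximum(curve.ods - baseline, 0.0)
    return float(np.trapezoid(y, curve.times))


def _common_span(a: GrowthCurve, b: GrowthCurve) -> tuple[float, float]:
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    return float(lo), float(hi)


def _restrict(curve: GrowthCurve, lo: float, hi: float) -> GrowthCurve:
    """Clip a curve to [lo, hi], interpolating the end points."""
    t, y = curve.times, curve.ods
    inner = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inner], [hi]))
    yy = np.interp(tt, t, y)
    return replace(curve, times=tt, ods=yy)


def inhibition_ratio(
    drug_curve: GrowthCurve, control_curve: GrowthCurve
) -> InhibitionRatio:
    """W = AUC(drug) / AUC(control), integrated over the common time span.

    Each curve keeps its own baseline (its first reading over the full span).
    The two curves must overlap over at least 90% of the control's span.

    Raises
    ------
    DegenerateControlError
        If the control area is at or below ``1e-6`` OD·min.
    ValueError
        If the overlap covers less than 90% of the control span.
    """
    lo, hi = _common_span(drug_curve, control_curve)
    ctrl_span = control_curve.times[-1] - control_curve.times[0]
    if hi - lo < 0.9 * ctrl_span:
        raise ValueError("curves overlap over <90% of the control span")
    base_d = float(drug_curve.ods[0])
    base_c = float(control_curve.ods[0])
    area_d = auc(_restrict(drug_curve, lo, hi), base_d)
    area_c = auc(_restrict(control_curve, lo, hi), base_c)
    if area_c <= DEGENERATE_AREA_FLOOR:
        raise DegenerateControlError(
            f"control area {area_c:g} OD·min is degenerate"
        )
    return InhibitionRatio(w=area_d / area_c, area_drug=area_d, area_control=area_c)


def avg_generation_time(curve: GrowthCurve) -> GenerationTime:
    """Average generation time from the exponential span of the log2 curve.

    Works on ``y = log2(max(od, floor))`` of an already-smoothed curve. The
    span is anchored at the global maximum of the first finite difference of
    ``y`` (maximal doubling rate, earliest on ties) and extends on each side
    to the nearest zero-crossing of the second finite difference (the
    lag→log and log→stationary inflections). Where a side has no crossing —
    the log-OD of a lag-free culture is concave throughout — the span extends
    to the furthest point whose slope still exceeds 90% of the maximum, so
    the secant stays inside the near-linear part of the log phase.

    ``avg_g = Δtime / Δlog2(od)`` over that span: minutes per doubling.
    """
    t, od = curve.times, curve.ods
    if od.max() - od[0] < NO_GROWTH_RISE:
        return GenerationTime(status=GrowthStatus.NO_GROWTH)
    y = np.log2(np.maximum(od, LOG_OD_FLOOR))
    d1 = np.diff(y) / np.diff(t)  # slope on [i, i+1]
    i_max = int(np.argmax(d1))
    if d1[i_max] <= 0:
        return GenerationTime(status=GrowthStatus.CENSORED)
    d2 = np.diff(d1)  # curvature between consecutive intervals

    # Left bound: last +→− sign change of d2 at or before the max-slope
    # interval; fallback to the 90%-of-max-slope shoulder.
    start = None
    for j in range(i_max - 1, -1, -1):
        if d2[j] >= 0:
            start = j + 1
            break
    if start is None:
        start = i_max
        while start > 0 and d1[start - 1] >= 0.9 * d1[i_max]:
            start -= 1
    # Right bound, mirrored.
    end = None
    for j in range(i_max, len(d2)):
        if d2[j] >= 0 and j > i_max:
            end = j + 1
            break
    if end is None:
        end = i_max + 1
        while end < len(d1) and d1[end] >= 0.9 * d1[i_max]:
            end += 1
    if end <= start or y[end] - y[start] <= 0:
        return GenerationTime(status=GrowthStatus.CENSORED)
    avg_g = float((t[end] - t[start]) / (y[end] - y[start]))
    return GenerationTime(
        avg_g=avg_g,
        inflection_start=float(t[start]),
        inflection_end=float(t[end]),
        status=GrowthStatus.OK,
    )


def relative_fitness(
    mut_drug: GenerationTime,
    mut_ctrl: GenerationTime,
    wt_drug: GenerationTime,
    wt_ctrl: GenerationTime,
) -> tuple[float, bool]:
    """Drug–gene interaction fitness of a mutant, normalised to wild type.

    ``fitness = (wt_drug / mut_drug) / (wt_ctrl / mut_ctrl)`` on the AvgG
    scale: 1.0 means the drug slows the mutant exactly as much as wild type
    (no interaction); values below 1 mean mutant hypersensitivity. Dividing
    by the no-drug ratio removes any constitutive haploinsufficiency defect.

    Returns ``(fitness, warned)``; a ``no_growth`` input propagates as
    fitness 0 with ``warned=True``.
    """
    gts = (mut_drug, mut_ctrl, wt_drug, wt_ctrl)
    if any(g.status == GrowthStatus.NO_GROWTH for g in gts):
        return 0.0, True
    if any(g.status != GrowthStatus.OK for g in gts):
        raise ValueError("all four generation times must have status ok")
    fitness = (wt_drug.avg_g / mut_drug.avg_g) / (wt_ctrl.avg_g / mut_ctrl.avg_g)
    return float(fitness), False
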