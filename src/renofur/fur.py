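"""Fractional uptake rate (FUR) via Patlak-Rutland graphical analysis.

The FUR clearance index is

    FUR = P(0) * (k_l + k_r) / [ID]        (%ID/min after x100)

where P(0) is the blood-pool count rate back-extrapolated to injection time
with a mono-exponential fit of the heart TAC, k_l and k_r are the slopes of
the linear-uptake (LU) segments of the per-kidney Patlak-Rutland plots

    y = R(t) / P(t)   vs   x = ∫_0^t P dτ / P(t),

and [ID] is the injected-dose count rate.  For an irreversibly trapped
tracer the early plot is linear with slope equal to the uptake constant
normalized by the blood ROI's visibility; that visibility cancels between
P(0) and the slopes, so FUR is calibration-free.

The LU segment must end before tracer outflow from the kidney (before the
renogram's time-to-peak) or the pure-uptake assumption breaks; both a fixed
default segment and an automatic search are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import FitError, ParameterError
from .phantom import FrameStack, ROISet
from .tac import (
    TAC,
    Renogram,
    background_correct,
    estimate_injected_rate,
    extract_tacs,
    to_renogram,
)

__all__ = [
    "BloodFit",
    "PatlakSeries",
    "RenogramMetrics",
    "FURResult",
    "fit_blood_monoexp",
    "patlak_rutland",
    "fit_lu_slope",
    "compute_fur",
    "renogram_metrics",
    "analyze_mouse",
]


@dataclass
class BloodFit:
    """Mono-exponential fit of the blood-pool TAC.

    ``p0_cps`` is the back-extrapolated rate at t = 0, ``lambda_per_min``
    the clearance constant of the fit (negative slope of ln rate vs t).
    """

    p0_cps: float
    lambda_per_min: float
    window_min: tuple[float, float]
    r_squared: float
    n_points: int
    n_excluded: int
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class PatlakSeries:
    """Patlak-Rutland coordinates and (after fitting) the LU-segment slope."""

    roi_name: str
    times_min: np.ndarray
    x_min: np.ndarray
    y: np.ndarray
    n_dropped: int = 0
    segment_min: tuple[float, float] | None = None
    slope_per_min: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    n_segment: int = 0
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class RenogramMetrics:
    """Shape descriptors of a kidney renogram."""

    peak_pct_ia: float
    time_to_peak_min: float
    decline_pct_ia: float  # peak %IA minus %IA at the frame nearest 10 min


@dataclass
class FURResult:
    """FUR with its components, renogram metrics and QC provenance."""

    fur_pct_id_min: float
    p0_cps: float
    lambda_per_min: float
    k_left_per_min: float
    k_right_per_min: float
    injected_rate_cps: float
    metrics: Mapping[str, RenogramMetrics] = field(default_factory=dict)
    qc_flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2 of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_blood_monoexp(
    blood: TAC, window_min: tuple[float, float] = (1.0, 12.0)
) -> BloodFit:
    """Log-linear least squares on ln(rate) vs t over the fit window.

    Non-positive rates inside the window are excluded (and counted); fewer
    than 5 usable points is an error.  A non-positive fitted clearance
    constant is flagged, not fatal.
    """
    t = blood.times_min
    in_win = (t >= window_min[0]) & (t <= window_min[1])
    usable = in_win & (blood.rate_cps > 0)
    n_excluded = int(in_win.sum() - usable.sum())
    if usable.sum() < 5:
        raise FitError(
            f"blood fit needs >=5 positive-rate frames in window {window_min}, "
            f"got {int(usable.sum())}"
        )
    slope, intercept, r2 = _ols(t[usable], np.log(blood.rate_cps[usable]))
    flags = []
    if -slope <= 0:
        flags.append("blood_lambda_nonpositive")
    return BloodFit(
        p0_cps=float(np.exp(intercept)),
        lambda_per_min=-slope,
        window_min=tuple(window_min),
        r_squared=r2,
        n_points=int(usable.sum()),
        n_excluded=n_excluded,
        qc_flags=flags,
    )


def patlak_rutland(kidney_corrected: TAC, blood: TAC) -> PatlakSeries:
    """Patlak-Rutland coordinates from a corrected kidney TAC and blood TAC.

    The cumulative blood integral uses the trapezoid rule on frame
    midpoints with the curve pinned to zero at t = 0 (no tracer in blood at
    injection).  Frames with non-positive blood rate are dropped and
    counted.
    """
    if kidney_corrected.times_min.shape != blood.times_min.shape or not np.allclose(
        kidney_corrected.times_min, blood.times_min
    ):
        raise ParameterError("kidney and blood TACs are on different time grids")
    t = np.concatenate(([0.0], blood.times_min))
    p = np.concatenate(([0.0], blood.rate_cps))
    cum = np.concatenate(([0.0], np.cumsum(np.diff(t) * (p[1:] + p[:-1]) / 2.0)))[1:]
    keep = blood.rate_cps > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise FitError("all frames dropped: blood rate never positive")
    return PatlakSeries(
        roi_name=kidney_corrected.roi_name,
        times_min=blood.times_min[keep],
        x_min=cum[keep] / blood.rate_cps[keep],
        y=kidney_corrected.rate_cps[keep] / blood.rate_cps[keep],
        n_dropped=n_dropped,
    )


DEFAULT_LU_SEGMENT = (0.5, 2.5)


def fit_lu_slope(
    series: PatlakSeries,
    segment: tuple[float, float] | str = DEFAULT_LU_SEGMENT,
    time_to_peak_min: float | None = None,
    r2_min: float = 0.98,
) -> PatlakSeries:
    """Fit the linear-uptake slope over a time segment of the Patlak plot.

    ``segment='auto'`` searches for the longest window starting at 0.5 min
    and ending at least 2 frames before the kidney renogram's time-to-peak
    (required, via ``time_to_peak_min``) whose fit reaches ``r2_min``; if
    none qualifies the default segment is used and a QC flag recorded.
    """
    if isinstance(segment, str):
        if segment != "auto":
            raise ParameterError("segment must be a (start, end) pair or 'auto'")
        return _fit_lu_auto(series, time_to_peak_min, r2_min)
    lo, hi = segment
    sel = (series.times_min >= lo) & (series.times_min <= hi)
    if sel.sum() < 4:
        raise FitError(f"LU segment {segment} covers {int(sel.sum())} points (<4)")
    slope, intercept, r2 = _ols(series.x_min[sel], series.y[sel])
    flags = list(series.qc_flags)
    if r2 < r2_min:
        flags.append(f"lu_r2_below_{r2_min}")
    return replace(
        series,
        segment_min=(float(lo), float(hi)),
        slope_per_min=slope,
        intercept=intercept,
        r_squared=r2,
        n_segment=int(sel.sum()),
        qc_flags=flags,
    )


def _fit_lu_auto(
    series: PatlakSeries, time_to_peak_min: float | None, r2_min: float
) -> PatlakSeries:
    if time_to_peak_min is None:
        raise ParameterError("segment='auto' requires time_to_peak_min")
    start = 0.5
    t = series.times_min
    if len(t) > 1:
        dt = float(np.median(np.diff(t)))
    else:
        dt = 0.0
    latest_end = time_to_peak_min - 2 * dt
    candidates = t[(t >= start) & (t <= latest_end)]
    # longest admissible window first
    for end in candidates[::-1]:
        sel = (t >= start) & (t <= end)
        if sel.sum() < 4:
            continue
        slope, intercept, r2 = _ols(series.x_min[sel], series.y[sel])
        if r2 >= r2_min:
            return replace(
                series,
                segment_min=(start, float(end)),
                slope_per_min=slope,
                intercept=intercept,
                r_squared=r2,
                n_segment=int(sel.sum()),
            )
    fitted = fit_lu_slope(series, DEFAULT_LU_SEGMENT, r2_min=r2_min)
    fitted.qc_flags.append("lu_auto_fallback_default_segment")
    return fitted


def compute_fur(
    blood: BloodFit,
    left: PatlakSeries,
    right: PatlakSeries,
    injected_rate_cps: float,
) -> FURResult:
    """FUR = 100 * P(0) * (k_l + k_r) / [ID], in %ID/min."""
    if not (injected_rate_cps > 0):
        raise ParameterError("injected rate must be > 0")
    for s in (left, right):
        if s.slope_per_min is None:
            raise ParameterError(f"Patlak series {s.roi_name!r} has no fitted slope")
    fur = (
        100.0
        * blood.p0_cps
        * (left.slope_per_min + right.slope_per_min)
        / injected_rate_cps
    )
    flags = list(blood.qc_flags) + list(left.qc_flags) + list(right.qc_flags)
    return FURResult(
        fur_pct_id_min=fur,
        p0_cps=blood.p0_cps,
        lambda_per_min=blood.lambda_per_min,
        k_left_per_min=left.slope_per_min,
        k_right_per_min=right.slope_per_min,
        injected_rate_cps=float(injected_rate_cps),
        qc_flags=flags,
    )


def renogram_metrics(renogram: Renogram, excretion_time_min: float = 10.0) -> RenogramMetrics:
    """Peak %IA, time-to-peak and the peak-to-10-min decline.

    Ties at the maximum break to the earliest frame; the 10-min value uses
    the frame whose midpoint is nearest 10 min (no interpolation).  A
    monotonically rising renogram yields a negative decline, returned as
    computed.
    """
    i_peak = int(np.argmax(renogram.pct_ia))
    i_ref = int(np.argmin(np.abs(renogram.times_min - excretion_time_min)))
    peak = float(renogram.pct_ia[i_peak])
    return RenogramMetrics(
        peak_pct_ia=peak,
        time_to_peak_min=float(renogram.times_min[i_peak]),
        decline_pct_ia=peak - float(renogram.pct_ia[i_ref]),
    )


def analyze_mouse(frames: FrameStack, rois: ROISet, config=None) -> FURResult:
    """Full per-acquisition pipeline: TACs -> corrections -> Patlak -> FUR.

    Deterministic given its inputs.  ``config`` is an
    :class:`~renofur.config.AnalysisConfig` (defaults used when ``None``).
    Stage provenance (windows, segments, QC) is stored on the result.
    """
    from .config import AnalysisConfig  # local import to avoid cycle

    cfg = config or AnalysisConfig()
    stage = "extract_tacs"
    try:
        tacs = extract_tacs(frames, rois)
        stage = "background_correct"
        corr = {
            side: background_correct(tacs[f"kidney_{side}"], tacs[f"bg_{side}"])
            for side in ("left", "right")
        }
        n_negative = {
            side: int((corr[side].rate_cps < 0).sum()) for side in ("left", "right")
        }
        stage = "estimate_injected_rate"
        inj = estimate_injected_rate(tacs, window_s=cfg.id_window_s, mode=cfg.id_mode)
        stage = "fit_blood_monoexp"
        blood = fit_blood_monoexp(tacs["heart"], window_min=cfg.blood_window_min)
        stage = "patlak_rutland"
        series = {}
        metrics = {}
        for side in ("left", "right"):
            reno = to_renogram(corr[side], inj.rate_cps)
            metrics[side] = renogram_metrics(reno)
            ps = patlak_rutland(corr[side], tacs["heart"])
            series[side] = fit_lu_slope(
                ps,
                segment=cfg.lu_segment,
                time_to_peak_min=metrics[side].time_to_peak_min,
                r2_min=cfg.lu_r2_min,
            )
        stage = "compute_fur"
        result = compute_fur(blood, series["left"], series["right"], inj.rate_cps)
    except Exception as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc

    result.metrics = metrics
    if inj.qc_warning:
        result.qc_flags.append("injection_site_above_10pct")
    for side in ("left", "right"):
        if n_negative[side]:
            result.qc_flags.append(f"negative_corrected_rates_{side}:{n_negative[side]}")
    result.provenance = {
        "blood_window_min": cfg.blood_window_min,
        "id_window_s": cfg.id_window_s,
        "id_mode": cfg.id_mode,
        "lu_segment": {s: series[s].segment_min for s in series},
        "lu_r2": {s: series[s].r_squared for s in series},
        "injection_site_frac": inj.injection_site_frac,
        "n_negative_corrected": n_negative,
    }
    return result
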