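"""ROI time-activity curves (TACs) and %IA renograms.

A TAC is the ROI count *rate* (counts/s) at every frame midpoint — rates,
never raw counts, so the frame duration is transparent.  Renograms express a
TAC as percent of injected activity (%IA), normalized by an injected-dose
count-rate denominator estimated from the early whole-body curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ExtractionError, ParameterError
from .phantom import FrameStack, ROISet

__all__ = [
    "TAC",
    "Renogram",
    "InjectedRateEstimate",
    "extract_tacs",
    "background_correct",
    "estimate_injected_rate",
    "to_renogram",
]


@dataclass
class TAC:
    """Per-ROI count-rate series: times (min, frame midpoints) and counts/s."""

    roi_name: str
    times_min: np.ndarray
    rate_cps: np.ndarray
    area_px: int

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.rate_cps = np.asarray(self.rate_cps, dtype=float)
        if self.times_min.shape != self.rate_cps.shape:
            raise ParameterError("times and rates must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.rate_cps)):
            raise ParameterError("rates must be finite")


@dataclass
class Renogram:
    """A TAC normalized to percent of injected activity (%IA)."""

    roi_name: str
    times_min: np.ndarray
    pct_ia: np.ndarray
    injected_rate_cps: float


@dataclass
class InjectedRateEstimate:
    """Injected-dose count rate with injection-site QC.

    ``injection_site_frac`` is the injection-site share of the whole-body
    rate over the estimation window; above 10 % a QC warning is raised.
    """

    rate_cps: float
    window_s: tuple[float, float]
    n_frames: int
    injection_site_frac: float | None
    qc_warning: bool


def extract_tacs(frames: FrameStack, rois: ROISet) -> dict[str, TAC]:
    """Sum counts over every ROI per frame and convert to counts/s."""
    if frames.counts.shape[1:] != rois.labels.shape:
        raise ExtractionError(
            f"label map {rois.labels.shape} does not match frame grid "
            f"{frames.counts.shape[1:]}"
        )
    times = frames.schedule.midpoints_min
    dt = frames.schedule.frame_duration_s
    flat = frames.counts.reshape(frames.counts.shape[0], -1)
    tacs: dict[str, TAC] = {}
    for name in rois.roi_names:
        mask = rois.mask(name).ravel()
        area = int(mask.sum())
        if area == 0:
            raise ExtractionError(f"empty ROI: {name}")
        rate = flat[:, mask].sum(axis=1) / dt
        tacs[name] = TAC(roi_name=name, times_min=times, rate_cps=rate, area_px=area)
    return tacs


def background_correct(kidney: TAC, background: TAC) -> TAC:
    """Area-ratio background subtraction (standard renography practice).

    corrected = kidney - background * (kidney_area / background_area), i.e.
    the per-pixel background rate scaled to the kidney's area.  Negative
    corrected rates (possible under noise) are retained for unbiased
    downstream fitting; callers may count them for QC.
    """
    if kidney.area_px <= 0 or background.area_px <= 0:
        raise ParameterError("ROI areas must be > 0")
    if kidney.times_min.shape != background.times_min.shape or not np.allclose(
        kidney.times_min, background.times_min
    ):
        raise ParameterError("kidney and background TACs are on different time grids")
    corrected = kidney.rate_cps - background.rate_cps * (
        kidney.area_px / background.area_px
    )
    return replace(kidney, roi_name=f"{kidney.roi_name}_corrected", rate_cps=corrected)


def estimate_injected_rate(
    tacs: dict[str, TAC],
    window_s: tuple[float, float] = (10.0, 60.0),
    mode: str = "wb",
) -> InjectedRateEstimate:
    """Injected-dose count rate: early-window mean of the whole-body TAC.

    The default window [10 s, 60 s] skips the bolus arrival and averages the
    frames whose midpoints fall inside it.  ``mode='wb_minus_injection'``
    subtracts the injection-site TAC from the whole-body TAC first; in
    either mode the injection-site share is reported for QC.
    """
    if mode not in ("wb", "wb_minus_injection"):
        raise ParameterError("mode must be 'wb' or 'wb_minus_injection'")
    if "whole_body" not in tacs:
        raise ExtractionError("whole_body TAC required to estimate injected rate")
    wb = tacs["whole_body"]
    t_s = wb.times_min * 60.0
    sel = (t_s >= window_s[0]) & (t_s <= window_s[1])
    if not sel.any():
        raise ExtractionError(f"injected-rate window {window_s} contains no frames")
    rate_wb = float(wb.rate_cps[sel].mean())

    inj_frac = None
    qc = False
    if "injection_site" in tacs:
        inj = float(tacs["injection_site"].rate_cps[sel].mean())
        inj_frac = inj / rate_wb if rate_wb > 0 else np.inf
        if inj_frac > 0.10:
            qc = True
            warnings.warn(
                f"injection-site rate is {100 * inj_frac:.1f} % of whole body "
                "in the injected-dose window (paravenous injection?)",
                stacklevel=2,
            )
    rate = rate_wb
    if mode == "wb_minus_injection":
        if "injection_site" not in tacs:
            raise ExtractionError("mode 'wb_minus_injection' needs an injection_site TAC")
        rate = rate_wb - float(tacs["injection_site"].rate_cps[sel].mean())
    return InjectedRateEstimate(
        rate_cps=rate,
        window_s=tuple(window_s),
        n_frames=int(sel.sum()),
        injection_site_frac=inj_frac,
        qc_warning=qc,
    )


def to_renogram(tac: TAC, injected_rate_cps: float) -> Renogram:
    """Normalize a TAC to percent of injected activity."""
    if not (injected_rate_cps > 0 and np.isfinite(injected_rate_cps)):
        raise ParameterError("injected rate must be positive and finite")
    return Renogram(
        roi_name=tac.roi_name,
        times_min=tac.times_min,
        pct_ia=100.0 * tac.rate_cps / injected_rate_cps,
        injected_rate_cps=float(injected_rate_cps),
    )
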