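"""Compartmental tracer-kinetics forward model for dynamic renal scintigraphy.

The model describes a renally extracted tracer (e.g. [99mTc]-MAG3) after an
intravenous bolus in a small animal:

* A fraction ``residual_frac`` of the dose stays at the injection site.
* The circulating fraction mixes into plasma as a linear ramp over ``t_mix``
  seconds; from then on the plasma fraction-of-injected-dose follows a single
  exponential ``p(t) = (1 - r) * exp(-lambda_total * t)`` whose back
  extrapolation to t = 0 is exactly ``1 - r``.  ``lambda_total`` is the sum of
  the two renal uptake constants and a non-renal clearance constant.
* Each kidney takes up plasma at rate ``kappa_k * p(t)`` and releases it into
  the bladder exactly one plug-flow transit time ``T`` later, so the kidney
  content is ``R_k(t) = kappa_k * (C(t) - C(t - T))`` with
  ``C(t) = \\int_0^t p``.  This produces the classic rise-peak-fall renogram
  with an analytically known peak.
* A non-renal compartment accumulates ``kappa_other * C(t)``; the bladder
  accumulates the summed kidney outflow.

All compartment series are fractions of injected dose and satisfy exact mass
balance: injection site + plasma + kidneys + bladder + other = 1 at every
instant.  No physical isotope decay is simulated (≈2 % over 12 min for
Tc-99m; folded into the camera sensitivity).

Times are handled in minutes internally; closed forms are exposed so tests
can check the sampled series against independent numerical integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "FrameSchedule",
    "KineticParams",
    "OrganActivitySeries",
    "plasma_fraction",
    "cumulative_plasma",
    "kidney_fraction",
    "simulate_kinetics",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Uniform dynamic-acquisition frame schedule.

    Defaults to the standard small-animal renography protocol of 144 frames
    of 5 s (12 min total).  Frame *i* is timestamped at its midpoint
    ``(i + 0.5) * frame_duration_s``.
    """

    n_frames: int = 144
    frame_duration_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if not (self.frame_duration_s > 0 and math.isfinite(self.frame_duration_s)):
            raise ParameterError("frame_duration_s must be positive and finite")

    @property
    def total_s(self) -> float:
        return self.n_frames * self.frame_duration_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration_s

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.midpoints_s / 60.0


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth tracer kinetics and camera calibration for one animal.

    Parameters
    ----------
    injected_activity_mbq:
        Administered activity (MBq).  Metadata only: count rates are set by
        ``sensitivity_cps``, which already refers to the full injected dose.
    residual_frac:
        Fraction of the dose remaining at the injection site, in [0, 1).
    t_mix_s:
        Bolus mixing time (s); plasma ramps linearly from zero over this
        interval.
    kappa_left, kappa_right:
        Per-kidney plasma uptake constants (min^-1, >= 0).
    kappa_other:
        Non-renal plasma clearance constant (min^-1, >= 0).
    transit_min:
        Intra-renal plug-flow transit time (min, > 0).
    beta_blood:
        Per-pixel soft-tissue blood fraction.  ``None`` (default) derives the
        value at render time so that all circulating activity is in view and
        whole-field counts are conserved.
    v_heart:
        Fraction of the plasma pool visible in the heart ROI, in (0, 1).
    sensitivity_cps:
        Whole-field count rate when 100 % of the dose is in view (counts/s).
    """

    injected_activity_mbq: float = 25.0
    residual_frac: float = 0.05
    t_mix_s: float = 15.0
    kappa_left: float = 0.058
    kappa_right: float = 0.058
    kappa_other: float = 0.010
    transit_min: float = 3.0
    beta_blood: float | None = None
    v_heart: float = 0.10
    sensitivity_cps: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("kappa_left", "kappa_right", "kappa_other"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0 <= self.residual_frac < 1):
            raise ParameterError("residual_frac must be in [0, 1)")
        if not (self.t_mix_s >= 0 and math.isfinite(self.t_mix_s)):
            raise ParameterError("t_mix_s must be >= 0")
        if not (self.transit_min > 0 and math.isfinite(self.transit_min)):
            raise ParameterError("transit_min must be > 0")
        if not (0 < self.v_heart < 1):
            raise ParameterError("v_heart must be in (0, 1)")
        if self.beta_blood is not None and not (0 <= self.beta_blood < 1):
            raise ParameterError("beta_blood must be in [0, 1) or None")
        if not (self.sensitivity_cps > 0):
            raise ParameterError("sensitivity_cps must be > 0")
        if not (self.injected_activity_mbq > 0):
            raise ParameterError("injected_activity_mbq must be > 0")
        if self.lambda_total <= 0:
            raise ParameterError("kappa_left + kappa_right + kappa_other must be > 0")

    @property
    def lambda_total(self) -> float:
        """Total plasma clearance constant (min^-1)."""
        return self.kappa_left + self.kappa_right + self.kappa_other

    @property
    def t_mix_min(self) -> float:
        return self.t_mix_s / 60.0

    @property
    def fur_true(self) -> float:
        """Ground-truth fractional uptake rate, %ID/min."""
        return 100.0 * (1.0 - self.residual_frac) * (self.kappa_left + self.kappa_right)

    def with_fur(self, fur: float, split_left: float = 0.5) -> "KineticParams":
        """Return a copy whose renal constants realize the given true FUR.

        ``split_left`` is the left kidney's share of the summed renal uptake.
        """
        if fur <= 0:
            raise ParameterError("fur must be > 0")
        if not (0 < split_left < 1):
            raise ParameterError("split_left must be in (0, 1)")
        total = fur / (100.0 * (1.0 - self.residual_frac))
        return replace(
            self, kappa_left=total * split_left, kappa_right=total * (1.0 - split_left)
        )


def plasma_fraction(t_min: np.ndarray | float, params: KineticParams) -> np.ndarray:
    """Plasma fraction-of-injected-dose p(t); t in minutes."""
    t = np.asarray(t_min, dtype=float)
    p0 = 1.0 - params.residual_frac
    lam = params.lambda_total
    m = params.t_mix_min
    decay = p0 * np.exp(-lam * np.maximum(t, 0.0))
    if m == 0:
        out = np.where(t >= 0, decay, 0.0)
    else:
        ramp = p0 * math.exp(-lam * m) * (t / m)
        out = np.where(t >= m, decay, np.where(t > 0, ramp, 0.0))
    return out


def cumulative_plasma(t_min: np.ndarray | float, params: KineticParams) -> np.ndarray:
    """Closed-form cumulative plasma integral C(t) = ∫_0^t p(τ) dτ (min)."""
    t = np.asarray(t_min, dtype=float)
    p0 = 1.0 - params.residual_frac
    lam = params.lambda_total
    m = params.t_mix_min
    if m == 0:
        c_after = (p0 / lam) * (1.0 - np.exp(-lam * np.maximum(t, 0.0)))
        return np.where(t > 0, c_after, 0.0)
    c_mix = p0 * math.exp(-lam * m) * m / 2.0
    c_ramp = p0 * math.exp(-lam * m) * np.square(np.clip(t, 0.0, m)) / (2.0 * m)
    c_after = c_mix + (p0 / lam) * (
        math.exp(-lam * m) - np.exp(-lam * np.maximum(t, m))
    )
    return np.where(t >= m, c_after, c_ramp)


def kidney_fraction(
    t_min: np.ndarray | float, kappa: float, params: KineticParams
) -> np.ndarray:
    """Kidney content R_k(t) = kappa * (C(t) - C(t - T)) under plug flow."""
    t = np.asarray(t_min, dtype=float)
    T = params.transit_min
    return kappa * (cumulative_plasma(t, params) - cumulative_plasma(t - T, params))


@dataclass
class OrganActivitySeries:
    """Per-compartment fraction-of-injected-dose series on a frame schedule.

    All arrays are aligned with ``schedule.midpoints_min``; every column is a
    dimensionless fraction of the injected dose.  ``injection_site`` is the
    mass-balance residual and therefore includes not-yet-mixed bolus during
    the ramp.
    """

    schedule: FrameSchedule
    params: KineticParams
    times_min: np.ndarray
    plasma: np.ndarray
    kidney_left: np.ndarray
    kidney_right: np.ndarray
    bladder: np.ndarray
    other: np.ndarray
    injection_site: np.ndarray

    compartments: tuple[str, ...] = field(
        default=(
            "plasma",
            "kidney_left",
            "kidney_right",
            "bladder",
            "other",
            "injection_site",
        ),
        repr=False,
    )

    def total(self) -> np.ndarray:
        return (
            self.plasma
            + self.kidney_left
            + self.kidney_right
            + self.bladder
            + self.other
            + self.injection_site
        )

    def mass_balance_error(self) -> float:
        """Maximum absolute deviation of the compartment sum from 1."""
        return float(np.max(np.abs(self.total() - 1.0)))


def simulate_kinetics(
    params: KineticParams, schedule: FrameSchedule | None = None
) -> OrganActivitySeries:
    """Evaluate the closed-form forward model on the schedule's midpoints.

    Returns the six-compartment fraction-of-dose series.  Mass balance is
    exact by construction: the injection-site series is the residual
    ``1 - p - R_l - R_r - B - O``, where the cleared compartments sum to
    ``lambda_total * C(t)``.
    """
    schedule = schedule or FrameSchedule()
    t = schedule.midpoints_min
    p = plasma_fraction(t, params)
    cum = cumulative_plasma(t, params)
    cum_delayed = cumulative_plasma(t - params.transit_min, params)
    r_left = params.kappa_left * (cum - cum_delayed)
    r_right = params.kappa_right * (cum - cum_delayed)
    bladder = (params.kappa_left + params.kappa_right) * cum_delayed
    other = params.kappa_other * cum
    injection = 1.0 - p - params.lambda_total * cum
    return OrganActivitySeries(
        schedule=schedule,
        params=params,
        times_min=t,
        plasma=p,
        kidney_left=r_left,
        kidney_right=r_right,
        bladder=bladder,
        other=other,
        injection_site=injection,
    )
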