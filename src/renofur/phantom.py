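"""Digital planar phantom and gamma-camera frame rendering.

The phantom is a 2D pixel label map mimicking a supine mouse under a planar
collimated detector: a whole-body ellipse containing heart, two kidneys with
peri-renal background annuli, bladder and an injection-site (tail) region.
ROIs coincide exactly with the organ supports — no misregistration is
modelled, so background correction and conservation identities are exact on
noiseless renders.

Rendering maps a compartmental :class:`~renofur.kinetics.OrganActivitySeries`
to expected counts per pixel per frame:

* organ pixels share their compartment's activity uniformly;
* the heart ROI shows a fraction ``v_heart`` of the plasma pool;
* every other body pixel carries a uniform vascular (plus non-renal
  clearance) signal, so kidney and background-annulus pixels see the same
  per-pixel tissue term and area-ratio background subtraction cancels it
  exactly.

With the default (derived) tissue blood coefficient the whole-field expected
count rate equals ``sensitivity_cps`` at every frame: the entire dose is in
view and no physical decay is simulated.  Poisson noise is drawn
independently per pixel per frame from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError, ParameterError
from .kinetics import FrameSchedule, KineticParams, OrganActivitySeries

__all__ = ["ROISet", "PhantomLayout", "FrameStack", "make_phantom", "render_frames"]

# integer labels of the phantom / ROI map; 0 = outside the animal
LABELS = {
    "injection_site": 1,
    "heart": 2,
    "body_tissue": 3,
    "kidney_left": 4,
    "kidney_right": 5,
    "bg_left": 6,
    "bg_right": 7,
    "bladder": 8,
}

#: ROI names exported as time-activity curves ("whole_body" = all labels > 0)
ROI_NAMES = (
    "whole_body",
    "kidney_left",
    "kidney_right",
    "bg_left",
    "bg_right",
    "bladder",
    "heart",
    "injection_site",
)


@dataclass
class ROISet:
    """Integer ROI label map with a name legend.

    ``whole_body`` is the union of all labelled pixels; every other ROI is a
    single label.  Kidney ROIs are disjoint from their background annuli by
    construction.
    """

    labels: np.ndarray
    legend: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    @property
    def roi_names(self) -> tuple[str, ...]:
        return ROI_NAMES

    def mask(self, name: str) -> np.ndarray:
        if name == "whole_body":
            return self.labels > 0
        if name not in self.legend:
            raise KeyError(f"unknown ROI {name!r}")
        return self.labels == self.legend[name]

    def area(self, name: str) -> int:
        return int(self.mask(name).sum())


@dataclass
class PhantomLayout:
    """Phantom geometry: grid size plus its ROI label map."""

    grid_size: int
    rois: ROISet

    @property
    def areas(self) -> dict[str, int]:
        return {name: self.rois.area(name) for name in self.rois.roi_names}


def _ellipse(shape: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape, 0:shape]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_phantom(grid_size: int = 128) -> PhantomLayout:
    """Build the default mouse phantom on a square grid (>= 64 px).

    Geometry is scaled with the grid.  Background annuli are sized so each
    sees roughly 2 % of the circulating blood pool under the default derived
    tissue blood coefficient.
    """
    n = int(grid_size)
    if n < 64:
        raise LayoutError(f"grid {n}x{n} too small: organs do not fit (need >= 64)")

    body = _ellipse(n, 0.50 * n, 0.50 * n, 0.46 * n, 0.30 * n)
    heart = _ellipse(n, 0.22 * n, 0.50 * n, 0.045 * n, 0.055 * n)
    kid_l = _ellipse(n, 0.47 * n, 0.36 * n, 0.070 * n, 0.055 * n)
    kid_r = _ellipse(n, 0.47 * n, 0.64 * n, 0.070 * n, 0.055 * n)
    # peri-renal annuli: same centres, radii x1.2 .. x1.5, kidney excluded
    bg_l = _ellipse(n, 0.47 * n, 0.36 * n, 0.105 * n, 0.0825 * n) & ~_ellipse(
        n, 0.47 * n, 0.36 * n, 0.084 * n, 0.066 * n
    )
    bg_r = _ellipse(n, 0.47 * n, 0.64 * n, 0.105 * n, 0.0825 * n) & ~_ellipse(
        n, 0.47 * n, 0.64 * n, 0.084 * n, 0.066 * n
    )
    bladder = _ellipse(n, 0.78 * n, 0.50 * n, 0.050 * n, 0.060 * n)
    injection = _ellipse(n, 0.91 * n, 0.50 * n, 0.035 * n, 0.030 * n)

    organs = {
        "injection_site": injection,
        "heart": heart,
        "kidney_left": kid_l,
        "kidney_right": kid_r,
        "bg_left": bg_l,
        "bg_right": bg_r,
        "bladder": bladder,
    }
    for name, m in organs.items():
        if not m.any():
            raise LayoutError(f"organ {name!r} empty on {n}x{n} grid")
        if (m & ~body).any():
            raise LayoutError(f"organ {name!r} does not fit inside the body outline")
    names = list(organs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (organs[a] & organs[b]).any():
                raise LayoutError(f"organs {a!r} and {b!r} overlap")

    labels = np.zeros((n, n), dtype=np.int16)
    labels[body] = LABELS["body_tissue"]
    for name, m in organs.items():
        labels[m] = LABELS[name]
    return PhantomLayout(grid_size=n, rois=ROISet(labels=labels))


@dataclass
class FrameStack:
    """Dynamic planar acquisition: counts indexed (frame, y, x).

    ``noise='poisson'`` stores integer Poisson-drawn counts; ``'none'``
    stores real-valued expected counts.
    """

    counts: np.ndarray
    schedule: FrameSchedule
    noise: str = "poisson"
    seed: int | None = None
    params: KineticParams | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ParameterError("counts must be a (frame, y, x) array")
        if self.counts.shape[0] != self.schedule.n_frames:
            raise ParameterError("counts/schedule frame count mismatch")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")


def tissue_blood_coefficient(params: KineticParams, phantom: PhantomLayout) -> float:
    """Per-pixel blood fraction for non-heart body pixels.

    Defaults (``beta_blood is None``) to ``(1 - v_heart) / n_pixels`` over
    the body excluding the heart, which places all circulating plasma in
    view and makes whole-field counts exactly conserved.
    """
    n_tissue = phantom.rois.area("whole_body") - phantom.rois.area("heart")
    if params.beta_blood is not None:
        if params.beta_blood * n_tissue + params.v_heart > 1.0 + 1e-12:
            raise ParameterError(
                "beta_blood allocates more than the available plasma pool"
            )
        return params.beta_blood
    return (1.0 - params.v_heart) / n_tissue


def render_frames(
    series: OrganActivitySeries,
    phantom: PhantomLayout,
    params: KineticParams | None = None,
    seed: int | None = None,
    noise: str = "poisson",
) -> FrameStack:
    """Render expected or Poisson-noised counts for every frame.

    Expected counts for organ *g* in frame *i* are
    ``sensitivity_cps * fraction_g(t_i) * frame_duration`` spread uniformly
    over the organ's pixels; body pixels outside the heart additionally
    carry the per-pixel vascular term and the uniformly distributed
    non-renal ("other") compartment.
    """
    if noise not in ("poisson", "none"):
        raise ParameterError("noise must be 'poisson' or 'none'")
    params = params or series.params
    schedule = series.schedule
    rois = phantom.rois

    masks = {name: rois.mask(name) for name in
             ("kidney_left", "kidney_right", "bladder", "injection_site", "heart")}
    body = rois.mask("whole_body")
    tissue = body & ~masks["heart"]  # includes kidneys, annuli, bladder, tail
    n_tissue = int(tissue.sum())
    beta = tissue_blood_coefficient(params, phantom)

    # per-pixel fraction-of-dose coefficient maps (float64, grid-shaped)
    coeff_maps: list[tuple[np.ndarray, np.ndarray]] = []  # (map, time series)
    coeff_maps.append((tissue * beta, series.plasma))
    coeff_maps.append((tissue / n_tissue, series.other))
    coeff_maps.append(
        (masks["heart"] * (params.v_heart / rois.area("heart")), series.plasma)
    )
    for name, comp in (
        ("kidney_left", series.kidney_left),
        ("kidney_right", series.kidney_right),
        ("bladder", series.bladder),
        ("injection_site", series.injection_site),
    ):
        coeff_maps.append((masks[name] / rois.area(name), comp))

    scale = params.sensitivity_cps * schedule.frame_duration_s
    expected = np.zeros((schedule.n_frames,) + body.shape, dtype=np.float64)
    for cmap, ts in coeff_maps:
        expected += ts[:, None, None] * cmap[None, :, :]
    expected *= scale

    if noise == "none":
        return FrameStack(expected, schedule, noise="none", seed=seed, params=params)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(np.int64)
    return FrameStack(counts, schedule, noise="poisson", seed=seed, params=params)
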