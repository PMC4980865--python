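# renofur

Quantitative dynamic renal scintigraphy, end to end: a ground-truthed
tracer-kinetics / gamma-camera simulator and the renography analysis it
validates — ROI time-activity curves, %IA renograms, Patlak-Rutland
graphical analysis, the **fractional uptake rate (FUR)** clearance
statistic, and the longitudinal group statistics used in small-animal
nephrotoxicity and nephroprotection studies.

## Who this is for

Preclinical nuclear-medicine groups monitoring renal function with a
renally extracted tracer such as [99mTc]-MAG3 (for example across a
radionuclide-therapy follow-up), and anyone who wants a fully synthetic,
reproducible test bed for renography pipelines: every simulated
acquisition carries its exact ground truth, so each analysis stage can be
verified against a closed form.

## The statistic

A 12-min dynamic planar acquisition (144 frames × 5 s) after a tracer
bolus yields per-ROI count-rate curves. Each kidney curve is
background-corrected with its peri-renal annulus (area-ratio subtraction)
and normalized to the injected-dose count rate [ID] (early whole-body
rate) to give a renogram in percent of injected activity (%IA). Renal
clearance is then summarized as the fractional uptake rate

    FUR = P(0) · (k_l + k_r) / [ID]        (× 100 → %ID/min)

where

* **P(0)** — blood-pool count rate back-extrapolated to injection time by
  a mono-exponential (log-linear) fit of the heart TAC;
* **k_l, k_r** — slopes of the linear-uptake (LU) segment of the
  per-kidney Patlak-Rutland plot, y = R(t)/P(t) against
  x = ∫₀ᵗP dτ / P(t), fitted before tracer outflow breaks the
  pure-uptake assumption.

The heart ROI's visibility cancels between P(0) and the slopes, so FUR is
calibration-free; it estimates 100·(1−r)·(κ_l+κ_r), the percent of the
injected dose cleared into the kidneys per minute.

The simulator generates the matching ground truth: mono-exponential
plasma clearance after a linear bolus-mixing ramp, plug-flow intra-renal
transit (rise–peak–fall renograms), bladder accumulation, an
injection-site residual, a digital mouse phantom with the standard ROI
scheme, and per-pixel Poisson counting noise. Cohort presets emulate a
dose-escalation nephrotoxicity study and an ACE-inhibitor
nephroprotection study with the published arm sizes and group means.

## Worked example

```python
from renofur import (KineticParams, make_phantom, simulate_kinetics,
                     render_frames, analyze_mouse)

params = KineticParams()            # kappa_l = kappa_r = 0.058 /min, r = 0.05
phantom = make_phantom(128)
frames = render_frames(simulate_kinetics(params), phantom, params,
                       seed=7, noise="poisson")
res = analyze_mouse(frames, phantom.rois)
print(f"true FUR {params.fur_true:.2f}  estimated {res.fur_pct_id_min:.2f} %ID/min")
print(f"P0 {res.p0_cps:.1f} cps   k_l {res.k_left_per_min:.3f} /min   "
      f"peak {res.metrics['left'].peak_pct_ia:.1f} %IA "
      f"at {res.metrics['left'].time_to_peak_min:.2f} min")
```

prints (seed 7):

```
true FUR 11.02  estimated 11.27 %ID/min
P0 189.4 cps   k_l 0.582 /min   peak 14.0 %IA at 3.12 min
```

The true FUR is 100·0.95·(0.058+0.058) = 11.02 %ID/min; one noisy
acquisition recovers it within ~2 % (across replicates the estimator's
spread is ~1.3 % CV). P(0) ≈ 190 cps is the heart-ROI
share (10 %) of the circulating dose at a whole-field sensitivity of
2000 cps; the renogram peaks about one transit time (3 min) after
injection. On noise-free renders the same call is exact to <0.1 %.

The same pipeline runs from the shell:

```bash
renofur simulate --scenario nephroprotection --seed 7 --out data/
renofur study --data data/ --out study/      # results.csv, summary.csv, report.txt
renofur show-config
```

## Layout

| module | contents |
| --- | --- |
| `renofur.kinetics` | compartmental forward model, closed forms |
| `renofur.phantom` | digital mouse phantom, ROI label map, frame rendering |
| `renofur.cohort` | study designs, presets, truncated-normal cohort draws |
| `renofur.tac` | TAC extraction, background correction, %IA renograms |
| `renofur.fur` | blood fit, Patlak-Rutland, LU slopes, FUR, renogram metrics |
| `renofur.stats` | Shapiro-Wilk-gated t / Mann-Whitney tests, study summaries |
| `renofur.io` / `renofur.cli` | NIfTI/CSV/YAML formats and the `renofur` CLI |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and numerical conventions.
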