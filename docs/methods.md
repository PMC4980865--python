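# Methods

## Forward model

The simulator describes a renally extracted tracer after an intravenous
bolus with six compartments, all expressed as fractions of the injected
dose (ID): injection-site residual, plasma `p(t)`, left/right kidney
`R_l, R_r`, bladder `B`, and a non-renal clearance pool `O`.

**Plasma.** A fraction `r` (`residual_frac`) of the dose never leaves the
injection site. The circulating fraction mixes over a linear ramp of
duration `t_mix` (default 15 s, i.e. three 5-s frames); from the end of
the ramp plasma follows a single exponential

    p(t) = (1 − r) · exp(−λ t),      λ = κ_l + κ_r + κ_other,

anchored so that its back-extrapolation to t = 0 is exactly `1 − r`.
This anchoring is deliberate: the analysis pipeline's mono-exponential
back-extrapolation of the blood-pool curve is then exact on noise-free
data, which turns P(0) into a testable ground truth rather than an
approximation. The cost is a small bookkeeping asymmetry — the dose
"missing" during the ramp, and its clearance, are charged to the
injection-site series, whose post-mixing plateau therefore sits slightly
above `r` (≈ 0.065 vs 0.05 at defaults). Mass balance (sum of all six
compartments = 1) is exact at every instant and asserted to 1e-9.

**Kidneys.** Uptake is irreversible at rate `κ_k · p(t)`; intra-renal
transport is plug flow with sharp transit time `T` (`transit_min`,
default 3 min): tracer entering at time τ leaves for the bladder at
τ + T. Hence

    R_k(t) = κ_k · [C(t) − C(t − T)],      C(t) = ∫₀ᵗ p,

which yields the classic rise–peak–fall renogram in closed form. For an
ideal (instantaneous) bolus the renogram peaks exactly at t = T; with
the default mixing ramp the peak shifts to T + m·e^{−λT} ≈ T + 10 s,
because the delayed outflow only catches the inflow once t − T clears
the ramp. Tests of the time-to-peak/transit identity therefore use the
ideal-bolus configuration; the ramp case is asserted at its analytic
offset.

No physical isotope decay is simulated (≈ 2 % over 12 min for Tc-99m;
absorbed into the sensitivity constant). Dispersed transit, reuptake and
pelvis pooling are not modelled.

## Phantom and rendering

A 128×128 label map mimics a supine mouse: whole-body ellipse, heart,
two kidneys with peri-renal background annuli, bladder and a tail
injection-site region. ROIs coincide exactly with organ supports — no
misregistration, partial volume, attenuation, scatter or motion — so
two identities hold exactly on noise-free renders and are exploited by
the tests:

* **Conservation.** All activity is in view: whole-field expected counts
  are `sensitivity_cps × frame_duration` at every frame (default
  2000 cps → 10 000 counts per 5-s frame).
* **Cancellation.** Kidney and background-annulus pixels carry the same
  per-pixel vascular + non-renal tissue signal, so area-ratio background
  subtraction recovers `sensitivity_cps · R_k(t)` exactly.

The heart ROI shows a fraction `v_heart` (default 0.10) of the plasma
pool. The remaining plasma is spread uniformly over non-heart body
pixels; with the default derived coefficient
`beta_blood = (1 − v_heart)/n_tissue_pixels` each background annulus
sees ≈ 2 % of the plasma pool. Setting `beta_blood` explicitly is
honored as-is, in which case whole-field conservation holds only if it
equals the derived value (an over-allocation is rejected). Poisson noise
is drawn independently per pixel per frame from a seeded generator;
`noise="none"` returns expectations.

Defaults (`KineticParams`): r = 0.05, t_mix = 15 s, κ_l = κ_r =
0.058 min⁻¹, κ_other = 0.01 min⁻¹, T = 3 min, v_heart = 0.10,
sensitivity = 2000 cps — chosen so the ground-truth FUR,
100·(1−r)·(κ_l+κ_r) ≈ 11.0 %ID/min, sits at the healthy-baseline scale
of murine MAG3 studies, with λ = 0.126 min⁻¹ giving a ~5.5-min plasma
half-time.

## Analysis pipeline

1. **TAC extraction** — per-ROI counts per frame / frame duration;
   curves are rates (counts/s) at frame midpoints `(i + 0.5)·Δt`, never
   raw counts.
2. **Background correction** — `kidney − background·(A_kid/A_bg)`.
   Negative corrected rates under noise are retained (unbiased for the
   fits) but counted and logged.
3. **Injected-dose rate [ID]** — mean whole-body rate over frames whose
   midpoints fall in [10 s, 60 s]; the injection-site share is reported
   and flagged above 10 % (paravenous injection QC). A
   `wb_minus_injection` mode subtracts the injection-site curve.
4. **Blood fit** — least squares of ln(rate) on t over [1, 12] min
   (start ≥ 1 min skips bolus mixing); P(0) = exp(intercept). Exact on
   the simulator's model; non-positive rates are excluded and counted;
   λ ≤ 0 is flagged, not fatal.
5. **Patlak-Rutland** — cumulative ∫P by trapezoid on frame midpoints
   with the blood curve pinned to (0, 0); frames with non-positive blood
   rate are dropped and logged. The LU slope is OLS of y on x over the
   default segment [0.5, 2.5] min, which ends before the default-transit
   renogram peak as the pure-uptake assumption requires; `"auto"`
   searches the longest window from 0.5 min ending ≥ 2 frames before the
   measured time-to-peak with segment R² ≥ 0.98, falling back to the
   default with a QC flag.
6. **FUR** — `100 · P(0) · (k_l + k_r) / [ID]` in %ID/min, computed from
   the background-corrected count-rate TACs (units cancel; the %IA
   normalization is for renogram display). Renogram metrics: peak %IA
   (max over frames, ties → earliest), time-to-peak (midpoint of the
   argmax frame), and the peak-to-10-min decline using the frame nearest
   10 min without interpolation. Since the peak is the global maximum,
   the decline is by construction non-negative.

### Numerical conventions and accuracy

Pinning the blood curve to zero at t = 0 makes the trapezoid exact on
the linear mixing ramp. The one frame whose interpolation straddles the
ramp/exponential kink contributes a single ~0.003 min underestimate of
∫P; past the ramp, trapezoid increments match the analytic integral to
~1e-5 relative. The end-to-end effect at defaults is < 0.1 % on FUR
(measured), and the Patlak slope on noise-free data is accurate to
~4e-4 relative. Because P(0) scales with `v_heart` and the slopes scale
with `1/v_heart`, FUR is invariant (to machine precision on noise-free
data) under changes of heart-ROI visibility, camera sensitivity and
injected activity; these invariances are asserted in the suite.

## Cohort scenarios and statistics

A `StudyDesign` lists arms with n mice, a mean true FUR at each anchor
day and a single between-mouse SD. Draws are independent
truncated-normal (lower bound 1 %ID/min) per mouse per day — no
within-mouse random effect, so consecutive scans of one animal are no
more correlated than scans of two animals; the paired-test mode is
therefore conservative on simulated data. Each drawn FUR is converted to
kinetic parameters by `Σκ = FUR/(100(1−r))`, split between kidneys
50/50 with a small normal asymmetry (SD 0.02, clipped to [0.4, 0.6]).
One integer seed drives a cohort; per-mouse streams are split from it
(`SeedSequence.spawn`), so cohorts are bit-reproducible and mice
independent.

Two presets emulate a radionuclide-therapy study design. Arm means at
the final follow-up day and arm sizes are the published group values
(dose escalation: 11.2/10.1/8.9/6.0 %ID/min at day 65, n = 6/8/7/7,
baseline 11.0, n = 12; nephroprotection: 11.8/9.3/11.9 %ID/min at day
86, n = 7 each, baseline 12.5, n = 12). Between-mouse SDs are
reconstructed from reported SEMs as SD = SEM·√n. Values the source
study reports only qualitatively are fixed stand-ins, stated once and
not tuned: the acute day-9 decline is 70 % of baseline in every treated
arm, interim recovery passes through 90 % of baseline at day 23 and the
midpoint to the final mean at day 44, and the non-therapy arm drifts
linearly from 12.5 to 11.9. Trajectories between anchor days are
piecewise linear.

Group comparisons follow the standard small-cohort scheme: Shapiro-Wilk
on each sample at α = 0.05; both normal → two-sided t test (paired, or
unpaired with Welch correction — no equal-variance assumption); either
non-normal → two-sided Mann-Whitney U, exact null distribution when the
pooled n ≤ 20 without ties, normal approximation with tie correction
otherwise. Summaries report mean ± SEM per (group, day) with raw
p-values flagged at 0.05/0.01; no multiple-testing correction is
applied, matching the emulated study's presentation. Baseline contrasts
default to unpaired against a distinct baseline group (a `paired` switch
covers the within-mouse reading). Zero-variance cells cannot be gated
and are flagged rather than fatal.

## What the simulator does and does not establish

Passing tests show the pipeline recovers the generative model's
parameters under its own assumptions — exact ROI registration, uniform
organ activity, plug-flow transit, pure Poisson noise, mono-exponential
plasma clearance. Real acquisitions add motion, attenuation, scatter,
depth-dependent sensitivity, dispersed transit and ROI-placement
variability, none of which are modelled; absolute accuracy on real data
is not claimed. Split renal function, absolute GFR/ERPF calibration and
dosimetry are out of scope.

Problem sizes used by the shipped studies: single acquisitions are 144
frames × 128×128 pixels; the parameter-recovery study uses 200 Poisson
replicates at each of four FUR levels; scenario-level Monte Carlo uses
500 reseeded cohorts per preset, operating on the drawn true FURs (the
imaging-chain error, ≲0.3 %ID/min at default counts, is an order of
magnitude below the between-mouse SDs of 1.0–2.1 %ID/min, so rendering
every cohort would change the group statistics negligibly while
multiplying the cost by ~10⁴).

## Known limitations

* The significance-pattern probability of the dose-escalation preset is
  intrinsically ≈ 0.55 (and nephroprotection ≈ 0.79) under the
  published group means and SEM-derived SDs: the 40-MBq arm's power at
  α = 0.05 is itself only ≈ 0.80, and the 20-MBq and enalapril arms
  each reject in ≈ 20 % of cohorts. A single-cohort study reporting the
  full tier pattern is thus a moderately lucky draw; the package
  reports the measured reproduction rate rather than forcing it.
* `beta_blood` cannot be varied freely while keeping whole-field
  conservation exact; the derived default is the conserving choice.
* The injection-site compartment absorbs the bolus-mixing bookkeeping
  (see above), so its rendered fraction slightly exceeds
  `residual_frac` when `t_mix > 0`.
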