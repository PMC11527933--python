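# Methods

This note documents the models, parameter choices and numerical conventions
behind `mrpet`, and what the synthetic data do and do not establish.

## Washout model and the k_E estimator

A decay-corrected tissue TAC is assumed mono-exponential after an early
uptake peak: `C(t) = C_p · exp(−k_E (t − t_p))` for `t > t_p`, with the peak
before 15 min. The estimator fits `ln C` against frame-midpoint time (in
hours) by unweighted ordinary least squares over the half-open window
[15, 90) min and reports `k_E = −slope` (h⁻¹), its standard error, the
intercept and R². Conventions:

* Frames belong to the window by **midpoint inclusion**; at least 3 frames
  and strictly positive values are required (violations raise, naming the
  offending frame).
* A perfectly flat curve has `k_E = 0` and R² defined as 1 (a perfect fit
  with no variance to explain).
* A rising curve returns a negative `k_E` as-is, flagged.
* The window is fixed, not an adaptive linearity search: the definition of
  the outcome is the slope over 15–90 min.
* OLS is unweighted; count-weighted variants were deliberately left out to
  keep the outcome definition simple and reproducible in any spreadsheet.

`k_E` is a model-free washout slope. It is not the compartmental efflux
constant `k₂`, which would require an arterial input function and is out of
scope.

Fitting a *non*-decay-corrected curve adds exactly the physical decay
constant λ = ln2/T½ (2.0423 h⁻¹ for C-11) to the slope;
`kE_decay_consistency` exposes this as a cross-check on decay handling.

## Synthetic subjects: what is emulated

The generator realises the study conditions with exactly known truth:

* **Frame schedule.** The list-mode re-binning 1×15 s, 3×5 s, 3×10 s,
  2×30 s, 3×60 s, 2×150 s, 2×300 s, 7×300 s sums to 55 min, although the
  acquisition lasts 90 min. The default schedule therefore widens the final
  block to 7×600 s — the unique single-block change reaching exactly
  5400 s — so washout is sampled to 90 min; the literal 55-min list remains
  available (`default_schedule(extended=False)`, CLI `--schedule literal`).
  Which re-binning the original acquisition actually used for the last
  35 min cannot be determined from the available description.
* **Tissue TACs.** Half-sine ramp to a peak (3–5 min post injection),
  then a pure exponential at the tissue's `k_E`. Default rates are the
  study-population means (overall and per sex): cortex 0.055, cerebellum
  0.033, choroid plexus 0.292, retina 0.234, lung 0.875, myocardium 0.641,
  kidney cortex 1.378, liver 0.685 h⁻¹. The piecewise form (rather than a
  convolution with a plasma input) makes the estimator's log-linearity
  assumption hold exactly in the noiseless limit, so ground truth is
  exactly recoverable — the property the test-bench needs. Peak SUVs for
  cortex and cerebellum are solved analytically so the model's 0–90 min
  areas equal the measured exposures (192 and 265 SUV·min); the remaining
  peak SUVs are plausible magnitudes (lung 3, myocardium 2.5, kidney cortex
  8, liver 4, choroid plexus 2.5, retina 1.5).
* **Frame values** are the exact time-average of the model over each frame
  (a midpoint-evaluation mode exists for bias-free estimator checks). The
  fit then uses midpoints as the time coordinate; the resulting bias is
  second order, `(k_E·Δt)²/24` per frame (≤0.22% for the kidney on 600-s
  frames), and propagates to ≤0.06% error in the fitted `k_E`. It is
  quantified by tests, not hidden.
* **Noise.** Zero-mean Gaussian with SD `noise_scale ·
  sqrt(model / (frame_duration · decay_factor(midpoint)))` — the standard
  dynamic-PET count-statistics heuristic (shorter and later frames are
  noisier); one seeded generator stream per subject; negative values are
  clipped at zero. The acquisition's true noise level is unknown; the
  default `noise_scale = 0.02` was chosen so the simulated test–retest
  spread of `k_E` lands in the reported 9–39% range across tissues and the
  low-signal brain regions remain reliably fittable. Between-subject
  variability is log-normal on `k_E` (unit-mean multiplier, default CV
  0.15, spanning the observed per-tissue CVs of roughly 0.08–0.30).
* **Blood and plasma.** Plasma follows a bi-exponential (amplitudes 14 and
  1.6 SUV, rates 0.45 and 0.004 min⁻¹ — plausible values; the study's own
  curves are shown only graphically). Whole blood is plasma divided by a
  saturating-exponential ratio pinned *exactly* through 1.51 at 10 min and
  1.59 at 90 min (rate 0.03 min⁻¹), sampled at 5, 10, 20, 30, 40, 60,
  90 min.
* **Plasma species.** Parent tracer constant at 30%; glutathione conjugate
  declining linearly in log-time through 63% (5 min) and 38% (40 min); the
  unidentified lipophilic species is the complement (7% → 32%). The
  complement construction is a modelling choice — the true kinetic form of
  the third species is unknown. Times early enough to make the complement
  negative raise an error.
* **Excretion.** Cumulative curves `F(1−exp(−k t))` with `F` chosen so the
  90-min values equal 55 %ID (bladder, rate 0.025 min⁻¹) and 2.7 %ID (gall
  bladder, 0.02 min⁻¹) exactly. A urine aliquot (250 ml counted at 95 min)
  carries an optional 8% CV measurement error, mirroring the looser
  agreement of gamma-counter-based excretion estimates with image-based
  ones.
* **HPLC fractions.** Fourteen 1-min fractions with counts distributed by
  the species model into retention windows (conjugate ~3.3 min, parent
  ~11.2 min, later-eluting remainder), physically decayed to each
  fraction's count time — the exact inverse of `species_percentages`.

What the synthetic data do **not** emulate: voxel-level images and VOI
delineation, partial-volume and motion effects, plasma-input-driven tissue
kinetics (TACs are generated directly in washout form), scanner physics
(dead time, randoms, scatter — corrected upstream in reality). Passing
tests therefore establish the correctness of the *computations* under the
stated model, not the behaviour of the estimator under violations of
log-linearity.

## Statistics

TRTV is `100 · (test − retest) / ((test + retest)/2)`, the signed percent
difference over the pair mean — zero for identical pairs, antisymmetric,
scale-invariant. The sign convention is test-minus-retest as the formula
states; note that a description of positive values as "higher on retest"
would imply the opposite sign. Paired comparisons use the classical paired
t (df = n−1); sex comparisons use the pooled-variance (Student) two-sample
t at α = 0.05 — the pooled form is a choice, Welch being equally
defensible. Statistics are computed from the textbook formulas with
p-values from `scipy.stats.t`, so independent implementations
(`scipy.stats.ttest_rel/ttest_ind`) serve as oracles in the tests rather
than as the implementation. Degenerate zero-variance inputs are defined by
convention: identical data give t = 0, p = 1; zero variance with separated
means gives ±∞, p = 0.

## Dosimetry

Residence times (time-integrated activity coefficients) use the convention
standard in clinical internal dosimetry: the **decay-corrected** source
curve is interpolated linearly between measured points — with activity
assumed zero at injection when the first sample is later — and the C-11
decay factor is integrated *analytically* within each segment; after the
last sample the region holds its activity subject to physical decay only
(analytic tail `A_last/λ`). This integrator is exact whenever the
decay-corrected curve is piecewise linear, in particular for pure-decay
sources; a plain trapezoid on the raw curve would overestimate the 10-min
late frames' contribution by several tenths of a percent at C-11's 20.364-min
half-life, which is why the decay-aware form is used.

The residence-time budget must close: sampled organs plus rest of body sum
to `1/λ = T½/ln 2` (29.38 min = 0.4897 h for
C-11); the rest-of-body term is the remainder and a sampled sum exceeding
the physical total raises (inconsistent inputs). Organ doses follow the
MIRD schema `D(target) = Σ_sources τ·S(target←source)` with τ in seconds
and S in mGy/(MBq·s), reported in µGy/MBq per phantom (adult male/female
chosen by subject sex, no sex-averaging). Effective dose is the ICRP 103
tissue-weighted sum (weights ship as an editable YAML together with an
explicit tissue→organ map); weighted tissues without an organ dose fall
back to the rest-of-body surrogate dose. With radiation weighting 1 for
photons/positrons, µGy/MBq and µSv/MBq coincide numerically.

The packaged S-value matrix is **synthetic**: six regions, self-dose
dominant, symmetric cross terms, a rest-of-body remainder column, female
values scaled 1.1× (smaller organs). It exercises the machinery and
preserves qualitative structure (the bladder wall tops the dose table when
excretion dominates), but absolute organ doses from it are not
reference-phantom dosimetry; supply a real S-value CSV for that. Organ
activity curves for the simulated subjects are built from the SUV TACs with
nominal effective volumes (kidneys 280, liver 1700, lungs 900 ml) — also
plumbing values, not phantom masses.

## Reporting conventions and problem sizes

The pipeline is deterministic from a single seed (per-subject child
streams); repeat runs are byte-identical, which is why per-stage timings
live in `run.log` rather than the manifest. TSVs are written with `%.17g`
and read with round-trip float parsing so interchange is lossless. Default
cohorts follow the study design (7 men + 6 women, 3 + 3 retested); test
and acceptance runs use these sizes or smaller (e.g. 2+2 cohorts for I/O
and determinism checks, 400 replicates for the power check, 2000 for the
type-I-error check), which keeps the full suite under a few seconds while
leaving Monte-Carlo error well inside the asserted bounds.

## Known limitations

* Tissue curves are generated in washout form, so the package cannot probe
  estimator bias under real (input-driven) kinetics that deviate from
  log-linearity within 15–90 min.
* The synthetic S-value fixture supports structural, not absolute, dose
  statements; effective doses on it differ from reference-phantom values.
* The unidentified plasma species is modelled purely as a complement.
* No bladder-voiding model: the bladder fills monotonically to scan end.
* `suv` assumes body-weight normalisation and tissue density 1 g/ml.
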