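# Methods

## Forward signal model (phantom)

The simulator's z-spectrum is an analytic sum of two Lorentzian lines
rather than a numerical Bloch–McConnell integration:

```
Z(Δω) = 1 − a_w · L(Δω − b0; γ_w) − s(b1) · A_cr · L(Δω − b0 − δ_cr; γ_cr)
L(x; γ) = γ² / (γ² + x²)
```

with `b0` the per-voxel water-centre shift (ppm) and
`s(b1) = 2·b1²/(1 + b1²)` a monotone, bounded, invertible
saturation-efficiency factor normalised so `s(1) = 1`. An analytic model
is sufficient to exercise every pipeline stage (field estimation,
resampling, asymmetry, kinetics); pulse-level fidelity, relaxation and pH
effects are explicit non-goals.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| water depth `a_w` | 0.85 | direct-saturation dip depth typical of muscle at 3 µT / 500 ms |
| water half-width `γ_w` | 1.8 ppm | γ·3 µT ≈ 128 Hz ≈ 1 ppm at 3 T; the direct-saturation line is broad |
| creatine centre `δ_cr` | +1.8 ppm | amine proton resonance |
| creatine half-width `γ_cr` | 1.2 ppm | exchange broadening, k_ex ≈ 1 kHz ≈ 1.2 ppm at 128 MHz |
| B0 field | 2-D quadratic, amplitude 0.1 ppm (0.25 in stress tests) | shim-error morphology |
| B1 field | 2-D quadratic in 0.9–1.1 (0.8–1.2 in stress tests) | coil-profile morphology |
| noise | additive Gaussian, sd 0 by default | at the simulated SNR the Gaussian/Rician distinction is negligible and keeps residual tests exact |
| WASSR grid | ±1 ppm, 21 points | a protocol decision the acquisition description leaves open; configurable |

These lineshape widths also matter numerically: the acquisition samples
only three offsets per side (±1.5/1.8/2.1 ppm), and the B0 correction is a
quadratic through those three points. For lines much narrower than the
0.3 ppm spacing the quadratic resampling error alone would exceed the
0.1 %asymmetry accuracy the correction chain is designed to hold; at the
physical widths above the worst-case deterministic error over
|b0| ≤ 0.25 ppm, b1 ∈ [0.8, 1.2] is below 0.08 %asymmetry.

The creatine amplitude `A_cr` is calibrated in closed form so the
asymmetry at 1.8 ppm equals a requested % exactly (including the creatine
tail under the −1.8 ppm reference side). Exercise kinetics are a step of
ΔCrCEST at the first post-exercise frame followed by
`rest + Δ·exp(−t/τ)`; default per-muscle values are the healthy-adult
medians (LG 6.2 %, 8.9 %, 138 s; MG 5.9 %, 5.0 %, 184 s; Sol 6.6 %,
3.4 %, 254 s).

Frame timing: baseline frames at −(n..1)·24 s, first post-exercise frame
at t = 0; the 2 min exercise interval itself is not imaged.

## Field corrections

**B0 (WASSR maximum symmetry).** Each voxel's water-only spectrum is
interpolated with a monotone cubic (PCHIP) onto a 10⁻³ ppm grid; the
centre `c` minimises the mean squared reflection residual
`Σ_ω (Ẑ(ω) − Ẑ(2c − ω))²` over offsets whose reflection stays inside the
sampled range. The search is a 0.01 ppm coarse grid over ±0.5 ppm
followed by a 10⁻³ ppm refinement around the coarse minimum — a
vectorised equivalent of golden-section refinement at the same tolerance,
chosen so the whole map is array-level numpy. Flat spectra (dip < 0.05)
are flagged invalid. Unit tests pin the estimator to an independent dense
grid-search oracle (10⁻⁴ ppm step).

**Offset resampling.** The measured spectrum is the ideal one shifted by
b0, so the ideal value at ±1.8 ppm sits at nominal offset ±1.8 + b0; each
side is resampled by a Lagrange quadratic through its three acquired
points, with a two-point linear fallback if one acquisition is flagged.
Voxels with |b0| > 0.3 ppm fall outside the three-point support and are
excluded from ROI averages rather than extrapolated.

**Asymmetry and B1.** `MTR_asym(%) = 100·(S(−1.8) − S(+1.8))/S(−1.8)`.
The `S(−Δω)` denominator convention is recorded in the output metadata
and switchable to the unsaturated `S0`. Voxels whose reference signal
drops to ≤ 0.05 are flagged (division instability). B1 correction divides
by `s(b1)` normalised to unity at nominal B1 — the generator-matched
inverse, documented and swappable, since the exact correction curve is a
sequence-level choice; voxels with b1 outside (0.5, 1.5) are flagged.
CrCEST is evaluated at the ±1.8 ppm pair only; the ±1.5/±2.1 acquisitions
serve B0-robust interpolation.

## Kinetics

ROI series are unweighted means of unflagged voxels per frame; frames
with zero usable voxels are dropped, and fits simply skip missing frames
(gap robustness is tested: dropping any interior frame moves a noiseless
τ̂ by < 1 %).

The recovery fit is bounded least squares of
`v(t) = asymptote + amp·exp(−t/τ)` on post-exercise frames only, with
τ ∈ [1, 5000] s. The asymptote is a free parameter, not pinned to the
resting level — nothing guarantees creatine returns exactly to baseline
within the 8 min window (a pin-to-baseline mode would be a trivial
extension). Initialisation: asymptote from the mean of the last three
frames, amplitude from the first post-exercise value, τ from a log-linear
regression of the positive residuals. Failure modes (non-convergence,
non-positive amplitude) surface as status `fit_failed` with diagnostics.

Plausibility bounds (τ < 24 s: below the temporal resolution; τ > 1000 s:
beyond the scan window, indicating an insufficient exercise response) are
applied *after* fitting so excluded estimates remain visible in the
outputs. The first post-exercise frame is included in the fit as well as
defining ΔCrCEST; fitting is unweighted. Both choices are configuration-
documented since either variant is defensible.

## Cohort statistics

Shapiro–Wilk screens normality; two-group Kruskal–Wallis compares groups
on non-normal outcomes. Mixed models (statsmodels `MixedLM`, REML) use a
subject random intercept with fixed effects age, sex, disease status and
muscle (LG reference), plus each named model's additional covariates
(resting: none / BMI / height + leg lean mass / height + leg fat mass;
Δ: none / total activity / waist; τ: none / Δ + resting / total
activity). Interaction screening is a likelihood-ratio test (ML fits) of
the disease × muscle block with χ²((m−1)(g−1)) reference; when an
interaction is present, per-muscle OLS suites are fitted. τ models use
plausible (status ok) rows only. Fixed-effect p-values and CIs use the
Wald normal approximation — the conventional degrees-of-freedom
corrections are deliberately not layered on, which costs a little CI
coverage at n = 32 (measured ≈ 93 % in the calibration tests, within the
92–98 % acceptance band). No multiple-testing correction is applied;
significance is two-sided p < 0.05.

The synthetic cohort generator draws 22 control + 10 FRDA subjects, three
muscle rows each, additively: control muscle median + disease effect +
subject intercept + residual, the two noise terms each at SD/√2 with
total SDs (1.5 %, 2.0 %, 105 s) matched to the observed interquartile
widths (IQR/1.349). Default disease effects are the observed FRDA −
control median gaps (e.g. τ: +136 s LG, +85 s MG, −44 s Sol). Covariates
mimic the cohorts (age ≈ 29 y, BMI and waist higher, activity lower in
FRDA) but are independent of outcomes unless injected.

## What the phantom does and does not show

Passing the recovery suites demonstrates that the algorithms are correct
and calibrated under the stated model: smooth fields, mono-exponential
kinetics, Lorentzian lines, Gaussian noise, perfect masks. Real scans add
motion, imperfect manual segmentation, magnetisation-transfer background,
pH sensitivity of the exchange rate, and non-exponential recovery in poor
exercise responders — none of which the phantom emulates, so the tests
validate the pipeline, not the biology. Problem sizes in the tests (64²
for most image-domain checks, 128² for the full-resolution round trip,
100–500 replicates for statistical calibration) were chosen as the
smallest at which the targeted effects are clearly resolved.

## Numerical details and edge cases

* Signals are clipped to [0, 1]; the forward model warns if parameters
  over-drive it by more than 10⁻⁶ before clipping.
* The WASSR dense grid uses exact-endpoint `linspace`; offsets are
  assumed to lie on (or near) the 10⁻³ ppm grid after PCHIP
  interpolation, which holds for any offset grid specified at ≥ 10⁻³ ppm
  resolution.
* Ties in the symmetry search resolve to the first (most negative)
  candidate; with the quantisation used, ties occur only on exactly
  symmetric noiseless data where all tied candidates are within one step
  of each other.
* Degenerate inputs raise typed errors: empty muscle masks, missing
  baseline or first post-exercise frames, constant samples in the
  normality test, singular mixed models, rank-deficient OLS designs, and
  unknown configuration keys (listed by name).
* All randomness flows through `numpy.random.default_rng` seeds recorded
  in session manifests; simulated sessions are bit-reproducible.

## Known limitations

* The B1 correction inverts the generator's own efficiency curve; for
  scanner data the curve should be replaced by a sequence-calibrated one
  (it is an isolated, documented function).
* 2-D single-slice geometry only; no world-affine reasoning.
* Mono-exponential recovery only; bi-exponential or gamma-variate models
  are out of scope.
* Wald-z inference slightly under-covers at small n (see above).
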