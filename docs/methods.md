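# Methods

`chromashift` quantifies short-term body-colour change (colour plasticity)
in individual fish from calibrated photographs and models those changes
with linear mixed-effects models. This note records the models, the
conventions, the defaults and the design choices, and what the synthetic
validation does and does not demonstrate.

## Colour measurement

Each photograph is paired with a binary region mask delimiting the fish
body. A pixel belongs to the region iff its mask grey value is strictly
greater than 127 on the 0–255 scale; mask and image must have identical
dimensions and are never resized.

Each included pixel is converted

    8-bit sRGB → linear RGB → XYZ → CIE 1976 L*a*b*

and the region value is the unweighted arithmetic mean of the per-pixel
L\*, a\*, b\* (the average is taken in Lab space, not RGB, because the
transform is nonlinear). Hue and chroma are derived from the *averaged*
opponent values, not averaged per pixel:

    C* = sqrt(a*² + b*²),   h* = atan2(b*, a*)  in degrees, wrapped to [0, 360)

A neutral region (C\* = 0) reports h\* = 0 by convention.

Colour standard: sRGB per IEC 61966-2-1 — two-piece transfer function
(threshold 0.04045, exponent 2.4) and the 4-digit D65 / 2° observer
primaries matrix. The reference white is the image of linear RGB (1,1,1)
under that matrix, so the white pixel (255,255,255) maps to exactly
L\* = 100, a\* = b\* = 0, and (0,0,0) to L\* = 0. Consumer-camera JPEGs are
sRGB by default, which motivates the choice; the 4-digit matrix agrees
with higher-precision published primaries to ≈0.02 Lab units over the full
8-bit cube (the cross-check against scikit-image in the test suite uses a
0.05 tolerance for this reason). Tristimulus values more negative than
−1e-9 are rejected as errors; smaller negatives are clamped to zero.

Hue is reported in degrees. Analyses of this kind sometimes carry hue in
radians or as a normalised ratio without saying so; the unit is therefore
recorded in every output's provenance sidecar rather than assumed
downstream.

## Calibration

Photographs carry a colour cast from the illumination. When a colour chart
with known nominal sRGB patch values is photographed alongside the fish,
the cast is modelled as a single 3×3 linear map acting on linearised RGB —
the simplest physically motivated description of an illumination change.
There is deliberately no offset term (black stays black) and out-of-gamut
corrected values are clipped, never renormalised (neutral patches stay
neutral). The matrix is fitted by ordinary least squares over the chart
patches and reported with its RMS patch residual in linear-RGB units;
fewer than three patches, or patches that do not span the three channels,
are rejected as underdetermined.

Numerical behaviour worth knowing: when the chart observations themselves
are 8-bit quantised, the fitted matrix carries noise of order 1e-2, which
on patches with a near-zero channel can move the corrected value by ~3
8-bit steps (the sRGB curve is steep near black). The exact-inversion
property — cast undone to within one quantisation step per channel — holds
for a noiseless (continuous) cast, and that is how it is tested; the
quantised pathway is validated at the coarser 1e-2 matrix tolerance. The
synthetic cast generator draws well-conditioned, near-identity matrices
and redraws any cast that would clip a chart patch at the gamut boundary,
since such a cast is not recoverable from chart data.

## Shift assembly

Each fish is photographed at 0, 24 and 48 h; the analysis response is the
change in an attribute over the intervals 0–24, 0–48 and 24–48 h, signed
later-minus-earlier (positive ΔL\* = lightening). Hue is circular, so Δh\*
is the signed shortest angular difference in (−180, 180], which avoids
spurious ±360 jumps near the wrap point; interval additivity
Δ(0–48) = Δ(0–24) + Δ(24–48) then holds exactly for L\* and C\* and modulo
360 for h\*. Series missing a time point are dropped with a logged
warning (imputation is deliberately not attempted); duplicated
(individual, treatment, time) records are an error. a\* and b\* shifts can
be computed but are not modelled — they enter only through hue and chroma.

## Experimental designs

Two designs are built in, mirroring the study structure the package
targets:

* **social**: two near-isogenic selfing lines (DAN, R) of the mangrove
  killifish *Kryptolebias marmoratus*; per line 8 control fish and 9 test
  fish, each test fish measured under both a single-conspecific and a
  group context — 34 unique fish, 52 fish×context series, 156 photographs.
  A test fish's random intercept is shared across its two series.
* **infection**: 80 fish (40 per line), half carrying an ectoparasite and
  half handled controls — 240 photographs.

## Inference

For one attribute the response is the shift `delta` with covariates
`line` (reference DAN), `treatment` (reference control) and `time`. Time
is coded as the interval-end hour (24, 48) by default — a single slope, as
one would use when shifts accumulate with exposure time — or optionally as
a three-level categorical interval; both codings are supported because
neither is canonical for interval-differenced responses, and the coding in
use is recorded in the provenance sidecar.

* **Candidate ladder.** Four models: {main effects, all interactions up to
  three-way} × {with, without a per-individual random intercept}. Random-
  intercept models are fitted with `statsmodels` `MixedLM`, fixed-effects
  models with OLS; selection fits use maximum likelihood.
* **AIC.** AIC = 2k − 2·logLik with k counting fixed coefficients plus
  variance parameters (the random-intercept variance when present, plus
  the residual variance). Candidates within 2 AIC units of the best are
  treated as equivalent and the simplest equivalent model is chosen, with
  a deterministic tie-break: fewest parameters, then fewest interaction
  terms, then no random intercept.
* **Simplification.** Backward elimination on the chosen model: among
  terms not marginal to a retained interaction, drop the one whose removal
  lowers AIC the most; stop when no removal lowers AIC. The elimination
  path is logged and attached to the returned fit. Note that AIC-based
  dropping retains a truly null term with probability ≈ P(χ²₁ > 2) ≈ 0.16,
  so simplified models legitimately keep an occasional noise term; the
  validation asserts retention of true effects, not removal of null ones.
* **Random intercept.** Likelihood-ratio χ² = 2(logLik_full −
  logLik_reduced) under ML between otherwise identical models, with
  degrees of freedom equal to the parameter-count difference (1 for a
  single added variance). The p-value uses the plain χ² reference
  distribution, which is conservative at the variance boundary. Reports of
  this test elsewhere sometimes quote d.f. = 2 for what appears to be the
  same comparison; this implementation reports the parameter-count
  difference and records it in the output.
* **t tests and degrees of freedom.** Fixed-effect t statistics use
  residual degrees of freedom n − k_fixed. For mixed models this is an
  approximation (Satterthwaite-style df are not available for `MixedLM`);
  at the built-in design sizes (≥156 observations) the difference from
  more refined df is negligible, and the convention is written into the
  provenance sidecar rather than silently assumed.
* **Final refit.** After selection and simplification, models with a
  random intercept are refit by REML for unbiased variance estimates; the
  coefficient tables report the REML fit while selection remains ML-based.
* **Post hocs.** Estimated marginal means: model predictions averaged with
  equal weights over the grid of the other categorical factors, continuous
  covariates held at their observed mean. All pairwise differences carry
  Tukey (studentized-range) adjusted p-values; with two levels the
  adjusted p equals the raw p. Degenerate fits (random-intercept variance
  < 1e-10) are flagged as boundary fits, not silently accepted.

## Synthetic data: what it emulates and what it does not

The generators replace the study's raw photographs and phenotype records,
which are not available.

* **Fish images** are ellipses of a known base Lab colour with independent
  Gaussian Lab mottling per pixel (default SD 3 Lab units, a coarse stand-
  in for the killifish's mottled grey melanin pattern), on a contrasting
  background, quantised to 8-bit PNG with a 255/0 ellipse mask. The
  recorded ground truth is the mean of the *rendered 8-bit* pixels,
  computed by a pure-scalar per-pixel loop that shares no code with the
  vectorised measurement path, so the two can arbitrate each other to
  1e-9. Not emulated: fish shape, fin edges, specular highlights, partial
  masking error, JPEG compression — so passing tests validate the
  measurement arithmetic, not robustness to real photographic artefacts.
* **Charts** are the 24 nominal sRGB patch values of the classic
  colour-rendition chart pushed through a known cast.
* **Phenotype tables** are drawn exactly from the stated model
  y = Xβ + u_individual + ε with u ~ N(0, σ_u²) per fish and independent
  Gaussian residuals per record, either directly as shifts (matching the
  model the inference assumes) or as attribute trajectories that are then
  differenced (exercising the assembly pathway). Defaults σ_u = 2,
  σ_ε = 4 Lab units give ICC = 0.2, and default effect sizes are of the
  order of a few L\* units — magnitudes chosen to be realistic for
  short-term melanin-based colour change, not fitted to any dataset.
  Because the generator matches the fitted model family, parameter
  recovery demonstrates correctness of the estimation machinery, not
  robustness to model misspecification.

All generators are deterministic given their seed; identical seeds give
bit-identical images and tables.

## Validation scales

The simulation studies in the test suite run at the built-in study scale
(80 individuals × 3 intervals): 500 replicates for confidence-interval
coverage (each generating coefficient covered by its 95% CI in 95% ± 3% of
replicates), 1000 null replicates for type-I error (rejection rates in
[0.03, 0.07] at nominal 0.05), and 60 high-ICC replicates for the
random-intercept LRT (p < 0.001 in ≥ 95%). These sizes keep the whole
suite to a few minutes while leaving the binomial noise on the checked
rates well inside the asserted bands.

## Known limitations

* No automatic segmentation: masks are inputs (or synthetic fixtures).
* The calibration model is a 3×3 linear map; it cannot represent
  nonlinear or spatially varying illumination changes.
* Mixed-model t tests use residual df (see above).
* Hue is treated as linear within (−180, 180] differences; attributes are
  modelled one at a time with no multivariate error structure.
* The paper-style Tables-1/2 coefficient layout is reproduced structurally;
  numerical agreement with any particular study is out of scope because no
  raw data are deposited with it.
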