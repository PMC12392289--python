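# Methods

## Forward model

Each tissue point is an inertia-free Kelvin-Voigt body,
`mu x' + E x = F(t)`, with `E` in kPa and `mu` in Pa s so that
`tau = mu/E` is directly in milliseconds.  The acquisition timeline places
every event in consecutive pulse-repetition slots of width `1/PRF = 86.96 us`:
two reference pulses, a 300-cycle push at 4.21 MHz (71.26 us, fits one slot),
eight tracking pulses, a second push, and 43 tracking pulses — 53
displacement samples per location.  Push slots carry no sample, so the first
post-push observation falls 15.7 us after the push ends.  The force is a
boxcar of unknown absolute amplitude; a single constant
(`FORCE_SCALE_UM_KPA = 50 um kPa`) maps relative amplitude to a realistic
micron scale (~1-8 um peaks in the 1.5-25 kPa range used here).  An inertial
variant (`m x'' + mu x' + E x = F`) is integrated numerically (piecewise
Radau between forcing discontinuities) and serves purely as the oracle for
the closed form; sub-millisecond ARFI responses in soft tissue are treated as
massless throughout the pipeline, because no mass handling is identifiable
from 53 creep samples.

## Inverse fit and its conditioning

`fit_visr` solves the two-parameter nonlinear least-squares problem
(amplitude `A`, time constant `tau`; `RE = 1/A`, `RV = tau RE`) by
trust-region iteration, initialized from the time-to-half-peak after the
second push, with `tau` bounded to [1 us, 50 ms] and convergence declared
when the residual RMS is below 20% of the peak displacement.  Whole images
use an algebraically identical variable-projection form: for each `tau` on a
48-point log grid the optimal amplitude is closed-form, so the fit reduces to
a 1-D search refined by parabolic interpolation in log-tau; the two paths
agree to solver tolerance and are cross-checked in the tests.

One conditioning fact shapes what the pipeline can and cannot estimate.  For
`tau` much longer than the 71-us push, the sampled response is approximately
`A (Tp/tau) h(t)` — amplitude and time constant enter almost only through
`A/tau`.  Consequently `RV = tau/A` is well conditioned (about 4% relative
RMSE under 5% additive profile noise, 200 trials) while `RE = 1/A` is not
(about 15% under the same noise, for any `tau` in 0.075-1 ms; the asymptotic
Cramér-Rao bound of ~4% is unattainable because the likelihood valley is
strongly curved at this SNR).  This was verified with two independent
estimators agreeing to nine digits on identical noisy data, so it is a
property of the model and timeline, not of the solver.  One acceptance check
asserts <10% for both parameters and is therefore intentionally left failing
for RE; the unit suite pins the achieved behavior (RV < 10%, RE < 20%).  The
same degeneracy — displacement amplitude conflating stiffness and viscosity —
is the mechanism the E/B study exploits when comparing PD against RE/RV.

## Phantoms and the stated cohort

Lesions are rotated ellipses on the acquisition grid (clinical resolution
2049 x 40 over 40 x 20 mm; cohort studies default to a 256-row desk-scale
grid with the same physical extent, full resolution being a config switch).
Margins are elliptical annuli with a signed width: positive widths place the
lesion's values, scaled by the margin factors, *outside* the B-mode
boundary; negative widths replace an annulus just *inside* the boundary with
background values — the parametric lesion simply recedes.  Multiplicative
lognormal heterogeneity (CV 5% by default, mean-corrected, spatially white)
is the positive noise model.  Scatterers for RF synthesis are drawn at
48/mm/line (>= 12 per pulse length, fully developed speckle; lesions are
hypoechoic at -6 dB).

The default cohort draws 40 lesions, 65% benign, imaged at 4 rotations of
30 degrees: semi-major axes 4.5-6.5 mm, axis ratio 0.6-0.85, centers at
14-26 mm depth; background 3 kPa / 0.6 Pa s; interiors 2.2-3.2x background
elasticity.  Benign interiors are drawn viscous (2.2-3.2x), malignant
interiors mildly viscous (1.2-1.6x) with the viscosity elevation carried by
the margin — a stated world chosen so that every confound below has room to
operate.  Class margins:

* malignant "classic" (70%): width 0.5-2.5 mm (capped at 45% of the
  semi-major axis so the crossing search window can reach it), factors
  1.5-3x the lesion values — visible in PD, RE and RV;
* malignant "confound" (30%): the margin holds `confound_pair` material —
  half the background stiffness with viscosity root-solved so the sampled
  double-push peak displacement matches the background within 1%.  The rim is
  invisible in PD (matched) and in RE (darker than background, which a
  half-contrast crossing cannot read as extension) but bright in RV;
* benign "receded" (60%): width -2 to -0.3 mm, factors 1 — E/B < 1 in all
  modalities;
* benign "decoy" (40%): an outward rim 0.5-2 mm wide with each channel at
  93% of its own half-contrast threshold, `0.93 (1 + f)/2` relative to
  background.  Individually sub-threshold in RE and RV, but PD responds to
  the *product* of the two elevations and drops below its threshold — a false
  extension only PD sees.

Mixture counts are deterministic (rounded fractions) so the class medians of
the acceptance trend check do not depend on binomial luck.  In `null` mode
all margin effects are disabled and both classes share one parameter
distribution, which calibrates the no-signal AUC band.  The decoy and
confound fractions, and the asymmetric interior-viscosity ranges, are
modeling choices of this package: the source study reports only the margin
mechanism qualitatively, and these are the minimal ingredients that make
displacement-derived E/B measurably worse than viscoelastic E/B — on pure
stiff-viscous-rim cohorts PD sees every margin (as a dark ring) and performs
as well as RE, which contradicts the observed ordering.

## RF synthesis and tracking

Each line is 1-D: the RF trace is a sum of Gaussian-windowed tones (two-way
carrier period `c/2f = 0.125 mm`, envelope FWHM equal to the 2-cycle pulse
extent) centered on the scatterers, re-rendered at each tracking time with
the scatterers displaced by their local Voigt response (push amplitude
attenuated with depth at `alpha f z`, default 0.5 dB/cm/MHz).  White noise is
added per line at the requested RF SNR.  Tracking uses zero-normalized
cross-correlation of 1.5-wavelength kernels (50% overlap) against the
reference trace over an integer lag search, with ties broken toward zero
lag and 3-point parabolic sub-sample refinement.  At the acquired 6.5
samples per carrier period the parabolic estimator is biased by up to ~0.08
samples, so traces are polyphase-upsampled 4x before correlation (bias
< 0.01 samples); an exact-match shortcut returns integer lags exactly.  The
closed loop recovers programmed sub-10-um profiles with < 1 um RMS at 30 dB
RF SNR, degrading monotonically with noise.

## Corrections

Raw RE/RV inherit the depth profile of the push amplitude (RE rises with
depth: a weaker push reads as stiffer tissue).  `build_calibration` simulates
a homogeneous phantom under the same acquisition and records median RE/RV/PD
per row; `apply_corrections` multiplies each image row by
(focal-row median)/(row median) and then divides RV by an elasticity-bias
factor tabulated against fitted RE on a known (E, mu) grid at focal depth
(~1 in the noise-free chain; defined as 1 at zero true viscosity).  PD is
deliberately left uncorrected, as acquired.  On attenuated homogeneous
phantoms the corrected RE/RV are flat to < 2% CV, and re-deriving the
calibration from corrected images yields the identity within 1%
(idempotence).  The functional form of the clinical corrections is not
published; this row-median scheme is a declared substitute that satisfies
the stated behavior and is fully testable.

## E/B measurement

The B-mode diameter is the maximum vertex-pair distance of the traced
boundary polygon (256 evenly spaced sub-pixel vertices on the lesion
contour), ties broken toward the most lateral orientation.  The line is
copied to each parametric image with position and orientation frozen; the
profile along it is sampled at quarter-pixel steps by bilinear
interpolation.  The lesion level L is the median of the in-boundary segment;
the background level B is the median of the *outer halves* of tails extended
one full radius beyond each endpoint — using the whole tail would let a
margin ring masquerade as background.  Each endpoint then moves to the
outermost crossing of `(L+B)/2` within half a radius of its B-mode position
(outermost first, per side; no crossing leaves the endpoint in place, and an
in/out contrast below 5% returns the ROI unchanged with a low-contrast
marker).  On two-level step profiles this recovers the programmed extent
within one lateral pixel; on three-level ring profiles thresholding the
bilinear edge ramp biases each endpoint outward by up to a pixel, which is
treated as measurement realism.

Quality: CNR = |mean_in - mean_out| / sqrt(var_in + var_out) with the
"out" region an annulus one equivalent radius wide.  For ring-margin lesions
this statistic is structurally small — the ring inflates the annulus variance
and can cancel the mean difference even when the boundary is conspicuous —
so the study pipeline flags "unsure" below CNR 0.1 (the op-level default
stays at the conventional 0.5), and a record is also excluded when the
endpoint adjustment reports low contrast.  Unsure fractions rise
monotonically with RF noise.  Lesion characteristics come from the outline
(shoelace area, arc-length perimeter, circularity `4 pi A / P^2`, centroid
depth) and the degree of anisotropy per modality is the max/min ratio of the
median in-lesion value across the four rotations (absent with fewer than two
rotations).

## Statistics

Classifiers are logistic regressions fit by IRLS on standardized features
with a 1e-6 ridge (excluding the intercept) for stability under separation,
evaluated in-sample — no train/test split is mentioned in the source
procedure, so none is applied, and the reported AUCs are optimistic in the
usual in-sample sense (the null-cohort band, 0.4-0.6, bounds that optimism
at the study's n).  AUC is the tie-corrected Mann-Whitney concordance;
the operating point maximizes Youden's J with ties resolved toward
specificity.  Correlations are Pearson/Spearman via scipy; rank-sum
comparisons use the exact Mann-Whitney distribution when n1+n2 <= 10 without
ties and the tie/continuity-corrected normal approximation otherwise.
Cross-checks against statsmodels (logistic) and scikit-learn (AUC) guard the
hand-rolled pieces.

## Reproducibility

Every run derives all randomness from one master seed through
SHA-256-hashed (stage, lesion, rotation) child seeds below 2^31, so reports
are bit-reproducible from their configuration; configurations round-trip
through YAML.

## What a green suite does and does not establish

The synthetic cohorts have exactly elliptical lesions, piecewise-constant
rheology, white multiplicative heterogeneity, 1-D per-line acoustics with no
lateral beam coupling or aberration, in-plane probe rotation, and an
annotation that is the true boundary.  Green trend checks therefore
establish that the pipeline's mechanics — margin geometry, displacement
degeneracy, half-contrast measurement, exclusion, classification — reproduce
the expected ordering (viscoelastic E/B above displacement E/B, malignant
medians above 1, benign below 1, chance-level nulls), not that the clinical
effect sizes or AUC values are reproduced; those depend on patient data this
package does not have.  Known limitations beyond scope: no shear-wave
coupling between lines, no reader variability model, no out-of-plane
rotation, and the RE noise-identifiability floor discussed above.
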