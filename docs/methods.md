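# Methods

`perfx` simulates, processes and compares CT-perfusion studies of acute
ischemic stroke on a digital phantom, for the purpose of studying how two
acquisition techniques — fast multidetector CT perfusion (MDCTP) and slow
rotational flat-panel CT perfusion (FDCTP) on the angiography C-arm —
agree or disagree when the same brain is measured with both.

## Forward model

Contrast kinetics follow the standard indicator-dilution model. For a voxel
with blood flow `f` (we store CBF in ml/100g/min and convert to the
per-second flow fraction `f = CBF/6000`), mean transit time `MTT` and bolus
arrival delay `d`,

    c(t) = f · (AIF ⊛ R)(t − d),      R(t) = exp(−t / MTT),

with contrast concentration expressed directly as HU enhancement above the
tissue baseline (the HU-to-concentration proportionality is set to 1; only
relative CBF is ever used downstream). The central volume theorem
`CBV = f · MTT = ∫c / ∫AIF` holds analytically and is verified numerically
to better than 0.1% on a 0.1 s grid (trapezoid-corrected convolution on an
internally refined grid).

The arterial input function is a gamma variate
`A (t−t0)^α e^{−(t−t0)/β}` with α = 3, β = 1.5 s and A scaled to a 200 HU
arterial peak. The default onset is `t0 = 15 s` after injection/scan start:
a typical arm-to-brain transit that places the bolus *after* the two
flat-panel mask sweeps (0–12 s) and inside both protocols' acquisition
windows, making the mask runs genuinely contrast-free.

## Phantom

The scene is an ellipsoidal brain (gray-matter shell, CBF 60; white-matter
core, CBF 40 ml/100g/min; MTT 4/5 s) inside a skull shell (+1000 HU)
surrounded by air (−1000 HU), on a 64×64×24 grid at 2×2×4 mm — small
enough that the full pipeline runs in seconds, large enough to hold a
territorial lesion of several tens of ml. A 4×4×3-voxel vessel cluster in
the healthy hemisphere carries the undiluted AIF (sized so its interior
survives the 3×3×3 median filter).

Brain tissue carries a smooth, mirror-symmetric baseline transit-delay
field (2 ± 1 s, quantised to 0.25 s). Healthy Tmax in vivo is dispersed,
not constant; without this dispersion, hemispheric median statistics are
degenerate and collapse under the flat-panel protocol's timing distortion.
Mirror symmetry makes homologous (contralateral) voxels exact controls.

The lesion is a cone ("wedge") from the brain centre into the left
hemisphere, emulating a middle-cerebral-artery territory deficit. Its extra
bolus delay is graded from 70% of the nominal `lesion_delay` at the
angular rim to 100% on the axis — the periphery-to-centre severity gradient
of real territorial ischemia. This grading is what produces the clinically
familiar volume hierarchy (visible extent > normalised-Tmax volume >
absolute Tmax>6 s volume > core). Lesion CBF is set *uniformly* to
`lesion_cbf_fraction` (extent, default 0.40) and `core_cbf_fraction`
(inner cone, default 0.15) times the reference white-matter CBF: severe
ischemia flattens the gray/white flow contrast, and this matches the rCBF
thresholds' semantics, which are defined relative to reference ROIs in the
contralateral centrum semiovale. The white/gray CBF contrast (40/60) is
deliberately milder than textbook values so that a single deep-white-matter
reference supports whole-brain relative thresholds on a phantom without
partial-volume confounds.

Rendering integrates each voxel's noiseless curve over every frame's
integration window (0.5 s MDCTP-like, 5 s FDCTP-like — a slow sweep
averages over the bolus peak), adds the per-label baseline HU and i.i.d.
Gaussian noise (2 HU MDCTP-like, 4 HU FDCTP-like, reflecting the lower
flat-panel SNR). Mask frames contain baseline only. Voxels are grouped by
unique (flow, MTT, delay) triples so a full render takes well under a
second.

## Map computation

The processing chain is: optional rigid 3D–3D registration of all frames
to the first (SimpleITK Euler3D, mean-squares; off by default since the
phantom is motion-free) → background subtraction (mean of the mask runs;
for mask-less MDCTP-like series, the mean of the frames before the
automatically detected bolus arrival) → per-frame 3×3×3 median filter →
per-voxel cubic-spline resampling of the frame-centre samples onto the
integer-second grid 0..floor(last centre), with values before the first
frame centre set to 0 (causality: no contrast before the first post-mask
measurement) and negative interpolants clipped → tissue masking (baseline
HU within [−100, 200]; peak enhancement below 50% of the arterial peak) →
automatic AIF detection (candidates above a 100 ΔHU floor, ranked by
peak / (time-to-peak × FWHM), mean of the top 5; deterministic
tie-breaking) → deconvolution.

Deconvolution is block-circulant truncated SVD: the AIF matrix is made
circulant by zero-padding to twice the series length (delay-insensitive),
and singular values below `ψ = 0.15` of the largest are zeroed. The
residue peak search covers causal lags plus a 2 s acausal margin: curves
that have not returned to baseline by the end of the acquisition window
leak a spurious acausal lobe into the wrap half of the circulant residue,
which would otherwise steal the argmax for strongly delayed lesions.
Per voxel, CBF = max of the residue, Tmax = its argmax refined by 3-point
parabolic interpolation (sub-second Tmax, as clinical products report),
CBV = Σc/ΣAIF, MTT = CBV/CBF, and TTP = time-to-peak of the
pre-deconvolution curve relative to the AIF peak, floored at 0.

Two numerical properties of the truncation matter and are handled
explicitly:

* it biases CBF low by a roughly common-mode factor (~30% at ψ = 0.15),
  which cancels in every relative-CBF quantity the volumetry uses;
* it shifts the residue peak late by a constant ≈ 2 s. That constant is
  measured on the operator itself — the detected AIF convolved with a
  nominal 4 s exponential residue (true Tmax 0) is pushed through the
  truncated inverse and the argmax of the result is subtracted from every
  Tmax. When nothing is truncated the correction is exactly 0, so the
  noiseless pseudo-inverse recovery (used to validate the machinery) is
  untouched.

Before deconvolution the concentration volumes are Gaussian-smoothed
(5 mm FWHM for MDCTP-like, 12 mm for FDCTP-like input) — the generic
analogue of the heavy spatial smoothing all clinical perfusion products
apply; without it the noise floor inflates low-flow CBF estimates and
destroys core segmentation. The AIF is always detected on *unsmoothed*
curves, since spatial smoothing dilutes the arterial peak.

## Volumetry

The segmentation battery mirrors the clinical workflow. The *visible
extent* stand-in thresholds the Tmax map at the healthy-hemisphere median
plus a margin — 1 s, or 1.5× the healthy interquartile spread when the map
is noisier than that (a reader judges salience against the map's own
contrast) — then applies a 3×3×3 binary opening and keeps the largest
connected component. All other masks are computed *within* the visible
extent: absolute Tmax > 6 s; rCBF < 30% and < 45% with rCBF = CBF divided
by the mean of three 3.5 mm-radius spherical reference ROIs placed in the
anterior/middle/posterior thirds of the contralateral deep white matter;
and the semi-automated cuts on hemispherically normalised maps (map divided
by the healthy-hemisphere tissue median × 100; normalised Tmax > 150%,
normalised CBF < 30%). The healthy hemisphere is the one with lower mean
Tmax and higher mean CBF; if the two criteria disagree, Tmax decides
(logged). Volumes are voxel count × voxel volume / 1000 (ml); mismatches
are hypoperfusion-minus-core differences floored at 0.

## Cohort simulation and the between-protocol pattern

A simulated study draws `n_subjects = 20` subjects. Per subject the lesion
delay (U(5, 13) s — a large-vessel-occlusion severity profile), severity
fractions and wedge geometry vary; the same scene is rendered under both
protocols. Each *scan* draws its own bolus arrival t0 ~ U(15, 20) s and
bolus width β ~ U(1.2, 2.0) s: the two acquisitions are separate
injections tens of minutes apart, and the flat-panel protocol's
reconstruction error depends strongly on the bolus phase and width
relative to its 6 s sweep cycle. These per-scan differences produce global
Tmax distortions of roughly 1–3 s in the flat-panel maps while the
multidetector maps stay accurate.

A noteworthy negative finding emerged from this simulation and is worth
stating plainly. The clinical expectation is that reader-style visible
extents agree between the protocols better than absolute Tmax > 6 s
volumes do, with median normalisation rescuing the thresholded agreement.
When both protocols are processed by *one consistent, calibrated* engine —
as this package does — that ordering is not structurally guaranteed and in
our experiments usually inverts: the absolute threshold is applied within
the visible extent and discards exactly the sub-6 s voxels where the
reader stand-in errs, making the thresholded volume a stabilised subset of
the reader mask, while the threshold itself rarely flips for lesions of
LVO severity. The clinically reported divergence of thresholded volumes is
therefore attributable less to temporal sampling per se than to absolute
Tmax calibration differences between the distinct software products used
for each modality in practice — a gap that disappears when a single
pipeline computes both maps. The dedicated agreement test encodes the
clinical expectation and is allowed to fail, documenting this finding.

## Agreement statistics

Pearson r uses the product-moment estimate with Fisher-z 95% CI and the
t-distributed two-sided p (scipy). The ICC is ICC(1,1) from a
subject-random-intercept model — variance components by REML (statsmodels
MixedLM) with the closed-form one-way ANOVA estimator as fallback, and the
exact F-distribution confidence interval in both cases; on balanced pairs
REML and ANOVA coincide. Bland-Altman reports mean difference (A − B),
bias ± 1.96 sd limits of agreement, and a normal-theory bias CI. The
method contrast DC is the fixed method effect (B − A) from the same
random-intercept model, equal to the paired mean difference on balanced
data (paired-t fallback on non-convergence). Wilcoxon-Mann-Whitney tests
use the exact null distribution for combined samples of ≤ 12 without ties
and the tie-corrected normal approximation otherwise. Summaries are median
with linear-interpolation (type-7) quartiles; two-sided tests, α = 0.05,
no multiplicity correction.

## What the phantom does and does not show

The generator emulates: protocol timing (30 × 0.5 s frames over ~47 s vs
10 × 5 s sweeps with 2 mask runs), sweep integration, detector noise
levels, bolus-phase variability between separate injections, a graded
territorial lesion with reduced flow and prolonged transit, and
gray/white/vessel/skull/air tissue classes. It does not emulate beam
hardening, scatter, motion (available behind a flag but off by default),
contrast recirculation, realistic anatomy, partial-volume gradients at
tissue interfaces, or inter-rater variability. Passing tests therefore
demonstrate the internal consistency of the estimation and segmentation
machinery and quantify how the two protocols' volumetry diverges under a
shared processing chain — not clinical performance on patient data, whose
per-patient distributions cannot be reproduced from published summary
statistics.

## Numerical choices and degenerate inputs

All argmax-style operations take the earliest index on ties. Spline
resampling falls back to linear interpolation below 4 frames (logged).
Registration failure passes the frame through with a warning. An all-zero
AIF, an empty tissue mask, a zero healthy-hemisphere median and a
reference ROI outside tissue raise descriptive errors; an all-zero tissue
curve yields zeroed map values with the mask bit cleared. Problem sizes in
tests (64×64×24 grid, 20-subject cohorts, 1000-replicate coverage
simulations) were chosen so the full validation battery runs in a few
minutes on one CPU.
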