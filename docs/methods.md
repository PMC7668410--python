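# Methods

`petrepro` implements a quantification-and-reproducibility protocol for
coronary ¹⁸F-fluoride PET and validates it end to end on synthetic data with
known ground truth. This note records the models, the defaults and why they
were chosen, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## The measurement protocol

Coronary ¹⁸F-fluoride uptake is quantified as a target-to-background ratio:
the hottest voxel of a lesion region of interest (SUV_max) divided by the
mean uptake of a background region (SUV_mean). Fluoride has very low
myocardial uptake, so cardiac blood pool activity (SUV_mean ≈ 1.14) stands
clearly above the interventricular septum (≈ 0.80), and the large atria
provide the most reproducible background; the package therefore uses
TBR_max = SUV_max(lesion) / SUV_mean(left atrium) by default, with the right
atrium, ventricles, superior vena cava, brachiocephalic vein and a
non-avid referent plaque available as alternative denominators. TBR values
are categorised against atrial blood pool as below (< 0.9), at (0.9–1.1,
both boundaries included — the range is printed as a closed interval) or
above (> 1.1). Visual positivity of a segment is adjudicated by consensus
(at least 2 of 3 observers), and one positive segment suffices for a
patient-level positive call. The deterministic ground-truth visual rule in
the simulator marks a lesion positive iff it lies on a plaque-bearing
segment and its along-vessel extent strictly exceeds 5 mm; the human
perceptual act itself is not modelled — observer fallibility enters only
through the stochastic observer described below.

The TBR_referent variant divides lesion SUV_max by the referent plaque's
SUV_max-style reading from a small ROI. Because reproducible perimeter ROIs
cannot be drawn around coronary segments, SUV_mean is not defined for
coronary lesions; the referent denominator is therefore the referent ROI
maximum. This is one of two defensible readings of the protocol; the atrial
TBR_max is the primary metric either way.

## Synthetic data

### Digital cardiac phantom

The phantom is a stylised heart on a 96³ grid of 2 mm isotropic voxels
(192 mm field of view): spherical atria (18 mm radius), ellipsoidal
ventricles with an 8 mm myocardial shell, a 6 mm-radius superior vena cava
and 5 mm-radius brachiocephalic vein as finite cylinders, and spherical
coronary lesions painted last. Blood pool is 1.14, myocardium 0.80 and air
0 in SUV-like units. The scanner point-spread function is an isotropic
Gaussian of 6 mm full width at half maximum (σ = FWHM/2.3548), applied with
nearest-neighbour boundary extension; all structures sit more than 3σ from
the grid edge, so total interior activity is conserved by the blur to well
within 0.1%. Voxel centres sit at (index + 0.5)·spacing with the origin at
the corner of voxel (0,0,0); all ROIs are specified in world millimetres
and membership is centre-in-shape with no partial-voxel weighting.

The geometry is deliberately minimal: it reproduces the partial-volume
phenomenology that drives background reproducibility (large uniform atria
versus narrow, gradient-dominated veins; spill-out from sub-centimetre
lesions) without attempting anatomical realism. There is no reconstruction
model, no attenuation or scatter, no gating, and no coronary tree.

### Background reproducibility simulation

Repeated background reads are simulated as: one shared blurred phantom;
per patient a global activity scale (SD 0.08, emulating dose/uptake
variability); per scan a calibration scale (SD 0.04) and fresh white
measurement noise (SD 0.05 SUV); per observer-and-scan an independently
jittered copy of the ROI set, with isotropic Gaussian displacement of
SD 1 mm per axis. The jitter SD is a free parameter — no published value
exists for observer ROI-placement variability — chosen once at 1 mm as a
plausible sub-voxel placement error. The coefficient of variation is
computed per patient per region across the 2 scans × 3 observers = 6
replicates (percent, SD with n−1 over mean) and summarised as mean ± SD
across patients. Under these conditions the atrial CoV is a few percent
and sits below the caval and brachiocephalic CoV, reproducing the reported
ordering; the absolute CoV level depends on the noise defaults and is not a
fitted quantity.

### Nested measurement tables

Measurement tables follow the generative mirror of the analysis model:

    tbr(p, s, k, j) = μ + study(p) + scan_k + observer_j + a_p + b_s(p) + ε

with independent Gaussian random effects for patient (variance 0.04),
segment nested within patient (0.02) and residual (0.01), and sum-to-zero
fixed-effect levels (the coding is a package decision; it makes the grand
mean interpretable and gives the between-level spread a closed form).
Binary visual reads flip the segment's true positivity with probability
`observer_error` (default 0.04) independently per observer and scan — the
simplest mechanism producing minor reporter discrepancies. Defaults emulate
a 30-patient, 18-segment, 2-scan, 3-observer study with two cohorts:
stable disease (prevalence 0.138 of truly positive segments, TBR excess
+0.30) and recent myocardial infarction (one culprit segment per patient,
always truly positive, TBR excess only +0.05 so its intensity often sits at
or below blood pool). Cohort shifts are illustrative, not fitted. All
generators are deterministic given their seed.

## Agreement statistics

### Nested REML

All agreement statistics rest on the two-level nested linear mixed model
y = Xβ + a_patient + b_segment(patient) + ε fitted by restricted maximum
likelihood. The implementation profiles β and the residual variance out of
the restricted likelihood, leaving a two-parameter problem in the variance
ratios γ_p, γ_s ≥ 0. The nested block covariance admits exact inversion by
two stacked Woodbury identities, so one objective evaluation needs only
per-segment and per-patient sufficient statistics (O(#segments) work after
a single data pass). Ratios are parametrised as θ² so the zero boundary is
attainable and no negative variance can ever be returned; the optimiser is
Nelder-Mead from three dispersed initialisations keeping the best restricted
likelihood, with convergence tolerance on the restricted log-likelihood
well below 10⁻⁸ and ratios capped at 10⁸ (the exact-fit limit). On balanced
designs with interior solutions the estimates agree with closed-form ANOVA
expected-mean-square estimators to better than 10⁻⁶ relative — this
equivalence is asserted in the test suite against an independently coded
oracle.

Degenerate nestings are detected rather than left on a likelihood ridge:
if every patient has one segment, the segment component is aliased with the
patient component and is fixed at zero; if every segment (or patient) has a
single row, the corresponding component is aliased with the residual and
fixed at zero. This makes the iid special cases (classic Bland-Altman,
Lin's concordance on simple pairs) exact reductions rather than flat-ridge
accidents. A fixed factor whose levels biject with patients is rejected
with an identifiability error, as is any factor collinear with earlier
design terms.

### Mixed-effects limits of agreement

For paired differences (scan 1 − scan 2 per patient/segment/observer, or
lower- minus higher-indexed observer per patient/segment/scan), the mean
bias is the intercept of a model containing only the nested random effects,
while the spread comes from a second model additionally adjusted for fixed
factors — study and observer for scan-rescan, scan and observer-pair for
interobserver ("observer comparison" is implemented as a categorical factor
over observer pairs). The 95% limits are bias ± 1.96·√(σ̂²_p + σ̂²_s + σ̂²_ε);
the normal multiplier (not a t quantile) matches the large-sample
convention. Without clustering this reduces to mean ± 1.96·SD of the
differences.

### Variance-components concordance and binary kappa

The concordance correlation coefficient is computed from the variance
components of the raw-response model (fixed factors: observer, study, scan):

    CCC = (σ̂²_p + σ̂²_s) / (σ̂²_p + σ̂²_s + φ̂²_A + σ̂²_ε)

where A is the scan factor for scan-rescan agreement and the observer
factor for interobserver agreement, and φ̂²_A = Σ_l (β̂_l − β̄)²/L is the
population-variance spread of the factor's L sum-to-zero level estimates
(d²/4 for two levels differing by d). The residual is not partitioned into
scan-noise and observer-noise parts — the single stated random-effects
structure admits no finer split, so both modes share σ̂²_ε; consequently the
two modes differ only through φ̂². The estimate lies in [0, 1] by
construction. Applied to the 0/1 visual read, the same formula yields a
kappa-type statistic; it is reliable only when the positive proportion is
not extreme, so proportions outside [0.1, 0.9] raise a warning and a
constant outcome returns an undefined estimate with its reason. Kappa
labels use the bands poor ≤ 0.20, fair ≤ 0.40, moderate ≤ 0.60, good
< 0.81 (the printed "good" band ends at 0.80; it is extended to < 0.81 so
the bands are contiguous), very good ≥ 0.81.

### Bootstrap confidence intervals

Confidence intervals for CCC/kappa use a nonparametric cluster bootstrap:
patients are resampled with replacement (segments travel with their
patient, respecting the nesting) and relabelled so duplicate draws remain
distinct clusters. Intervals are bias-corrected percentile (no acceleration
constant): z₀ = Φ⁻¹(#{θ* < θ̂}/B), endpoints at the Φ(2z₀ ± 1.96)
percentiles of the replicate distribution, read off with the (B+1)p
order-statistic convention (quantile type 6), which avoids the inward bias
of linear interpolation at moderate B. The default is B = 2000 replicates
(B is not externally prescribed); everything is deterministic given the
seed, and an estimator failing on more than 10% of replicates aborts with
an instability error.

## Pipeline

`run_pipeline` chains simulate → quantify → categorise → agree, writing the
measurement CSV, background reads and CoV summaries, category frequencies
by cohort among consensus-positive segments, agreement JSON for
{all segments, visually positive plaques} × {between scans, between
observers}, and a manifest carrying a SHA-256 hash of the canonical
configuration; identical configurations give byte-identical outputs apart
from the manifest timestamp. "Visually positive" is defined as consensus
positivity on at least one scan. Bland-Altman point sets use the stated
sign conventions with the mixed-effects bias and limits as overlays.

## Problem sizes used in validation

The test suite checks the oracle equivalences at the sizes where the
reductions are exact or tight: balanced 4×3×2 ANOVA; 5000 iid differences
for the Bland-Altman reduction; 500 pairs for Lin's concordance; 2000
segment pairs for Cohen's kappa; variance-component recovery at 200
patients × 18 segments × 2 scans × 3 observers averaged over 50 seeds;
limits-of-agreement coverage on 2000 nested differences; bootstrap coverage
over 1000 simulated Normal-mean datasets at B = 500; background-CoV
ordering over 100 simulated patients with a one-sided Wilcoxon test at
α = 0.01. The acceptance script re-runs the same machinery at comparable
sizes (20 recovery seeds, 500 bootstrap-coverage datasets, B = 500 for the
study CIs) — sizes chosen to make Monte Carlo error small relative to the
assertions.

## Known limitations

* The phantom validates ROI arithmetic and partial-volume phenomenology,
  not image formation: reconstruction artefacts, motion, attenuation and
  registration error are absent, so passing tests say nothing about those
  error sources in real data.
* The stochastic observer flips calls independently per read; real observer
  errors correlate with lesion conspicuity and location (the reported
  difficulty near high right-atrial background has no counterpart here).
* The binary kappa shares the linear variance-components route of the
  continuous CCC; no logistic mixed model is offered, by design.
* TBR values below zero are possible in extreme simulated tails since the
  generative model is Gaussian; derived SUVs are floored at zero but TBR
  responses are left untouched for the agreement models.
* Scan-to-scan variability enters the CCC only through the fixed scan
  effect and the shared residual; a residual partitioned by scan would
  need replicate reads within scan-observer cells, which the design lacks.
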