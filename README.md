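# petrepro

Quantification and reproducibility analysis for coronary ¹⁸F-fluoride
PET, validated end to end on synthetic data with known ground truth.

¹⁸F-fluoride PET can localise microcalcification in coronary plaques, but a
useful imaging biomarker must be measured the same way twice: by different
observers and on repeat scans. `petrepro` is for imaging methodologists and
biostatisticians who need (a) the uptake metrics — SUV_max, SUV_mean and
target-to-background ratios standardised to atrial blood pool
(TBR_max = SUV_max / SUV_mean(left atrium)), with categorisation against the
blood-pool thresholds 0.9/1.1, 2-of-3 consensus adjudication and the
single-positive-segment patient rule — and (b) the agreement statistics
appropriate to nested designs (segments within patients, repeated across
scans and observers):

* **Nested REML variance components** for
  y = Xβ + a_patient + b_segment(patient) + ε, with sum-to-zero fixed
  factors (observer, study, scan), via a profiled restricted likelihood
  with closed-form block inversion;
* **Mixed-effects limits of agreement**: bias from a random-effects-only
  model of the paired differences, limits at bias ± 1.96·√(σ̂²_p+σ̂²_s+σ̂²_ε);
* **Variance-components concordance**
  CCC = (σ̂²_p+σ̂²_s)/(σ̂²_p+σ̂²_s+φ̂²_A+σ̂²_ε), with the between-level spread
  φ̂²_A of the scan factor (scan-rescan) or observer factor (interobserver)
  in the denominator; applied to binary visual reads it yields a
  kappa-type statistic with the usual poor→very good interpretation bands;
* **Bias-corrected percentile cluster bootstrap** CIs resampling patients.

Because no patient data ship with the package, a first-class synthetic-data
module provides the inputs: a digital cardiac phantom (blood pool SUV 1.14,
myocardium 0.80, 6 mm Gaussian point spread) for exercising ROI
quantification and partial-volume behaviour, and a hierarchical
measurement-table simulator with configurable variance components, cohorts
(stable disease vs recent infarction with a low-intensity culprit lesion)
and a stochastic observer that misreads with fixed probability.

## Worked example

```python
import petrepro as pp

# a 30-patient, 18-segment, 2-scan, 3-observer study with variance truth
# (patient 0.04, segment 0.02, residual 0.01) on the TBR scale
table = pp.simulate_measurements(pp.SimDesign(seed=5))

fit = pp.fit_nested_reml(table, "tbr_max", ("observer_id", "study", "scan"))
print(fit.summary())

loa = pp.mixed_loa(pp.paired_differences(table, "scan"), ("study", "observer_id"))
print(loa.summary())

ccc = pp.vc_ccc(table, "scan_rescan", n_boot=500, seed=1)
print(ccc.summary())
```

prints (abridged):

```
Nested variance components (REML)
==========================================
observations                3240
patients                    30
segments (nested)           540
...
var(patient)                0.0350597
var(segment|patient)        0.0320751
var(residual)               0.00990042

Mixed-effects limits of agreement
==========================================
pairs                       1620
mean bias                   0.0028
total SD of differences     0.1415
95% limits                  -0.2745 to 0.2802

Variance-components concordance
==========================================
mode                        scan_rescan
outcome                     continuous
CCC                         0.8715
95% bootstrap CI            0.8472 to 0.8989  (B=500)
```

The variance components recover the simulation truth (segment variance is
inflated here because the cohort lesion shifts act at segment level); the
between-scan differences are centred near zero with limits ≈ ±1.96·√(2σ̂²_ε);
and the concordance says that ~87% of the total measurement variance is
stable patient/segment signal rather than scan-level wobble or noise.

The same analysis runs from the shell on a measurement CSV:

```bash
petrepro all --seed 5 --out runs/demo          # simulate + quantify + agree
petrepro agree --table runs/demo/measurements.csv --seed 5 --out runs/demo
```

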