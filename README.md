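# emmetrics

Bigaussian analysis of ocular biometry in emmetropia and ametropia.

Adult refractive error is not normally distributed: it is leptokurtic and
skewed, and is well described as the sum of two overlapping Gaussian
populations — a narrow **Regulated** (emmetropised) group whose corneal
power, lens power and axial length are well matched, and a broad
**Dysregulated** group in which one or more components deviate. `emmetrics`
implements the full analysis chain needed to study these subpopulations in
a per-eye biometry cohort, for researchers in visual optics, myopia research
and ophthalmic epidemiology:

- **Paraxial eye optics** — corneal power from the thick-lens equation,
  Bennett's crystalline-lens power estimate, whole-eye power and cardinal
  points from a ray-transfer-matrix engine, axial power, and the refractive
  identity `SE = P_ax − P_eye`;
- **Bigaussian modelling** — a histogram fit of
  `Dist(SE) = a₁·exp(−((SE−μ₁)/σ₁)²) + a₂·exp(−((SE−μ₂)/σ₂)²)`
  (note the exponent carries no ½, so a component's SD is σ/√2), and a
  five-dimensional two-component Gaussian-mixture EM over
  (SE, P_c, P_lb, ACD_tot, AL) with k-means initialisation, seeded restarts
  and AIC selection;
- **Subgroup classification** — pairwise covariance ellipses of the compact
  mixture component, scaled by a factor ε calibrated so the Regulated
  fraction matches the refractive fit's narrow-component weight
  `w₁ = a₁σ₁ / (a₁σ₁ + a₂σ₂)`;
- **Synthetic cohorts** — a seeded generator that reproduces the published
  cohort moments, correlation structure and bigaussian refraction, with
  every synthetic eye optically self-consistent (its Bennett lens power
  reproduces its refraction exactly);
- **Descriptive analyses** — emmetropic-vs-cohort summary tables,
  Bonferroni-masked correlation matrices, 1 D refractive binning,
  anterior-segment alignment regressions, uniqueness pair counting at
  instrument repeatability, and AL-relative scaling profiles.

The statistical machinery follows the scikit-learn estimator idiom
(`BigaussianHistogramFit`, `TwoComponentGaussianMixture`,
`EllipseSubgroupClassifier` with `fit`/`predict` and trailing-underscore
attributes); module-level functions wrap these for scripting.

## Worked example

Run the whole pipeline on a 2000-eye synthetic cohort:

```bash
emmetrics all --n 2000 --restarts 50 --seed 1 --out run/
```

or equivalently from Python:

```python
from emmetrics import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=1, n=2000, restarts=50, out_dir="run"))
```

The run directory then contains the derived cohort, every table and figure,
and `report.md`, which for this seed reads (abridged):

```
- weights (Regulated/Dysregulated): 75.3% / 24.7%
- narrow component: mu = 0.373 D, sigma = 1.016 D
- r2 = 0.9999
- calibrated epsilon = 2.430 (1-D coverage 98.49%)
- Regulated fraction = 75.3%
- emmetropic eyes classified Regulated: 86.52%
- ACD_tot = 0.1665 AL + -0.6776 (r2 = 0.209, residual SD = 0.28 mm)
- ASL   = 0.0858 AL + +5.4312 (r2 = 0.073, residual SD = 0.27 mm)
- indistinguishable emmetropic pairs at limits of agreement: 2
```

Reading the output: the 1-D histogram fit splits the refractions into a
narrow Regulated component (here 75.3% of eyes; the generating reference
value is 71.4%, and single-cohort estimates scatter by a few points because
the two components overlap strongly) and a broad Dysregulated component.
The ellipse scale ε is then calibrated until the same fraction of eyes lies
inside all ten pairwise covariance ellipses of the compact 5-D mixture
component; most emmetropic eyes are Regulated, but a sizeable minority of
Regulated eyes are not emmetropic — matching refractive weights does not
make the two definitions coincide.  The anterior-chamber regression slope
and residual SD, and the near-unique biometric fingerprints (only a couple
of indistinguishable pairs among ~10⁶ comparisons at instrument
repeatability), mirror the published cohort behaviour.

To work with your own data, point the pipeline at a CSV with the header
`eye_id, age_y, sex, SE_D, r_ca_mm, r_cp_mm, CCT_mm, AD_mm, LT_mm, AL_mm`
(millimetres and dioptres):

```bash
emmetrics all --config myconfig.json   # with "input_csv" set in the config
```

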