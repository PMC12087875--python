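# Methods

This note documents the models, conventions and design choices behind
`emmetrics`, in the order the pipeline applies them.

## Paraxial eye model

Each eye is a centred paraxial system in air: a thick two-surface cornea
(radii `r_ca`, `r_cp`, thickness `CCT`, index 1.376), aqueous and vitreous
humours at a common index n = 4/3, and a crystalline lens reduced to a thin
power `P_lb` acting between two principal points placed at Gullstrand–Emsley
proportions of the lens thickness: `0.571·LT` behind the anterior lens
vertex and `0.378·LT` in front of the posterior vertex.  Distances are in
millimetres, powers in dioptres, with the 1000 mm/m factors kept explicit in
every closed form.  Axial positions are signed and referenced to the
anterior corneal vertex, positive towards the retina.

Surface and total corneal powers use the classical forms

    P_ca = 1000 (1.376 − 1) / r_ca
    P_cp = 1000 (4/3 − 1.376) / r_cp
    P_c  = P_ca + P_cp − 0.001 P_ca P_cp CCT / 1.376

and the whole-eye power is the thick-lens combination of `P_c` and `P_lb`
over the reduced separation between the cornea's second and the lens's
first principal point.

**Cardinal points are normative from the matrix engine.**  All principal
points come from a reduced-angle ray-transfer matrix (`ParaxialSystem`,
unit-determinant elementary matrices).  The classical shorthand formulas
for `pp_c2` and `pp_eye2` circulating in the literature use index symbols
whose referents are ambiguous; with one reading they reproduce the engine's
principal point *referenced to the posterior corneal vertex*, with another
they disagree with thick-lens optics altogether.  Rather than silently
choosing, `paper_literal_corneal_pp2` / `paper_literal_eye_pp2` evaluate the
literal shorthands so the discrepancy can be inspected (a test pins it
down); every derived quantity in the pipeline uses the engine.  The two
internal routes — matrix engine and closed-form combination with the true
principal-point separation — agree below 1e−9 D by construction, and this
is enforced by tests.

A degenerate convention: a lens with exactly zero power contributes no
principal-plane pair, so the system collapses to the cornea (the
inter-principal-plane jump is skipped when `P_lb = 0`).

## Refraction and Bennett lens power

The model refraction is the dioptric mismatch `SE_model = P_ax − P_eye`
with `P_ax = 1000 n / (AL − pp_eye2)` the power that would focus a distant
object on the retina.  Input refractions are taken as already referenced to
the corneal plane; no spectacle-vertex correction is applied in the
pipeline (an optional 12 mm conversion exists but is never used).

Bennett's lens-power estimate is implemented two ways:

- **`eq1-solve`** (default): the unique root of `SE_model(P_lb) = SE` on
  the physiological bracket [5, 45] D, found by vectorised bisection to
  machine precision.  This guarantees an exact round trip through the
  forward model (|ΔSE| < 1e−9 D over 10⁴ random eyes, tested).
- **`vergence`**: the classical vergence propagation from the cornea's
  second principal point to the lens.  The two routes reference the
  refraction at different principal planes (corneal vs ocular), a
  second-order effect in SE; they agree within 0.25 D for |SE| ≤ 8 D and
  the agreement is a test contract, not a runtime assertion.

## AL scaling

Dividing every axial distance by AL and multiplying every power by AL/1000
makes the eye unitless with AL = 1.  Under this isotropic rescaling the
thick-lens combinations are form-invariant: scaled surface powers compose
to the scaled total power exactly (tested to 1e−12), which is what makes
cross-eye comparison of surface positions and "relative powers" meaningful.

## The bigaussian convention

The refractive distribution is modelled as

    Dist(SE) = a1 exp(−((SE−μ1)/σ1)²) + a2 exp(−((SE−μ2)/σ2)²)

with **no factor ½ in the exponent**.  Consequently a component's standard
deviation is σ/√2, its integral is a·σ·√π, and the relative component
weights are `w_i = a_i σ_i / Σ a_j σ_j` (the √π cancels).  Every sampler
and moment formula in the package uses this convention; it is the single
most corrupting thing to get wrong, hence it is asserted in several tests
(e.g. the sampled narrow-component SD must be 0.935/√2 ≈ 0.661 D for the
reference parameters).

The package's reference parameter set (`REFERENCE_SE_FIT`) is the published
1 D-binned fit of an adult cohort's refractive distribution:
a₁ = 0.423, μ₁ = 0.372 D, σ₁ = 0.935 D, a₂ = 0.0668, μ₂ = 0.226 D,
σ₂ = 2.369 D, giving weights 71.4% / 28.6%.

### 1-D histogram fit

The sample is binned into **proportions** on integer-centred bins
(half-integer, left-closed edges; 1 D wide; ±10 D by default); proportions,
not counts or densities, are the only scale on which the reference
amplitudes are meaningful.  The bigaussian is fitted to the
(centre, proportion) pairs by unweighted nonlinear least squares from a
method-of-moments start plus 10 seeded jittered restarts; components are
relabelled narrow-first (σ₁ ≤ σ₂, ties broken by amplitude).  The model is
evaluated at bin centres, as in the reference protocol; fitting exact
bin-integrated proportions recovers μ₁ and w₁ to < 0.02 (tested), so the
centre-evaluation bias is immaterial at 1 D bins.  At n = 2000 the
narrow-component weight has a sampling SD of ~6 points because the two
components overlap strongly; single-cohort weight estimates therefore
scatter visibly even though the 20-seed mean is within ±0.03 of the
generating value.

### 5-D mixture

The biometry vector (SE, P_c, P_lb, ACD_tot, AL), restricted to |SE| ≤ 10 D,
is fitted with a two-component full-covariance Gaussian mixture by EM.
Each restart initialises from a seeded k-means split; the log-likelihood is
recorded every iteration (non-decreasing, a tested invariant); convergence
is a relative log-likelihood change below 1e−8 with a 500-iteration cap
(the reference protocol's tolerances are unpublished; these are tight
enough that the AIC ranking is stable).  Among converged restarts the fit
with the lowest AIC = 2k − 2 ln L (k = 41 free parameters: 1 weight,
2×5 means, 2×15 covariances) is kept — for a fixed model this equals
picking the highest likelihood, and the restart seed stream is a prefix
sequence so more restarts can never worsen the selected AIC.  Degenerate
covariance updates get a diagonal regularisation of 1e−6·trace/5.  The EM
implementation is the package's own (the per-restart trace and AIC
bookkeeping are part of the contract); a test cross-checks it against an
independent mixture implementation on a planted sample.

## Regulated/Dysregulated classification

The compact mixture component (smaller covariance determinant, ties broken
by weight — the selection rule had to be fixed here, as no published rule
exists) defines the Regulated template.  For each of the C(5,2) = 10
dimension pairs, its 2×2 covariance submatrix gives an ellipse with
semi-axes ε·√λ along the eigenvectors; an eye is **Regulated** iff its 2-D
Mahalanobis distance to the template centre is ≤ ε in every pair metric —
the exact inside-all-ellipses test, implemented as the Mahalanobis
inequality for numerical robustness (unit changes rescale ellipses but
cannot change labels; tested).

ε is calibrated by bisection on [0.5, 5.0] (tolerance 1e−3) to the smallest
value whose Regulated fraction reaches the target — the narrow-component
weight of the same cohort's 1-D refractive fit.  The fraction is a step
function of ε, so the achieved fraction generally overshoots the target
slightly; the published 70.3% vs 71.4% gap is exactly this artefact.
Two coverage readings of ε are reported side by side, because the operative
definition is ambiguous in the literature: the two-sided 1-D normal
coverage 2Φ(ε)−1 (97.62% at ε = 2.26) and the single-ellipse 2-D coverage
1 − exp(−ε²/2) (92.2% at the same ε).  Neither is asserted as "the"
coverage; classification uses ε directly.

## Synthetic cohort generator

The generator emulates a screened adult population cohort (right eyes,
|SE| ≤ 15 D) with n = 2000 by default.  Targets are the published
entire-cohort moments — CCT 0.53±0.03, AD 2.64±0.32, LT 4.25±0.29,
AL 23.14±0.90 mm, P_c 42.02±1.47 D — and the published Pearson correlation
matrix over (SE, AD, LT, VCD, AL, P_c, P_lb); the refraction marginal is
the reference bigaussian.

Default mode, *refraction-first*: draw SE from the mixture; draw
(AD, LT, AL, P_c) from the Gaussian conditional given SE; draw CCT
independently (the cohort shows no meaningful CCT correlations); invert
P_c into radii with a fixed posterior/anterior ratio 6.5/7.8 (no radii
moments are published, only powers — the quadratic inversion round-trips
P_c to 1e−9); and obtain P_lb by Bennett `eq1-solve`, so the forward optics
of every synthetic eye reproduce its drawn SE exactly.  Rejection sampling
enforces AL ∈ [19, 32] mm, positive distances and a bracketed Bennett root,
capped at 10× the requested size.

Two deliberate deviations from naive conditioning:

- **SE conditioning uses the mixture's own implied mean and variance**
  (0.330 D, 1.057² D²), not the cohort table's 0.02 ± 1.52 D.  The
  bigaussian fitted to a histogram has a smaller implied SD than the raw
  sample; conditioning with the larger table SD would attenuate every
  planted SE correlation by ~30%.  Using the actual SE marginal's moments
  plants the target correlations exactly in second moments (the mixture's
  non-normality does not enter covariances).
- **VCD is never sampled**: it is the accounting identity AL − (CCT+AD+LT),
  so its correlation with AL (target 0.951) is emergent, and checked within
  ±0.03 rather than imposed.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: lens-power correlations are emergent from the
Bennett inversion, not planted (the generated r(P_lb, SE) is positive where
the cohort's is slightly negative, because P_lb here is exactly the optical
balancing residual); age/sex structure is absent; measurement error beyond
the uniqueness repeatabilities is absent; and the per-component multivariate
covariances of the real cohort are unpublished, so the planted 5-D
structure used in recovery tests is self-defined.  A consequence of the
SE-conditioned linear design worth knowing: the emmetropic subset's mean AL
sits ~0.13 mm above the full-cohort mean (the conditional-mean line is
evaluated at the emmetropic SE average, which lies below the mixture mean);
the corresponding test checks against this generator-implied value, not the
printed cohort value.

`validate_cohort` grades means (within 4 standard errors), the imposed
correlations and AL–VCD (±0.05), SE leptokurtosis, and the raw-data
invariants; emergent lens-power correlations are reported as diagnostics
only.

## Descriptive analyses

- **Summary table**: emmetropia is −0.5 ≤ SE ≤ +0.5 D, bounds inclusive.
  The group test compares the emmetropic subset against the *entire*
  cohort (overlapping groups — the published table's own choice, kept for
  comparability), Bonferroni-corrected at 0.05/11.
- **Correlations**: Pearson r with p-values, masked at p < 0.05/11;
  zero-variance columns are flagged (NaN r, p = 1) instead of propagating.
- **Refractive bins**: integer-centred, half-integer left-closed edges
  (0.49 D → bin 0, 0.50 D → bin 1; the edge convention is not published and
  had to be fixed).  95% CIs use the t distribution; bins with n < 3 are
  reported with suppressed CIs.
- **Alignment regressions**: OLS of ACD_tot and ASL on AL for eyes with
  AL ∈ [20, 27] mm (beyond ~27 mm the anterior segment stops tracking AL);
  residual SD is reported alongside slope/intercept/r².  Per-group slopes
  use 1 D bins with ≥ 20 eyes.
- **Uniqueness**: exhaustive O(n²) comparison on (SE, P_c, P_lb, ACD_tot,
  LT, AL) with per-parameter absolute-difference tolerances of 1.96× the
  instrument repeatabilities (0.25, 0.12, 0.25 D; 0.009, 0.015, 0.019 mm).
  All unordered pairs are counted without removing matched eyes (three
  mutually identical eyes = three pairs); the convention is switchable in
  principle but this reading is the default.
- **Relative scaling**: surface positions as % of AL and the power shares
  P_c/P_eye, P_lb/P_eye.  An alternative "effectivity" share (powers
  vergence-translated to the ocular principal plane) is computed behind a
  flag and labelled non-normative: the translated shares do not sum to one,
  and no published recipe reconciles the two readings, so neither is
  asserted.

## Pipeline, sizes and determinism

The pipeline chains the stages in study order and writes every artifact
plus a manifest carrying the package version, seed and a hash of the
canonical config JSON (per-file hashes are not embedded in the CSVs, which
stay plain tabular files).  All randomness flows from the single config
seed; identical configs give byte-identical CSV/JSON outputs (tested).

Default problem sizes are the study conditions: cohorts of n = 2000 and
1000 EM restarts.  The test suite and the acceptance script use reduced
restart counts (5–50) and 20 fit seeds, which keep the full suite under a
minute of mixture fitting while leaving every statistical conclusion
unchanged (the AIC-selected fit on these well-conditioned cohorts is stable
from a handful of restarts on).

## Known limitations

- Accommodation, astigmatism, chromatic effects and gradient-index lens
  structure are out of scope; the lens is a thin power at fixed fractional
  principal points.
- Published cohort-specific values (table means, correlation entries,
  regression coefficients, the 70.3%/29.7% split, the three uniqueness
  pairs) are generator targets and documentation, not reproducible numbers:
  the underlying cohort data are not public, and the synthetic cohort
  reproduces the published *structure*, not the sample.
- The 1-D weight estimate is weakly identified at n = 2000 (overlapping
  components); treat single-cohort w₁ values as ±6 points.
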