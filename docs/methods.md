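# Methods

## The measurement model

The package treats a spectrally resolved CT scan as a voxelwise iodine
density map ID(v) in mg/mL, a surrogate for regional pulmonary blood
volume. Two manually placed blood-pool regions provide the scan's own
reference scale: the mean ID in the main pulmonary artery (ID_MPA, the
feeding vessel of the pulmonary circulation) and in the left atrium (ID_LA,
downstream of the lung and of any systemic-to-pulmonary collateral return).
All downstream quantities are either raw densities or ratios against these
two references, which removes inter-patient variation in contrast timing
and cardiac output.

### Compartment segmentation

The lung mask is partitioned by two thresholds derived from the references:

* **malperfused** — ID(v) < 0.05 · ID_MPA
* **normally perfused** — 0.05 · ID_MPA ≤ ID(v) < 0.5 · ID_LA
* **vessel** — ID(v) ≥ 0.5 · ID_LA

Boundary convention: a voxel exactly at 5% of the MPA is NORMAL and exactly
at 50% of the LA is VESSEL. The convention is arbitrary on a measure-zero
set but makes the three intervals a strict partition, which is asserted on
every segmentation. Degenerate references with 0.05 · ID_MPA ≥ 0.5 · ID_LA
are rejected with both values named, since no normal interval exists.

Two consequences worth stating because they are used as test invariants:
the malperfused compartment's ID_max,MPA is capped below 0.05 and the
normal compartment's ID_max,LA below 0.5, by construction; and the three
compartment fractions always sum to 100% of lung voxels (the vessel
remainder is reported explicitly rather than left implicit).

### Histogram features and normalization

Per compartment the package reports the voxel-count fraction of the lung,
ID_mean, ID_max, moment skewness g1 = m3/m2^(3/2) and excess kurtosis
g2 = m4/m2^2 − 3 (normal law = 0). Excess kurtosis is the right scale
here: a bounded, near-uniform density histogram — which is what a
threshold-truncated perfusion-defect compartment looks like — sits near
−1.2, and that is the regime the malperfused compartment occupies.

Biased (population) moment estimators are used rather than small-sample
corrected forms: compartments contain 10^4–10^6 voxels, where the two
coincide, and the population form makes the oracle tests exact. A
compartment with fewer than 2 voxels or zero variance reports NaN for the
moment features — 0/0 has no defensible value — and an empty compartment
reports NaN for everything except its 0% fraction.

Normalized features divide by the references:
ID_mean,MPA = ID_mean/ID_MPA, ID_max,MPA = ID_max/ID_MPA,
ID_mean,LA = ID_mean/ID_LA, ID_max,LA = ID_max/ID_LA. The LA-normalized
mean of the malperfused compartment is the marker of interest for chronic
disease: systemic collaterals raise residual defect perfusion, and scaling
by the LA (which integrates total left-heart contrast return) makes that
elevation comparable across patients.

Features are computed on voxel counts, not physical volumes; spacing is
assumed isotropic within a case. Mask editing and ROI placement are inputs,
not steps: real-data users supply final masks, and the phantom generates
consistent ones.

## Diagnostic-performance statistics

* **AUC** — tie-corrected Mann-Whitney estimator via midranks; equal to
  exhaustive cross-class pair counting (ties credit 1/2), which the test
  suite verifies exactly on small data. Direction is explicit
  ("higher"/"lower" is positive); flipping it complements the AUC exactly.
* **DeLong** — variance and covariance of correlated AUCs from per-subject
  placement values (structural components), sample covariances with
  ddof=1; 95% CIs as AUC ± z·SE clipped to [0,1]; paired two-sided test on
  the AUC difference. A perfect marker has zero estimated variance and
  yields a degenerate point CI, flagged with a warning rather than an
  error. The implementation is cross-checked in the tests against a
  stratified bootstrap, the Hanley–McNeil closed form under an exponential
  model, and the independent pROC implementation in R.
* **Youden cutoff** — candidates at midpoints between adjacent distinct
  scores plus ±∞ sentinels; this family attains every achievable
  (sensitivity, specificity) pair, so the midpoint search is globally
  optimal (verified against brute force). Ties in J resolve toward higher
  sensitivity, then the lower cutoff — favoring rule-out use. Cutoffs are
  derived on the training split and transferred unchanged to validation.
* **Predictive values** — Bayes' rule from sensitivity, specificity and
  prevalence; in split evaluation PPV/NPV come from the confusion counts of
  the set being reported, so validation values use validation prevalence.
* **Marker combination** — the two-marker score A + b·B + c is fitted as an
  unpenalized logistic model and rescaled by the anchor's coefficient, which
  reproduces the clinically reportable anchored form including an
  intercept. A distribution-free alternative maximizes empirical AUC over b
  on a sign-symmetric grid scaled by sd(A)/sd(B) (including b = 0 and
  near-dominant magnitudes, so the search can never do worse than either
  marker alone); it is also the automatic fallback when the logistic MLE
  diverges under perfect separation. The returned combination never has
  lower training AUC than either single marker. On equal-covariance
  Gaussian groups both estimators recover the Fisher discriminant direction
  Σ⁻¹Δ, which the tests check at n = 10^5.
* **Split** — stratified by group, per-stratum train size round(ratio·n),
  both sides non-empty, deterministic given the seed. Stratification is a
  deliberate choice: it keeps small validation sets usable and is declared
  rather than hidden. α is configuration (default 0.05), never hard-coded
  into decisions.

## The synthetic generators

### Voxel-level phantom

Two ellipsoidal half-lungs (radii 80×90×40 mm) on a default 32×40×40 grid
at 6 mm isotropic spacing — coarse relative to clinical CT but sufficient
to exercise every segmentation and feature path at interactive speed.
Within the lung, baseline iodine density is 1.6 mg/mL (chosen so that with
an MPA reference of 12.6 mg/mL the normal compartment's ID_mean,MPA lands
near 0.13, the observed scale) rising linearly along the ventral→dorsal
axis at 2%/cm from the ventral-most lung voxel — the gravity-dependent
perfusion gradient of a supine patient, modeled linearly because no
functional form is established. Measuring the gradient from the ventral
edge guarantees every lung voxel carries at least the baseline.

Perfusion defects are cones ("wedges") with the apex directed from the
hilum toward the pleura, mimicking segmental anatomy; anything protruding
beyond the lung is clipped to it. Inside a defect the density is
local_baseline · (defect_multiplier + collateral_fraction): the first term
is residual perfusion common to both diseases, the second the
systemic-collateral contribution characteristic of chronic disease. Group
presets: controls have no defects; acute embolism uses multiplier 0.10 and
no collaterals; chronic disease adds collateral_fraction 0.15. Collaterals
can supply up to ~30% of pulmonary blood flow, but 0.15 keeps the dorsal
end of a defect safely below the 5%-of-MPA detection threshold under the
default gradient — a phantom whose "defect" is not detectable by the very
rule being tested would be self-contradictory, and the builder rejects such
parameterizations unless explicitly told the case need not be detectable.

Blood-pool ROIs are 12 mm spheres in the mediastinum set to the true MPA
(12.6 mg/mL) and LA (10.1 mg/mL) densities; noise is additive Gaussian,
truncated at 0 mg/mL (the simplest model preserving non-negativity),
applied inside lung and ROIs only so that air stays exactly zero.
Everything is deterministic given the seed, and the noiseless phantom is
recovered exactly by the segmentation — the ground-truth defect mask equals
the malperfused compartment voxel for voxel. At noise SD = 10% of baseline
the defect fraction is recovered within 3 percentage points (dominated by
dorsal defect voxels whose density sits closest to the threshold).

Morphological features (MPA diameter, MPA/aorta ratio, RV/LV ratio,
bronchial-artery diameter) are manual radiologist readings in practice, so
a phantom case samples them from the feature-level distributions below
rather than pretending to measure them from the image.

### Feature-level cohort simulator

Draws per-patient feature vectors from per-group normal distributions with
the published group sizes (57 acute / 52 chronic / 22 controls) and the
published means and SDs for every reported continuous feature (references,
morphology, compartment fractions, normalized histogram features).
Positive-support features (diameters, densities, ratios, fractions)
redraw non-positive values rather than truncating analytically — at the
observed coefficients of variation the redraw probability is ≲1%, the bias
negligible, and the procedure is trivially auditable; redraw counts are
logged. Bronchial-artery diameter is missing-at-random per group at the
published detectability rates (31/57, 46/52, 5/22); chronic patients are
labelled with central vs peripheral thrombus level at the published 14:38
ratio (a simulated label, never an image measurement). Features are drawn
independently within group; one pair may optionally be drawn jointly with a
configured correlation. No within-group correlation between MPA diameter
and malperfused ID_mean,LA is published, so the default is 0 — the
combined-marker results below inherit that independence assumption.

**What the simulator does not emulate:** real cohorts have non-Gaussian,
skewed and bounded feature distributions, correlated features, and
measurement error shared across features of one patient. Passing tests
therefore demonstrate that the estimators and pipeline are correct, and
that the published group-level separations imply the published AUCs under
Gaussian independence — not that the pipeline generalizes to any particular
clinical population.

## Reproduction of the headline AUCs

The patient-level data are not deposited, so the three headline AUCs are
reproduced by simulation: 500 replicate 57-vs-52 cohorts, Mann-Whitney AUC
per replicate, averaged. Under the binormal closed form
AUC = Φ(Δμ/√(σ₁²+σ₂²)) the configured parameters give 0.726 for
malperfused ID_mean,LA, 0.768 for MPA diameter, and 0.828 for the published
combined score under independence — within ~0.01 of the published 0.72 /
0.76 / 0.82, which is what the acceptance script observes empirically.
Published sensitivity/specificity/PPV/NPV and the disease-vs-control
skewness AUCs are split- and sample-specific and are exercised
qualitatively in the pipeline example only, not reproduced numerically.

## Numerical choices and degenerate inputs

* Problem sizes: default study at the published 131-patient scale;
  estimator-oracle checks at n ≤ 20 (exhaustive), asymptotic recoveries at
  n = 10^4–10^5; phantom property loops on reduced 12×16×16 grids.
* CSV floats use the shortest round-trip representation and reads parse
  with round-trip precision, so write→read→write is byte-identical.
* Label maps are uint8 with fixed codes OUTSIDE=0, MALPERFUSED=1, NORMAL=2,
  VESSEL=3; volumes are stored in mg/mL with no rescale slope/intercept.
* Seeds: every stochastic component takes an explicit seed;
  replicate/per-case seeds are derived via `SeedSequence` and masked below
  2^31.
* Empty ROIs, single-class label vectors, zero-variance markers, singleton
  strata and degenerate thresholds raise typed errors naming the offending
  quantity; zero-variance DeLong CIs and degenerate predictive-value
  denominators degrade to flagged NaN/point values instead of failing.

## Known limitations

* No physical CT simulation: no spectral decomposition, reconstruction, or
  beam-hardening/motion pseudo-defects. The phantom tests the analysis, not
  the acquisition.
* No automatic lung segmentation or ROI placement; masks are inputs.
* The combined-marker reproduction assumes within-group independence of the
  two markers (see above); published coefficients cannot adjudicate the
  logistic vs rank-maximizing variant of the combination method, so both
  are provided.
* Whether the published CIs are DeLong- or bootstrap-based is not stated;
  DeLong is adopted as the choice consistent with the paired testing.
* Voxel-count (not volume-weighted) fractions; "% normal perfused lung" is
  computed relative to the whole lung including the vessel compartment,
  the reading consistent with the published group means summing to ~97–98%.
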