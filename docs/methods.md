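# Methods

## The mapping model

VLSM here is a mass-univariate linear-probability model.  For each voxel
*v* of the template grid, the binary lesion indicator across subjects is
regressed on the symptom design `X = [score, sex, age, volume, 1]` by
ordinary least squares, and the per-voxel statistic is the t-value of
the frequency-score coefficient.  Lesion status is deliberately the
*response* and the symptom score a *predictor* — the reverse of the
orientation much of the lesion-mapping literature uses — because the
per-voxel question being asked is "is this voxel more likely to be
lesioned in patients with frequent seizures, holding sex, age and tumor
volume fixed?".  The ordinal score (0–4) enters as a numeric covariate;
this treats the grade spacing as linear on the lesion-probability scale,
which is an assumption, not a fact about the scale.

The design always contains an intercept, and the nuisance columns are
mean-centered.  Centering cannot change the frequency t-statistic (the
fit is invariant to shifting or rescaling any nuisance column — this is
tested), but it keeps the frequency coefficient interpretable as a
probability change at the covariate mean.  A nuisance column that is
constant across the cohort (e.g. a single-sex cohort) is dropped with a
warning rather than left to make the design singular.

Internally every fit goes through the Frisch–Waugh–Lovell
residualization: the score column and the lesion data are both
residualized against the nuisance block once, after which the
coefficient, its classical standard error, and the t-value follow from
two inner products per voxel.  This is an exact algebraic identity with
the full normal equations (verified against an independent
`(XᵀX)⁻¹Xᵀy` solver at 1e-8 relative tolerance) and it makes a
1,000-permutation run a single matrix product per permutation.

## Eligibility: the power screen

Voxels lesioned in very few (or almost all) subjects cannot yield a
reliable contrast.  Before any testing, a power map is computed from the
lesion overlap count: with *k* of *n* subjects lesioned, the power to
detect a standardized two-group difference *d* at two-sided level α is
`Φ(d·√(k(n−k)/n) − z₁₋α/₂)` (normal approximation; it agrees with the
noncentral-t calculation to a few parts in a thousand at cohort sizes).
Voxels with power strictly above 0.8 are eligible; the screen runs
*before* the GLM and the permutation null, so ineligible voxels are
never tested.  The assumed effect size defaults to d = 1.0 ("large" in
Cohen's convention) — a documented package default, configurable, since
the screen is a coverage filter rather than a substantive hypothesis.
Voxels whose lesion indicator is constant across subjects are ineligible
regardless of the screen.

## Permutation thresholding

The null distribution is built by permuting the frequency-score column
across subjects while sex, age and volume stay attached to their
subject's lesion: the hypothesis being broken is the score–lesion
association, not the covariate structure.  With N permutations the
per-voxel threshold is the ⌈(1−α)·N⌉-th order statistic (ascending) of
the permuted t at that voxel, and a voxel is retained only when its
observed t is *strictly* greater — a one-sided rule that retains only
positive associations.  With N = 200 and α = 0.05 the expected retention
rate under exchangeability is 11/201 ≈ 0.055, slightly above α; this is
the usual discreteness of permutation tests, not an error.

Two caveats are worth stating plainly.  First, permuting the raw score
is exchangeable only when the score is independent of the lesion data.
If the score depends on lesion *volume* (as it does in the synthetic
cohorts, where volume is a latent-model covariate), the simple scheme is
mildly anti-conservative even though the per-voxel null hypothesis
(zero partial coefficient) holds: measured retention on null cohorts
runs ≈ 0.06–0.075 at nominal 0.05.  A Freedman–Lane scheme — permute
the reduced-model residuals of the lesion data instead — is provided
(`scheme="freedman_lane"`) for users who want covariate-robust
permutation; the simple scheme stays the default as the minimal reading
of "permutation testing" of the symptom of interest.  Second, the
default thresholding is *voxel-wise* (each voxel against its own 95th
permuted percentile), which controls the per-voxel error rate, not the
familywise rate; `mode="max_stat"` substitutes the permutation
distribution of the maximum t over eligible voxels for FWE control.

Voxels fitted exactly (zero residual — possible at small n with a
deterministic lesion/score relation) would have infinite t; they are
reported at the finite cap 1e12 and flagged.  Fixed seed implies
bit-identical thresholds (tested).

## Clusters, peaks, involvement

Retained voxels are grouped into connected components, by default under
26-connectivity (a common volumetric choice; 6 and 18 are available).
Each cluster reports its size, peak-t voxel and peak t; clusters are
ordered by peak t descending with ties broken by the lexicographically
smallest coordinate, and the peak search itself resolves t ties the same
way.  Voxel coordinates are 0-based (x, y, z) internally; report tables
additionally print 1-based coordinates, since published template
coordinates are often 1-based.  "Involvement" of a subject is binary:
does the tumor mask contain the top cluster's peak voxel.  Involved and
non-involved subjects' frequency scores are then compared by a
Mann–Whitney U test (midranks for ties, tie-corrected normal
approximation without continuity correction — the scores are five-level
ordinal data, far from the exact test's assumptions).

## Clinical statistics

Pearson chi-square is computed *without* Yates continuity correction:
the printed cohort tables this package reproduces are only matched by
the uncorrected statistic (e.g. the resection × frequency table gives
p = 0.0080 uncorrected, 0.012 corrected).  p-values are printed to three
decimals, "<0.001" below that.  The multivariate logistic model admits
exactly the variables with univariate p strictly below 0.05; fits that
fail to converge or show (quasi-)separation — detected via the
statsmodels separation warning and a |coefficient| > 15 guard — are
flagged and their coefficient tables withheld.  Engel outcome analysis
dichotomizes Class I vs II–IV and silently drops subjects with no
recorded class.

## The synthetic cohort generator

The generator emulates the statistical structure the mapping assumes,
not glioma biology.  Per subject it draws a connected ellipsoidal blob
lesion (a thresholded anisotropic Gaussian bump; the threshold is chosen
as the k-smallest-distance level, so the voxel count is hit exactly)
with volume from a normal distribution truncated at 1 cm³.  The
pre-truncation location is calibrated so the *truncated* mean equals the
configured cohort mean (80.8 cm³ with SD 60 — typical of LGG series;
naive truncation would inflate the realized mean by ~10 cm³).  A hidden
spherical ROI (default radius 3 voxels) is the planted epileptogenic
zone, and the ordinal frequency category comes from a latent score

    latent = γ · involvement_fraction + 0.2·sex + 0.2·age_z + 0.2·vol_z + ε,
    ε ~ N(0, 1)

cut at (−0.5, 1.0, 2.0, 3.0).  With γ = 0 a subject's category is
covariate noise (≈ 69% have some seizure history, matching the high
seizure prevalence of LGG cohorts); the default γ = 6 makes full ROI
involvement a ~6-SD latent shift — a deliberately strong planted effect,
because the recovery property being validated is "the pipeline finds
what is there", not a statement about clinical effect sizes.  Ages are
uniform on 16–68 years, sex ~60% male, and the categorical covariates
(seizure type, ASM use, resection extent, pathology, lobes, Engel class)
are sampled to match realistic cohort marginals; their *joint* structure
is not modelled, and lesions are single blobs with no infiltration,
growth or cortical-anatomy constraints.  Passing tests therefore show
the machinery is correct and calibrated under the stated generative
model — they do not certify performance on real glioma masks, where
lesion correlation structure is far richer.

The default grid is 24×28×24 voxels at 4 mm (a ~1 L volume), on which a
60-subject, 1,000-permutation run takes about a second; the method is
resolution-agnostic and the grid fully configurable.

## Problem sizes in the test suite

The calibration check uses 200 null cohorts (γ = 0, n = 40, 200
permutations each) and asserts the mean voxel-wise retention rate lies
in the 95% binomial band around α computed at 200 replicates; the
recovery check uses 20 cohorts at the generator defaults (n = 60, 1,000
permutations) and requires the top-cluster peak inside the ROI in ≥ 90%
of them; the exhaustive-enumeration check uses n = 6 subjects where all
720 score permutations can be enumerated by an independent
normal-equations oracle.  These sizes keep the full suite under a
minute while leaving each check statistically meaningful.

## Known limitations

- Linear-probability OLS on a binary response has heteroscedastic
  errors; the t-statistic is the field's convention here, not an
  efficient estimator.
- Voxel-wise permutation thresholds do not control familywise error;
  use `max_stat` mode when a corrected map is needed.
- Registration is out of scope: masks must arrive on (or be
  nearest-neighbour resampled to) the template grid; no deformable
  alignment is provided.
- The involvement dichotomy hinges on a single peak voxel; peak location
  is stable in the synthetic tests but can be fragile on real data with
  plateaued t-maps.
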