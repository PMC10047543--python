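# Methods

This note records the models, defaults and design decisions behind the
package, and what the synthetic benchmark can and cannot establish.

## Scoring model

Submissions are complete real-valued prediction sets over a test
partition (missing values are an error, never imputed at scoring time).
Per subject *k* the MSE_k is computed over that subject's test
observations and aggregated as WMSE = Σ√n_k·MSE_k / Σ√n_k. Uncertainty
comes from a paired within-subject bootstrap: each iteration draws, for
every subject, n_k observation indices with replacement and applies the
*same* index multiset to every model, so per-iteration WMSEs are paired
and a signed-rank comparison between models is meaningful. The p-value
of a submission versus the Null baseline is the fraction of iterations
in which the Null scores strictly lower, with exact ties counted as ½: a
submission identical to the Null thus gets p = 0.5, where a strict rule
would give the pathological 0. (The strict rule is available via
`ties="strict"`.) Distinguishability of two submissions uses the
one-sided Wilcoxon signed-rank test on the paired bootstrap scores;
zero differences are dropped, and all-zero differences return p = 1 by
convention. Leaderboard ties in WMSE break lexicographically by
submission id.

## Severity models

The **Null model** predicts each subject's training-label mean and
refuses unseen subjects (a global fallback would silently change the
benchmark). The **per-subject archetype** fits one random-forest
regressor per subject-symptom on 30-second-window features, tunes
hyperparameters by random search (default 25 draws over trees 100–500,
depth {3, 5, 10, ∞}, min leaf 1–20) under grouped 5-fold CV in which all
windows of one observation stay in one fold, refits on all training
windows, and predicts an observation as the **median** of its window
predictions. The **global archetype** fits one forest per cohort on
window features plus subject covariates (age, gender, MDS-UPDRS I/II
totals, Part IV items, Part III on/off item sums and the first principal
component of the Part III items) and aggregates windows by the **mean**.
Observation predictions are clipped to the symptom's harmonized label
range — clipping can only reduce squared error. Multi-device
observations are predicted per device and averaged. An observation whose
windows were all dropped falls back to the subject's Null prediction so
prediction sets stay complete. Subjects with a single training label
value get a constant model.

## Data preparation rules

Harmonization maps the second cohort's native scales onto the common
ones: tremor 1–5 minus one; the four-category medication diary to
(on_off, dyskinesia) = OFF→(1, 0), ON without dyskinesia→(0, 0), ON with
non-troublesome dyskinesia→(0, 1), ON with severe dyskinesia→(0, 3).
The coding 0 = ON, 1 = OFF keeps "larger = worse" across all three
symptoms; dyskinesia level 2 is unused by construction. First-cohort
records pass through unchanged (their diary is natively 0–4 for all
three symptoms, so its dyskinesia scale remains 0–4). Harmonization is
idempotent: already-harmonized records are recognised structurally (a
numeric medication field) and validated rather than re-transformed.

Activity, which the segment filter needs, is defined as the presence of
at least one sample in a 1-second epoch; segments with fewer than 120
active seconds (boundary inclusive) are removed. A motion-based
criterion (epoch vector-magnitude SD > 0.01 g) is available behind a
flag. Subject eligibility per symptom: ≥40 non-missing observations and
(≥2 label categories with ≥10 observations or ≥3 categories with ≥5).
The train/test split is drawn once and shared across symptoms,
stratified within subject on the joint label tuple (missing values form
their own stratum); the per-subject test count is round(0.25·n) with
half rounding up, apportioned to strata by largest remainder, and
singleton strata go to train. Timestamps are 0-based float seconds and
windows are half-open `[a, b)` throughout.

## Feature extraction

"RMS combination" of the axes is the per-sample Euclidean norm
√(x²+y²+z²) — the standard accelerometry vector magnitude, not divided
by 3. Windows are 30 s, non-overlapping; windows holding under 50% of
the expected samples are dropped. Time-domain features use the raw
samples; spectral features are computed on a uniform grid obtained by
linear interpolation (sampling gaps from missing data would otherwise
bias the FFT), with the periodogram computed directly from the rFFT.
The generic set is a documented ~35-feature family (quantiles, moments,
peak count with support 1 — a sample strictly greater than both
neighbours —, zero crossings, FFT DC coefficient real/absolute value,
band powers 0.5–3 / 3–7 / 7–12 Hz, normalized spectral entropy with the
DC bin excluded, dominant frequency 0.3–15 Hz); an exhaustive
generic-library replication is deliberately out of scope since model
interpretation rests on the named features. The actigraphy set is
exactly 16 triaxial features; counts-per-minute is defined as the
integral of |VM − 1 g| over the window scaled to a per-minute rate (the
conventional counts algorithm is proprietary), and zero-variance axes
yield correlation 0 by convention. Constant windows have zero peaks and
zero spectral entropy (a relative 1e-10 threshold absorbs rFFT residue).

## Synthetic cohorts

Each segment is gravity (≈1 g with a slow random-walk orientation
drift), band-limited 0.5–8 Hz Gaussian voluntary motion, a tremor
sinusoid, 1–3 Hz dyskinetic noise, and white sensor noise, thinned by a
missingness rate. Defaults (units g unless noted):

| parameter | default | rationale |
|---|---|---|
| sampling_rate | 50 Hz | typical consumer smartwatch |
| segment_duration | 1200 s | one 20-minute segment per diary report |
| tremor_coupling κ_T | 0.05 /unit | places tremor well above the motion floor |
| dyskinesia_coupling κ_D | 0.005 /unit | keeps dyskinetic power near the voluntary-motion floor (see below) |
| onoff_attenuation γ | 0.5 | ON-state tremor suppression; makes medication state sensor-visible |
| baseline_motion_sd σ_b | 0.02 | free-living motion order of magnitude |
| activity_variability | 0.5 (log-sd) | per-segment log-normal scale on σ_b |
| sensor_noise_sd σ_n | 0.005 | MEMS noise floor order of magnitude |
| missingness_rate | 0.02 | transmission dropouts |

Two modelling choices deserve emphasis. First, the tremor direction is
drawn with a guaranteed vertical component (|u_z| ≥ 0.5): wrist tremor
rotates the watch and therefore oscillates the projection of gravity
onto the sensor axes, and without that component a horizontal sinusoid
enters the vector magnitude only at second order (frequency doubled,
outside 3–7 Hz). Second, the per-segment activity scale is what makes
dyskinesia the hardest symptom, as it is in practice: dyskinetic
movement is gross motion sharing the 1–3 Hz band with ordinary voluntary
activity, so when the voluntary background varies segment to segment the
dyskinesia band power is confounded with it, whereas the narrowband
tremor peak remains detectable above any broadband background. Labels
are round(θ_s + N(0, label_sd)) clipped to the native range; medication
state alternates in 4-hour ON/OFF cycles with a per-subject phase;
reporting lags are exponential; report slots are ≥30 minutes apart.
UPDRS covariates are noisy integer items whose means increase with the
subject's latent severities, so covariates genuinely carry
between-subject signal. Everything is deterministic given the spec and
seed (per-subject substreams via `SeedSequence.spawn`).

What the generator does **not** emulate: gait and activity-type
structure (no walking bouts, no circadian rhythm), gyroscope channels,
label reporting biases (lags are recorded but do not corrupt labels),
and realistic tremor amplitude distributions — the magnitudes are
order-of-magnitude choices, config-exposed. Consequently a passing
benchmark shows the pipeline's statistics and machine learning behave
correctly on data with this coupling structure; it does not certify
performance on real patients.

## Ensembles

Training observations are split into six within-subject stratified
folds; five form the inner CV that generates out-of-fold base
predictions and tunes ensemble parameters, and the sixth (evaluation)
fold is used only to select one unsupervised (mean/median) and one
supervised winner before a final refit. Base models inside this package
are five heterogeneous configurations of the severity archetypes
(per-subject RF, global RF with covariates, global gradient-boosted
trees, the Null, and Null plus seeded noise), standing in for
independently developed models.

Meta-features at selection and test time are the **across-fold means**
of the same fold models that produced the out-of-fold training matrix.
Using a single all-data model instead creates a distribution shift
between the meta-learner's training inputs (bases trained on k−1 folds)
and its inputs at test time (bases trained on everything); measured on
this benchmark the shift degraded tree-based meta-learners by ≈0.05
WMSE while leaving linear blends untouched. Fold-averaging, the
standard stacking practice, removes the mismatch by construction.

Stacking fits five meta-learner families (unregularized linear, L1
linear, L2 linear, random forest, gradient-boosted trees) on raw,
z-scored or per-subject-transformed base predictions; each family's
regularization parameter (L1/L2 strength; minimum leaf size for the
tree families, their effective regularizer on a 5-column input) is
selected by inner CV. Per-subject meta-models require ≥10 rows and a
non-singular design, otherwise the pooled model is used. CES starts
from the best single base by WMSE and greedily adds (with replacement)
whichever base most improves the running mean, stopping when nothing
strictly improves (cap 50 additions), without bagged initialization.
The systematic-search family enumerates all non-empty base subsets
(bounded at 12 bases), fits an L2 combination per subset on an 80%
within-subject learn split, scores on the held-out 20%, and refits the
winner; with few bases its optimum typically collapses onto a ridge
blend of the full base set, which is exactly the behaviour the search
is meant to reproduce, and it *is* the brute force, so no separate
verification oracle exists for it beyond re-enumeration.

## Post-hoc analyses

Lift_model = MSE_Null − MSE_model per subject; its variability comes
from 100 paired within-subject bootstrap resamples, and a subject's
lift is called significant when the bootstrap 2.5th percentile exceeds
zero (the interval rule is a package choice; no formal rule is
standard). Covariate associations use Kendall's τ-b (lift and UPDRS
covariates tie frequently), converted to Pearson's r by Greiner's
relation r = sin(πτ/2) and pooled across models by a fixed-effect
meta-analysis on the Fisher-z scale with weights n−3 (the n entering
each correlation); |r| = 1 is rejected with guidance to shrink by ε,
and correlations with n < 4 are excluded from pooling. Clinical
validation compares model predictions on short (~30 s, single-window)
clinician-rated task segments with the expert ratings by within-subject
Pearson correlation — a correlation, not an MSE, because patients' and
clinicians' severity scales may be shifted — with one-sided p-values
(H_A: r > 0) combined across subjects by Fisher's method,
X² = −2Σln p on 2m df. In the staged pipeline the clinician rating for
tremor/dyskinesia is the harmonized severity that generated the
segment, and for on/off it is the rounded effective tremor intensity
(an overall-severity surrogate, since medication state is not directly
observable in a 30-second task).

## Pipeline determinism and problem sizes

One global seed fans out to stage seeds via
`SeedSequence([seed, stage_index])`; every stage writes a manifest of
SHA-256 input/output hashes, reruns skip current stages, a re-executed
stage forces everything downstream to re-execute, and changed upstream
artifacts are refused with an explanation. Reports contain no
timestamps or absolute paths, so two runs under one config are
byte-identical.

The shipped test and acceptance studies use 120-second segments at
50 Hz, cohorts of 8–10 subjects with 60–80 reports each, bootstrap
sizes B = 250–1000, and random-search budgets of 1–2 draws — sizes
chosen so the full study re-runs in minutes on one CPU while leaving
every statistical mechanism (stratification, grouped CV, paired
bootstraps, nested ensemble selection) exercised at full fidelity.
Expect noisier estimates than a full-scale study; the type-I-control
check in the acceptance suite quantifies exactly this at 40 replicates.

## Known limitations

Per-subject random search is the only hyperparameter strategy; no
deep-learning archetype ships (the model interface accepts one). The
eval-fold selection among ~19 ensemble candidates rests on a single
small fold and is therefore noisy at desk scale — the winner can be a
few hundredths of WMSE off the best candidate in truth. The REAL-style
cohort simulates a second accelerometer stream but no gyroscope, and
gender/race covariates carry no signal. Leaderboard p-values are
nominal and unadjusted, as in the benchmarking design the package
implements.
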