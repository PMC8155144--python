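# Methods

## The analysis

The pipeline models a four-arm acute-stress magnetic resonance spectroscopy
(MRS) study. Each participant contributes a pre-stress and a post-stress
scan of medial-prefrontal metabolites expressed as ratios to total
creatine (Glu/Cr, Glx/Cr, Cho/Cr). The primary quantity is the percent
change

    %Δ = 100 · (post − pre) / pre,

computed identically for all three metabolites (one parameterized code
path). Three arms receive an acute laboratory stressor (two healthy-control
samples and one MDD sample); the fourth is a matched no-stress control.

In stressed healthy controls, %ΔGlu falls linearly with recent perceived
stress (PSS, 0–40). The line fitted by ordinary least squares on the
designated *calibration* arm only — raw PSS, no centering, so the intercept
is the expected change at PSS = 0 — defines the expected change for any
other subject, and the **maladaptive glutamate response** is the
out-of-sample residual

    MGR = %ΔGlu_observed − %ΔGlu_expected.

Positive MGR means glutamate rose more than a healthy calibration predicts
at that subject's stress level. The fit never touches the scored subjects;
the pipeline enforces this structurally by naming the calibration group in
its configuration.

## Quality control

Scans fail QC iff SNR < 9, FWHM > 0.15 ppm, or glutamate CRLB > 20% —
strict inequalities, so boundary values are retained (configurable). A
participant is excluded if either session fails or is missing. After QC,
participants whose %ΔGlu lies more than 3 sample standard deviations from
the pooled mean are excluded study-wide (sample SD with n−1; a zero-SD pool
flags nobody). Relaxing any threshold never excludes a previously included
scan. Only glutamate's CRLB is enforced; whether other metabolites' CRLBs
were screened is unknowable from the source and left out.

## Manipulation checks

Cortisol is re-expressed as percent change from the pre-stressor sample
(the baseline maps to exactly 0 and is kept as an ANOVA level); a
non-positive baseline makes the participant unscorable rather than
silently dropped. Mood (VAMS) items are bipolar 0–100 scales; items whose
positive pole sits at the high end of storage are reflected (100 − x)
before averaging into a per-timepoint negative-affect score, which makes
the score invariant to consistent polarity relabeling. The magnitude of
the cortisol response is d = mean(Δ)/SD(Δ) (change-score standardizer;
a pre-score-SD variant is available because the defining reference for
"standard mean-change" is not at hand).

## EMA scoring

Surveys arrive six per active day, two hours apart, on alternate days for
four weeks. A survey is invalid iff any rule fires: incomplete (missing
answers or never finished), beyond the sixth survey of a day, filled in
under 30 s (started→completed), completed more than 24 h after delivery
(sent→completed), or completed outside 1–3 h (inclusive) after the
previous *completed* same-day survey. The completed-survey reading of the
spacing rule matters: measuring against the previous *valid* survey would
let one missed survey invalidate the entire rest of the day, which is
inconsistent with the usable-survey yields the design reproduces. The
filter annotates rather than drops, enumerating every fired rule, so it is
idempotent by construction. Unparseable timestamps are flagged
(`bad_timestamp`), never silently removed.

Each valid survey after the first valid survey of its day whose planned
activity happened contributes a matched pair: its reported outcome against
the expectation recorded at the immediately preceding valid survey
(invalid surveys are transparent to pairing). The prediction error
δ = outcome − expectation is classified pessimistic (δ > 0), accurate
(δ = 0; exact zero on the integer grid), or optimistic (δ < 0). Summary
denominators differ by variable: expectations and affect average over all
valid surveys, experienced outcome and inaccuracy (mean |δ|) over matched
pairs, directional means over their class only — and are *absent*, not
zero, when a class is empty. Participants need ≥ 20 valid surveys
(surveys, not pairs) for inclusion.

## Statistics

* Spearman correlations (average ranks, t-approximation p) for single-sample
  associations; all tests two-tailed.
* Partial Pearson correlations by double OLS residualization on the
  covariates plus intercept, df = n − 2 − k, pairwise exclusion. An exact
  linear dependence on the covariates is an error, not a zero.
* Repeated-measures/split-plot ANOVA with Greenhouse–Geisser correction.
  ε is computed from the double-centered within-factor covariance
  (eigenvalue form; exactly 1 under compound symmetry, bounded below by
  1/(k−1)). The pipeline applies the correction whenever ε < 1
  ("always" mode, giving fractional dfs); "auto" mode (correct only when
  Mauchly rejects at 0.05) is available. Linear and quadratic trend
  contrasts come from per-subject orthonormal polynomial scores: the trend
  F tests the unweighted grand mean score against zero, and the
  trend × group F is the one-way ANOVA of scores across groups.
* Hierarchical regression: block 1 forced, block 2 candidates entered by
  probability-of-F stepwise selection (enter 0.05 / remove 0.10, the common
  default of the software family the design mirrors; configurable).
  Continuous predictors are mean-centered before interaction products.
  ΔR² F-change compares the block-1 model with the final model;
  standardized β = b·SD(x)/SD(y) over all entered design columns. The
  quadratic-PSS model is a forced (not stepwise) nested comparison of
  y ~ x versus y ~ x + x², x centered before squaring.
* Steiger's Z1* for two dependent correlations sharing a variable, with the
  pooled-correlation covariance term; exactly zero for equal correlations
  and antisymmetric under swapping them.
* Bootstrap CIs are percentile with B = 1000 case resamples (BCa is not
  claimed by the design being mirrored); resamples on which a statistic is
  undefined are redrawn and counted.
* Test–retest reliability: single-measure two-way mixed absolute-agreement
  ICC (McGraw–Wong A,1) from the mean squares, with F = MSR/MSE on
  (n−1, (n−1)(k−1)) df. Absolute agreement penalizes constant session
  offsets, unlike the consistency form.

## The synthetic generator

The generator is the package's stated world, not a tuning knob. Defaults:

| parameter | default | source/rationale |
|---|---|---|
| group sizes | 25 / 22 / 18 / 23 | study demographics table |
| PSS mean ± sd per arm | 10.12±3.70, 9.00±5.04, 12.11±5.45, 27.43±5.89 | demographics table |
| calibration line | 35.647 − 3.093·PSS (%) | published line |
| slope multiplier | 1 for stressed HC, 0 for NSC and MDD | stated group laws |
| %ΔGlu residual sd | 20% | calibrated so the stressed-HC population correlation is ≈ −0.5, matching reported effect sizes |
| baseline Glu/Cr | 1.0 ± 0.1 | placeholder scale; reference values unavailable |
| age ↔ baseline Glu/Cr | r = −0.237 (Gaussian copula) | reported association |
| cortisol rise | +25% / +10% (stress), −5%/−8% (NSC), noise sd 65% | yields d ≈ 0.4, near the reported 0.37 |
| EMA | 14 active days × 6 surveys, completion 0.844, invalid fraction 0.05 | stated protocol and completion rate |
| pessimism coupling | 0.5 | reported MGR–pessimism association |

PSS is drawn Gaussian (continuous; optional clipping to 0–40 is off by
default because clipping biases the moments the tests check). The
post-stress ratio is constructed as pre·(1 + %Δ/100), so the percent-change
equation inverts the generator exactly. The EMA coupling is a Gaussian
copula between the group-standardized generating-law maladaptive response
and a latent per-subject pessimistic-delta magnitude (mean 2.0, sd 0.8 on
the 9-point grid); the coupling parameter therefore targets the
group-adjusted correlation the analysis estimates. Corrupted surveys carry
labeled violation types (`too_fast`, `too_late`, `beyond_sixth`,
`off_schedule`) plus the validity flag the scoring filter must reproduce,
which the integration tests assert exactly.

What the generator does *not* emulate: raw spectra or scanner physics,
integer PSS responses, skewed cortisol reactivity distributions,
non-uniform EMA missingness (time-of-day or fatigue compliance patterns),
and within-day autocorrelation of affect. A green recovery test therefore
establishes that the pipeline recovers the stated generating laws under
Gaussian noise and uniform missingness — not that it would be unbiased
under every real-world violation of those assumptions.

Measured behaviour of the stated world (computed by the acceptance suite,
not asserted from outside): the recovered MGR–pessimism partial correlation
at coupling 0.5 averages ≈ 0.42 over 200 seeds — inside the ±0.15 band but
attenuated below the copula target by outcome clamping to the ±4 grid,
finite pairs per subject, and out-of-sample calibration noise.

## Numerical choices and degenerate inputs

Percent change requires a strictly positive pre value. Zero-variance
guards: identical change scores with nonzero mean make d undefined
(raised, not returned); a zero-SD outlier pool flags nobody; constant PSS
makes the calibration line unidentifiable. The generator funnels all
randomness through one seeded stream consumed in a documented fixed order,
so identical configurations are byte-identical; the EMA stream uses a
child seed derived from the same seed. Bootstrap determinism comes from an
explicit seed or generator handed to `bootstrap_ci`.

## Known limitations

The stepwise trace uses p-of-F entry on the final-model t tests, which is
the textbook rule but can differ from sum-of-squares-based F-to-enter in
borderline collinear designs. The split-plot trend contrasts assume a
balanced within-factor design. The report's bootstrap CIs are percentile
only. EMA pairing assumes the outcome question refers to the previous
valid survey; if respondents instead referenced an invalidated survey's
plan, scored prediction errors would be noisier than modeled.
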