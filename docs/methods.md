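# Methods

## Model

The package implements a literature-coefficient ("Rothman–Keller") logistic
risk model for diabetic retinopathy (DR) among type 2 diabetics. Rather than
fitting a regression to a local cohort, each coefficient is taken as the
natural log of a pooled odds ratio from published meta-analyses, and the
intercept is anchored to the local DR prevalence p via α = ln(p/(1−p)).
The working assumptions are therefore strong: the pooled ORs are treated as
mutually adjusted effects (they are not — each comes from a separate
univariate meta-analysis), factor effects combine additively on the
log-odds scale, and the local population differs from the meta-analytic
populations only through its baseline prevalence.

A patient's probability P = logit⁻¹(α + Σβᵢxᵢ) is reported as the relative
risk score LP = P/p, the patient's risk as a multiple of the average local
diabetic's.

## Coefficient sets: printed vs derived

Two coefficient sets are shipped and an element-wise reconciliation is
always available:

- **printed** (the default): the canonical published numbers, intercept
  −0.949 at p = 0.278. This is the default because the model's worked
  example is reproducible only with these exact values.
- **derived**: βᵢ = ln(ORᵢ) recomputed from the evidence table, rounded
  half-to-even to 3 decimals (the presentation precision of the source),
  and α = ln(p/(1−p)).

The reconciliation (tolerance 0.001) flags exactly two entries for the
shipped table at p = 0.278:

- **smoking**: the published coefficient −0.083 is not ln(0.68) = −0.386,
  and the stored OR 0.68 lies outside its own 95% CI (0.86–0.98). The row
  is kept as published and flagged; −0.083 would correspond to OR ≈ 0.92,
  roughly the CI's geometric mean, but the true source value is unknown
  and is not guessed. The printed set keeps −0.083 because the worked
  example's sum requires it.
- **intercept**: ln(0.278/0.722) = −0.9544, while the published value is
  −0.949 (consistent with p ≈ 27.9%). Both are retained; the printed set
  uses −0.949.

A third discrepancy is internal to the source itself: its results section
gives the myopia coefficient as −0.375 while its abstract and ln(0.70)
give −0.357. The package treats −0.357 as canonical and records the other
value as a known erratum.

## Patient encoding

Binary factors take levels present/absent; lipid-lowering drug duration is
one three-level categorical (none = baseline, <3 years, >3 years), mutually
exclusive by construction. Continuous questionnaire inputs are binarized
with configurable thresholds: FPG is "elevated" above 6.1 mmol/L (the upper
normal fasting limit) and HbA1c at or above 6.5% (the diagnostic
threshold). These defaults make the worked-example patient (FPG 6.5,
HbA1c 7%) elevated on both. Height, weight and age are carried through but
never scored — no coefficient exists for them. Diabetes duration is a
binary exposure; the source gives no duration threshold, so the caller
decides what counts as "long".

Classification conventions: under the P = 0.5 rule the boundary belongs to
"high" (high iff P ≥ 0.5, equivalently logit ≥ 0); under the LP rule the
inequality is strict (high iff LP > 2.24), following the published wording
"greater than 2.24". The 2.24 value itself is shipped as a documented
constant: it does not equal 0.5/0.278 = 1.80 and its derivation is not
given in the source, so it is not re-derived.

## Monte Carlo cutoff simulation

`cutoff_sim` draws n independent profiles (default n = 1000), factor by
factor, from configurable marginal level probabilities; scores them; sorts
the probabilities ascending; and reports the first rank at which the curve
reaches P* = 0.5, plus the LP equivalent P*/p. The source does not state
the marginals behind its own 1000 draws, so the default is uninformative —
0.5/0.5 for each binary factor, uniform over the three lipid-duration
levels — and fully configurable. All randomness flows through a seeded
numpy PCG64 generator; identical configs give bit-identical curves. The
curve is exported as CSV (`rank,probability`) with an optional matplotlib
scatter; visual parity with the source's plot is not asserted.

## Synthetic validation cohorts

The original model was validated on a 60-patient questionnaire cohort
(30 DR cases, 30 controls) that is not publicly available, and its
discrimination metrics (AUC 0.912, sensitivity/specificity 0.867) are
therefore not reproduction targets. `synthetic_cohort` provides a
stand-in: given a control exposure probability q₀ and a target OR, cases
are drawn with the tilted probability

    q₁ = OR^λ·odds₀ / (1 + OR^λ·odds₀),   odds₀ = q₀/(1−q₀),

so the case-vs-control exposure odds ratio equals OR^λ exactly in
expectation (for multi-level factors this holds for each level against
the rest, which is also how the empirical OR is tabulated). The effect
scale λ interpolates from a null cohort (λ = 0) to full published effects
(λ = 1) and beyond.

Defaults: 30 cases + 30 controls (the original validation size), control
marginals 0.3 per non-baseline level (a plausible exposure rate; the real
cohort's distributions are unreported, so no default can claim
faithfulness). Factors are independent within group — no exposure
correlation (e.g. between FPG and HbA1c) is modelled. Consequences for
interpretation: passing tests show the pipeline's internal consistency
(parameter recovery, chance-level AUC under the null, AUC growing with
λ), not the model's accuracy on real patients, where correlated exposures
and non-transportable ORs could degrade or inflate discrimination.

Empirical ORs use the 2×2 cross-product (a·d)/(b·c) with a 0.5
Haldane–Anscombe correction on all cells when any cell is zero.

## ROC machinery

`validation` implements the ROC sweep from first principles: thresholds
descend over the unique scores with ties grouped (one point per unique
score), the curve is anchored at (0,0) and (1,1), and the AUC is the
trapezoidal area. Predictions are positive at score ≥ threshold, matching
the scoring module's boundary convention. Tests cross-check the AUC
against a brute-force Mann–Whitney concordance count (ties = ½) and
against scikit-learn. Besides metrics at any fixed threshold, the
Youden-optimal point (maximizing sensitivity + specificity − 1, ties
broken toward the higher threshold) is reported, since the source does not
state how its published operating point maps onto its ROC. Confidence
intervals for the AUC (e.g. DeLong) are out of scope.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make the statistical assertions
sharp at interactive runtimes: binomial concentration and determinism at
n = 1000 (the published simulation size), marginal-shift monotonicity at
n = 10,000, null-cohort AUC at 2,000 per arm (±0.05 band), and OR recovery
at 50,000 per arm (3-standard-error bands on the log scale). The inverse
logit is computed in its numerically stable branch form and saturates
cleanly at extreme arguments. Coefficient rounding is half-to-even at 3
decimals. Scoring validates profiles strictly: any missing factor, unknown
factor or undeclared level raises an error naming all offenders.

## Known limitations

- The pooled ORs come from univariate meta-analyses; summing their logs
  assumes independence of effects that was never established.
- The LP cutoff 2.24 is adopted, not derived; its provenance is unknown.
- The smoking row of the evidence table is internally inconsistent and is
  shipped as published, flagged, with no attempt at correction.
- Synthetic cohorts cannot stand in for real-patient validation; any
  agreement with the published AUC would be coincidence, and none is
  claimed.
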