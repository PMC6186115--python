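# Methods

This note documents the rules the pipeline implements, the parameters that
matter, the design choices made where a convention had to be fixed, and what
the synthetic-data generator does and does not emulate.

## Study design

The pipeline implements a retrospective new-user cohort design on
administrative claims for hereditary angioedema (HAE), a rare disease
treated with four disease-specific medications in scope: two intravenous
plasma-derived C1-esterase-inhibitor concentrates — one labeled for routine
prophylaxis (Cinryze), one for on-demand treatment of attacks (Berinert) —
and two subcutaneous on-demand agents (icatibant, ecallantide).  Recombinant
C1-INH and subcutaneous C1-INH are out of scope, as are androgens and
tranexamic acid except as non-index-eligible background therapy.

**Index date.** The date of a patient's first fill of any of the four
HAE-specific products inside the study window.

**Overall cohort.** Requires (a) an HAE diagnosis (ICD-9-CM 277.6) on any
medical claim during the study period, (b) an index date, and (c) at least
90 days of continuous enrollment after the index date.  **HCRU cohort**
(the utilization-analysis subset): additionally 90 days of continuous
enrollment before the index and 30 days after.  Months are fixed at 30 days
(claims convention; calendar-month arithmetic is ambiguous across month
lengths).  Whether the diagnosis must precede the medication claim is not
constrained: either ordering is accepted.  Enrollment spans separated by at
most `grace_days` uncovered days (default 0) are merged before window
arithmetic.

## Treatment episodes

Intent of use is not recorded on a pharmacy claim, so episodes are defined
from refill patterns per patient and C1-INH(IV) brand:

1. **Segmentation.** Fills form a *continuous refill run* while successive
   fill dates are at most `continuity_gap_days = 45` days apart; a longer
   silence starts a new run.  Prophylactic dosing is every 3–4 days, so 45
   days decisively breaks continuity; the threshold is configurable because
   no universal convention exists.
2. **Coverage end.** A run ends at its last fill date plus that fill's
   days-supply, or plus `terminal_coverage_days = 7` when days-supply is
   missing.  This avoids zero-length spans for single fills and crediting
   no coverage to the final fill.
3. **Dose rate.** `avg_weekly_dose = total_IU × 7 / span_days` over the
   whole run span (a plain average, not a rolling window).  The labeled
   low-end prophylaxis regimen of 1000 IU every 4 days averages exactly
   1750 IU/week under this rule.
4. **Classification.** Runs spanning at least 13 weeks (91 days) are
   *prophylactic* when the average is ≥ 1500 IU/week (inclusive) and
   *on-demand* otherwise.  Runs shorter than 91 days match neither
   sustained-use pattern and are reported separately as *unclassified*;
   medication-usage tables treat them as on-demand-like use.
5. **Rescue.** Within a prophylactic episode, any fill of icatibant,
   ecallantide, or the *other* C1-INH(IV) brand is a rescue
   (breakthrough-attack) event.  Same-brand fills fold into the refill
   stream and are never rescue: same-product on-demand use cannot be
   separated from prophylaxis refills in claims data, which biases rescue
   counts downward.  SC fills outside any prophylactic episode count as
   ordinary on-demand usage, not rescue.

## Central venous access devices

Ports are identified from procedure codes.  Because published claim
analyses rarely print their CPT lists, the package ships symbolic codes
(`INSERT_PORT`, `REMOVE_PORT`, repair/replacement procedures, catheter
complication diagnoses) with a user-editable mapping table for real codes.

Insertions open a device; a removal closes the most recently opened open
device of that patient (LIFO pairing; orphan removals are logged and
ignored).  A device with no removal claim is assumed in place through the
end of the continuous-enrollment period containing the insertion — absence
of a claim is not evidence of removal, and the relatedness rules need an
end bound.

A device is **related** to intravenous HAE therapy when either: (A) it was
inserted within 91 days (13 weeks) before the index date and was still in
place 30 days after it, or (B) it was inserted during an HAE-medication use
interval (the union of refill runs of any HAE-specific product, extended by
terminal coverage) and stayed in place at least 30 days.

**Complications** are events dated within the device interval plus a
30-day grace window, in four categories: mechanical complication (diagnosis
or repair procedure), catheter replacement (partial/complete replacement
procedure), other/unspecified catheter infection, and local catheter
infection.  Patient-level "any complication" counts a patient once
regardless of event count.

## Charlson comorbidity index (Deyo adaptation)

Seventeen diagnosis categories with fixed weights
(1,1,1,1,1,1,1,1,1,1,2,2,2,2,3,6,6) are flagged from ICD-9-CM codes on
claims in the half-open window [index − 180 days, index); index-day
diagnoses are excluded because the window is "prior to" treatment start.
Codes match dot-insensitively by prefix against the shipped mapping
(`data/deyo_icd9.csv`, transcribed from the published Deyo ICD-9 list and
editable).  Hierarchy rules prevent double counting: complicated diabetes
supersedes diabetes, moderate/severe liver disease supersedes mild liver
disease, metastatic solid tumor supersedes non-metastatic malignancy.  Any
diagnosis position counts; unrecognized codes are ignored, never an error.

## Healthcare resource utilization

Counting conventions: a hospitalization is a maximal run of consecutive
inpatient claim days (claim-line granularity would inflate admissions); an
ED claim on the same day as an inpatient claim folds into the
hospitalization; office visits are distinct office-claim days.  Each
setting is counted all-cause, HAE-related (claim carries 277.6) and
CVAD-related (claim carries a CVAD procedure code); related counts are
bounded by all-cause counts by construction.

Two framings are emitted and labeled: counts within the 12-month (365-day)
post-index window truncated at enrollment end, used by the adjusted model;
and any-use flags over the whole study period, used by the crude stratified
rate table (stratified by C1-INH(IV) use and by related-CVAD use, row
percentages to 1 decimal).

## Propensity matching and relative risk

The exposure model is a multivariable logistic regression of related-CVAD
use on age, region, payer, insurance type, pharmacy benefit, initial
treatment course and Charlson score, fitted on the HCRU cohort.  *Initial
treatment course* is defined as the product class of the index-date claim
(intravenous C1-INH vs subcutaneous on-demand).  Categorical levels carried
by fewer than 5 patients are collapsed to `OTHER` before fitting; perfect
separation is flagged and the fit marked unusable.

Matching is greedy 1:1 nearest neighbor without replacement on
logit(score), exposed patients processed in a seed-randomized order over a
canonical (sorted) id list, so the pair set depends only on the seed, not
on input row order.  The caliper defaults to 0.2 standard deviations of the
logit scores, a common epidemiologic default; exposed patients with no
control inside the caliper are reported unmatched.  Optimal matching is
deliberately not claimed.

The outcome is binary: any hospitalization and/or ED visit in the 12-month
window.  Relative risk comes from a log-link Poisson GLM with HC0 sandwich
variance: the point estimate is the maximum-likelihood RR, the sandwich
variance is valid under the binary outcome's mean-variance
misspecification, and — unlike the log-binomial — the fit does not fail on
small strata.  With zero events in either arm the MLE diverges, so the
estimate falls back to the 2×2 table with a 0.5 continuity correction
(Katz log method) and is flagged unstable.  Both a matched-set estimate and
a full-cohort covariate-adjusted estimate are reported, since either
framing is defensible; the matched estimate is adjusted for the full
covariate set only when the matched sample supports it (at least ~5
outcome events per model parameter), otherwise for the continuous
covariates (age, Charlson score) alone — small matched sets cannot support
a full dummy expansion and would otherwise yield numerically absurd
estimates.  Balance is reported as standardized mean differences
(difference in means over the pooled standard deviation, with categorical
covariates expanded to level indicators) before and after matching.

## Synthetic data generator

The generator emulates the structure of a commercially insured US claims
population with HAE: demographics (71% female; ~90% aged 17–<65; regional
and payer mixes of a commercial database), enrollment spans with occasional
coverage gaps, an HAE-coded index encounter, prophylaxis refill streams,
attack-driven on-demand fills, acute-care encounters, port events and
baseline comorbidity diagnoses.  Key defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `p_female` | 0.71 | reported HAE claims-cohort composition |
| `age_distribution` | 2.7 / 4.3 / 89.5 / 3.5 % | commercially insured age mix |
| `prophylaxis_uptake` | 0.25 | ≈ quarter of patients with ≥1 prophylactic episode |
| `mean_attack_rate` | 6 /patient-year | plausible mid-range attack frequency; not identifiable from published summaries |
| `attack_rate_shape` | 0.8 | attack frequency is strongly overdispersed across patients (gamma mixture) |
| `p_attack_ed`, `p_attack_hosp` | 0.08, 0.02 | yield study-period any-ED ≈ 50% and any-hospitalization ≈ 20% at the default attack rate |
| `cvad_prevalence` | 0.054 | port prevalence among intravenous C1-INH users |
| `complication_rate` | 0.556 | per-port probability of ≥1 major complication |
| `comorbidity_rates` | see `DEFAULT_COMORBIDITY_RATES` | gives mean Charlson score ≈ 0.35 |

Prophylaxis users receive fill streams of 1000 IU every 4 days
(1750 IU/week) sustained ≥ 92 days — satisfying the episode rule by
construction — so the configured uptake is recoverable by running the
classifier on the output.  Identical (config, seed) produce byte-identical
datasets; every fill lies inside an enrollment span of its patient.

What the generator does **not** emulate: real ICD/CPT code dictionaries
beyond the minimal sets the rules consume; dose titration and adherence
drift; attack clustering in time; seasonal or calendar effects; mortality
and disenrollment correlated with disease severity; costs.  Tests passing
on generated data therefore validate the *rules and their composition*,
not the clinical realism of any particular prevalence.

Separately from the sampled generator, the package ships deterministic
*engineered fixtures* (`F-COHORT`, `F-EPI`, `F-CVAD`, `F-TAB4`, `F-ALL`):
explicit per-patient claim scripts, built constructively rather than by
rejection sampling, whose pipeline outputs reproduce fixed target counts
exactly.  They exercise every rule boundary (episode thresholds, rescue
windows, relatedness patterns, complication categories, eligibility
windows) at realistic population scale.

## Numerical choices and degenerate inputs

- Thresholds are inclusive where stated (≥1500 IU/week, ≥91 days, ≥30 days
  in place); the pre-index comorbidity window is half-open.
- Same-day index fills of several products tie to the same index date; the
  initial-treatment-course covariate prefers the intravenous class when
  both appear on the index day.
- Empty datasets yield empty cohorts with a warning, not an error; a run of
  zero span, a negative fill quantity, or a reversed enrollment span is a
  data error.
- Matching ties (equal distances) break on the control id string, keeping
  results order-independent.
- Episode summaries with no prophylactic episodes flag duration statistics
  as undefined instead of emitting NaNs silently.

## Verification problem sizes

The test suite validates the rules on: brute-force oracle comparison for
refill segmentation (random fill sets up to 15 fills against exhaustive
split enumeration), day-enumeration oracles for enrollment and dose
arithmetic, an exhaustive sweep of the comorbidity hierarchy lattice,
closed-form 2×2 checks for the propensity and risk models, and Monte-Carlo
recovery of a known relative risk (500 two-arm cohorts of 2000 patients per
arm for bias and coverage; 1000 replicates of 500 per arm for the null
test's type-I error).  Pipeline-level checks run on simulated cohorts of a
few hundred patients and on the engineered fixtures at their natural sizes
(631 / 521 / 155 / 18 patients).

## Known limitations

- Episode classification is a surrogate for clinical intent; heavy
  on-demand users can exceed the prophylaxis threshold and same-product
  rescue is invisible.
- The symbolic CVAD code set must be mapped to real CPT/ICD-9 codes before
  use on production claims.
- The Deyo mapping is ICD-9 only (the design period predates ICD-10 in US
  claims); no age-adjusted or Quan-updated variants.
- The relative-risk machinery assumes a binary outcome and two exposure
  arms; no inverse-probability weighting or multiplicity adjustment.
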