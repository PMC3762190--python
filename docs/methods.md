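# Methods

## Severity criteria

Six rules over five binary components, one point each:

| component | predicate | note |
|---|---|---|
| C | confusion present | tri-state; may be missing |
| U | urea > 7.0 mmol/L (strict) | may be missing |
| R | respiratory rate ≥ 30 /min | |
| B | systolic < 90 mmHg **or** diastolic ≤ 60 mmHg | a single point |
| 65 | age ≥ 65 years | |
| SI | heart rate / systolic BP > 1.0 (strict) | |
| ASI | adjusted shock index > 1.0 (strict) | |

CURB-65 = C+U+R+B+65 (severe ≥ 3), CRB-65 = C+R+B+65 (severe ≥ 3),
CURSI = C+U+R+SI, CURASI = C+U+R+ASI, CRSI = C+R+SI, CRASI = C+R+ASI
(each severe ≥ 2). All strict/non-strict cutoffs are pinned by tests
exactly as listed; SI = 1.0 and urea = 7.0 score zero, respiratory rate =
30 and diastolic = 60 score one.

### Adjusted shock index

ASI deducts 10 beats/min per 1.0 °C of temperature above 37.0 °C before
taking the ratio, compensating the physiological heart-rate rise under
fever. Two readings of "per 1.0 °C increase" are supported:

- `continuous` (default): deduct `10 × (T − 37.0)` for any fractional
  excess. Chosen as the assumption-minimal, smooth reading.
- `whole_degree`: deduct 10 per *completed* degree, `10 × ⌊T − 37.0⌋`.

The two differ only for fractional fevers (e.g. HR 101, SBP 100, T 37.5 °C:
ASI 0.96 vs 1.01 — a patient who flips classification between modes).
Temperature at or below 37.0 °C never adjusts the heart rate upward — the
adjustment is defined as a deduction only — so SI- and ASI-based criteria
coincide on afebrile patients (a tested invariant). The adjusted heart rate
is floored at 0 to keep the ratio defined for extreme fever with a slow
pulse.

### Missing data

Confusion and urea may be unrecorded. Rather than imputing, the scorer
brackets: `score_lower` treats every missing component as 0, `score_upper`
as 1. If both bounds land on the same side of the severity cutoff the
patient keeps that class (`allocated_despite_missing`); if the cutoff lies
strictly between the bounds, the class is indeterminate and the patient is
`excluded_borderline`, dropped from the 2×2 tables and counted in the
excluded ledger. This deterministic rule generalises the per-patient
narrative of the original evaluation (patients confirmed in their group
irrespective of absent values vs the borderline patient excluded) and
reproduces each of its dispositions.

## Diagnostic accuracy

For analysed patients, severity class vs outcome gives tp/fn/fp/tn;
sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
NPV = tn/(tn+fn). A zero denominator marks the metric *undefined* rather
than 0. `tp+fn+fp+tn+excluded = n` always.

Confidence intervals default to the Wilson score interval **with
continuity correction** (Newcombe's method 4, z = Φ⁻¹(0.975)): this is the
method that reproduces, to the printed decimal, every interval in the
published evaluation these criteria come from (e.g. 7/8 → 46.7–99.3%,
4/8 → 17.4–82.5%). Bounds are clipped to [0, 1], with exact 0/1 at s = 0 /
s = n. The closed form is verified in tests against a brute-force numerical
inversion of the continuity-corrected score test for every (s, n), n ≤ 50,
to 1e−9. Plain Wilson and Clopper–Pearson are available (`ci_method`) for
sensitivity analysis. Display rounding is one decimal, half away from zero;
published tables occasionally truncate instead, which the ±0.1 pp test
tolerance absorbs.

The published evaluation's own counts (module `capscore.study`) contain one
internal inconsistency: the CRB-65 mortality column implies 4 deaths in the
severe group (sensitivity 50.0% of 8; specificity 91.9% ⇒ tn = 80), while
the accompanying figure narrative says 3. The module follows the table
arithmetic (4), which is self-consistent across all four metrics of that
column; the discrepancy is recorded here, not resolved.

## Paired comparison

Two criteria on one cohort give paired binary classifications; sensitivity
comparisons restrict to patients with the event, specificity comparisons to
those without. The Wilcoxon signed-rank test ranks |differences| with
midranks; with ≤ 25 non-zero differences the exact two-sided p is computed
by dynamic programming over the distribution of the positive-rank sum under
all 2ⁿ sign assignments (ranks doubled to integers so midranks stay exact —
necessary here because binary differences are maximally tied and standard
exact tables do not apply). Above 25, a tie-corrected normal approximation
with continuity correction is used. Zero differences are dropped by default
(`zero_policy="drop"`); Pratt's method (zeros ranked but excluded from the
statistic) is available. All-zero differences return p = 1 with a warning
flag. The exact path is tested against full enumeration (n ≤ 10) and
against scipy's exact tables in the tie-free case.

Because a signed-rank test on per-patient binary indicators conditions on
little more than the discordant pairs, an exact McNemar test (binomial on
the discordant split) is offered alongside as the conventional analysis for
paired classifiers.

## Synthetic cohort generator

The generator emulates the 95-patient inpatient cohort the criteria were
evaluated on, so the whole pipeline runs without patient data.

Marginals (defaults = the cohort's published profile):

| variable | model | target |
|---|---|---|
| age | truncated normal, bounds 17–96, rounded to years | mean 58.8, sd 18.75 |
| sex | Bernoulli | 56.8% male |
| confusion | Bernoulli | 28.4% |
| urea | truncated log-normal, bounds (1, 30.9) | median 6.65, mean 7.9 |
| resp. rate | truncated normal, bounds 10–40, integer | mean 24.2, sd 6.46 |
| systolic BP | truncated normal, bounds 75–208 | mean 130.8, sd 27.0 |
| diastolic BP | truncated normal, bounds 40–113, resampled until < SBP | mean 72.9, sd 14.4 |
| heart rate | truncated normal, bounds 56–170 | mean 101.9, sd 19.4 |
| temperature | truncated normal, bounds 33.4–40.0 | mean 37.78, sd 1.18 |

The targets are interpreted as moments of the *truncated* distribution
(they are sample moments of a bounded cohort), so parent (μ, σ) are solved
by moment matching (`fsolve` on the truncated mean/sd; for urea, on the
truncated median/mean). Naive truncation of a normal with the target mean
would bias the age mean alone by ≈ 0.44 years — larger than the Monte-Carlo
error at the n = 10⁵ validation size. Sampling is inverse-CDF from a single
seeded `numpy` Generator threaded through all draws (no global state), so
cohorts are reproducible and the draw count per variable is fixed. Two
deliberate emulation artifacts: integer rounding (age, respiratory rate)
adds 1/12 variance and a sub-0.05 mean shift, and the dbp < sbp resampling
trims the diastolic upper tail, lowering its mean ≈ 0.6 mmHg; tests allow
for both.

Outcomes: a latent severity burden — the standardised sum of z-scored
respiratory rate, log-urea, shock index and age plus 1.5 × confusion —
drives logistic models. ICU admission uses `expit(a_icu + slope·burden)`;
death uses `expit(a_death + slope·burden + boost·ICU)` with a shared
`icu_death_boost` (default 4.0 log-odds) reproducing the strong death/ICU
overlap of the real cohort (6 of 10 ICU admissions died). Intercepts are
calibrated per cohort by root-finding so the *expected* event rates equal
the targets (death 8/95, ICU 10/95) at any slope; the implied composite
rate ≈ 12/95 matches the 11–12/95 observed. Default slope 1.0 gives a
moderate, realistic association between vitals and outcome; the association
strengthens monotonically with the slope (tested over a slope grid).

Not emulated: joint correlations among vitals (the published profile gives
only marginals; independence is the default and the only mode currently
implemented), seasonality, comorbidity, treatment effects. Passing
parameter-recovery tests therefore demonstrates correct marginal structure
and outcome calibration, not realism of joint clinical presentation.

## Validation problem sizes

Marginal recovery uses one n = 10⁵ cohort (binomial/normal 3-SE bands, with
the two documented artifact allowances); outcome calibration uses 200–300
replicate cohorts of n = 95 and single cohorts of n = 20 000 for the slope
tests. The published-table reproduction is exact arithmetic on counts and
runs in milliseconds.
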