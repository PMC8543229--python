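# Methods

## Problem and model

A dispensation register row gives person, drug (ATC code and Nordic
article number, which fixes tablet strength and package size), date,
number of packages, and a free-text dosing instruction. The quantity of
interest is the prescribed daily dosage (pills/day, and via strength,
mg/day) and the continuous treatment periods it implies. The method is a
cascade: learned text classification where the text is informative,
structured imputation where it is not, and a deterministic supply
calculus that turns resolved dispensations into periods.

### Text classifiers

Both classifiers share one architecture: trainable token embedding
(default dimension 32) over a padded id sequence (default length 40),
flattened, one rectified hidden layer (default 64 units), and either a
single sigmoid output (NLP1: probability the sig is non-informative) or a
16-way softmax (NLP2: daily-dosage class). Training uses Adam
(lr 1e-3) on cross-entropy, 10 epochs, batch 32, 10% validation split.
These hyperparameters are engineering defaults, all exposed in
`TrainConfig`. The implementation is plain numpy: with a fixed seed,
weight initialization, epoch shuffling and hence every learned weight are
bit-reproducible on CPU.

The 16 dosage classes are 0.5, 1, …, 9 pills/day plus the collapsed
intervals 10–11, 12–13, 14–15, 16–17, 18–19 and 20+. Interval classes
map to their lower bound when converted back to pills/day, consistent
with the minimum-dose reading applied to range ("1–2 tabletter") and
add-on instructions. Probability 0.5 exactly is treated as informative at
stage 1 and as confident at stage 2 (the decision rules are "> 0.5"
and "≥ 0.5" respectively); argmax ties break toward the lower class.

### Fallback cascade

Deferred texts are resolved in dispensation-date order, so earlier
resolutions feed later imputations and no step ever consults a future
dispensation. Carry-forward takes the person's most recent resolved
dosage of the same ATC strictly before the index date and within 365
days; when several qualify the most recent wins. The remainder go to a
100-tree random forest over six integer-coded features; the dispensation
sequence number is operationalized as one plus the count of same-ATC
dispensations in the trailing 183 days. The forest is fitted with
scikit-learn, but predictions are the explicit majority vote over the
per-tree outputs with ties toward the lower class, not probability
averaging. Categorical levels unseen at fit time get a dedicated
"unknown" code.

### Supply calculus

Per dispensation: expected days = dispensed pills / pills-per-day;
clamped to [1, 90] days (if clamped, the dosage is updated to
pills / clamped-days, so clamped-days x dosage always equals the
dispensed pills); extended by the adherence coefficient 7/5 (weekday
dosing with weekend omissions). Extended lengths are rounded half-up to
whole days (minimum 1) only when placed on the calendar — register dates
have day resolution.

Titrated sigs walk their segments in stated order, consuming
duration x dosage pills per segment with stated duration and the
remainder at the first segment without one; if pills run out mid-walk the
supply ends there. The adherence extension applies to the total titrated
length; segment days are scaled proportionally and apportioned to whole
days by largest remainder so strata tile the supply exactly. A titration
detected without a splittable boundary, or a non-final segment without a
stated duration, is flagged for review rather than dropped.

Joining uses a single running-end rule per person x ATC stream: a
dispensation dated on or before the current running end is stockpiled and
its whole supply appended at the running end; one dated later closes the
period. This one rule implements both the stockpiling step and the
reach-the-next-dispensation step. Accumulated stockpile is not capped.
The adherence extension is applied per dispensation, before joining.
Different ATC streams of one person are independent and may overlap
(simultaneous consumption); same-drug overlap is sequential by
construction. Periods are stratified by mg/day; adjacent strata with
equal mg/day merge. No administrative censoring happens in this module —
that is the analysis layer's concern.

### Validation metrics

Accuracy CIs come in both Wilson score and Wald (normal approximation)
forms, via statsmodels; reports label which is which. (At n = 1000 with
p̂ = 0.992 the Wald interval is 98.6–99.8%, the Wilson interval
98.4–99.6%.) The weighted g-means is defined here as one-vs-rest
g_i = sqrt(recall_i x specificity_i), prevalence-weighted, with
zero-prevalence classes dropped and weights renormalized. Overall
accuracy divides correct final dosages by prescriptions classified
informative at stage 1, counting gold-non-informative texts in that set
as errors; the all-prescription variant is reported alongside for audit.
Error bins are (0, 0.2], (0.2, 0.5], (0.5, inf) on relative error
|pred − gold| / gold, with exact predictions excluded.

### Usage patterns

Incident users: first dispensation in the analysis window with no
study-drug dispensation in the preceding 365 days, age ≥ 6 at index.
Follow-up runs to the end of the first continuous treatment episode
(discontinuation event) or the window end (censored); a later restart
does not undo the event. Age bands 6–12, 13–17, 18–29, 30–49 and 50+
are fixed at the index date. Kaplan–Meier estimation uses lifelines;
tests cross-check the product-limit closed form by hand. A person's
methylphenidate dose is the duration-weighted stratum mean of their
longest period (ties to the earliest), categorized low (≤30), medium
(31–60) or high (>60 mg/day).

## Synthetic register

The generator is the package's stand-in for restricted register data.
Defaults mirror the study conditions the pipeline is meant for: training
corpora of 8,000 sigs and validation corpora of 1,000; a class mix
skewed toward 1–3 pills/day; 6% titrated, 15% non-informative, 4% range
and 2% add-on texts; 1% returned dispensations and 1% other-indication
(narcolepsy / MS) records to exercise the filters; a four-drug ATC
catalog (methylphenidate, atomoxetine, amfetamine, dexamfetamine) with
realistic strengths and package sizes. Longitudinal histories draw
refill gaps around the extended supply length (sd 12% — some early
refills create stockpiling, some late ones small gaps) and an
age-band-dependent per-refill discontinuation hazard; non-informative
texts continue the person's true dosage trajectory, which is what makes
carry-forward learnable. Fraction and hazard values are free knobs of the
generator, chosen once as plausible for ADHD pharmacotherapy; real
sig-length and vocabulary distributions are unknown.

The surface grammar is a curated template set (quantity x frequency
phrases, dose-time sums, ranges, add-ons, "varannan dag", half-tablet
spellings ½/halv/0,5, casing/punctuation noise). An independent
regex parser (`sigdose.audit`), sharing no code with the generator,
re-derives every gold label from the text; tests require 100% agreement.
The generator also computes its own truth timelines with an independent
supply loop; with adherence 1.0 and exact refills the period engine must
reproduce them exactly.

What passing these tests shows: the pipeline recovers dosage and
timelines when texts come from the shipped grammar and supplies follow
the stated rules. What it does not show: performance on real clinical
free text, whose spelling variation, abbreviation habits and instruction
styles are far richer than any template set.

## Numerical and degenerate-input choices

- Vocabulary indices: descending corpus frequency, ties lexicographic;
  index 0 is padding, 1 is out-of-vocabulary. Over-long token sequences
  truncate from the end with a logged warning.
- The Swedish stemmer implements the Snowball algorithm (steps 1–3 with
  the R1 region). It is not a fixed point for every word (e.g.
  "läkares" -> "läkar" -> "läk" over two passes); it is one on the
  dose-bearing vocabulary, which is what the classifiers rely on.
- Duration phrases convert at dag(ar) x1, vecka/veckor x7, månad(er) x30.
- Proportion CI bounds are clipped to [0, 1] and snapped to contain the
  point estimate (guards float round-off at p̂ = 1).
- Dosage values below 1 pill/day classify as the 0.5 class; values at or
  above 20 as 20+; otherwise the greatest class lower bound not
  exceeding the value (minimum-dose convention).
- Empty inputs: empty period list writes a header-only CSV; an empty
  corpus or single-class training set raises immediately.

## Known limitations

- The indication filter inspects free text only; the register model
  carries no diagnosis codes.
- Titration-splitting syntax rules and keyword lists are configurable
  reconstructions, not a validated clinical lexicon.
- The forest trains on all texts the current run resolved confidently,
  not on a fixed external corpus.
- No cross-ATC switching episodes: continuity is per drug substance.
- Problem sizes in the test and acceptance runs (8,000/1,000 sigs,
  hundreds of synthetic persons, 1,000 simulated histories) are the
  package's chosen desk-scale defaults; national-register scale outputs
  (hundreds of thousands of prescriptions) are out of scope.
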