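# sigdose

Prescribed daily dosage from free-text prescriptions, and continuous
treatment periods from dispensation registers.

Many prescription registers (the Swedish Prescribed Drug Register among
them) record *what* was dispensed — drug, strength, package size, date —
but carry the prescribed daily dosage only inside an unstructured
free-text instruction ("1 tablett 2 gånger dagligen"). Pharmacoepidemiology
needs the dosage and the treatment duration it implies. `sigdose`
implements a complete pipeline for this problem:

1. **Preprocessing** — drop returned dispensations, exclude non-target
   indications by keyword, detect and split *titrated* instructions
   (stepwise dose changes, "1 tablett dagligen i 1 vecka, därefter 2
   tabletter") into per-interval entries, then lowercase, strip
   punctuation (keeping dose tokens like `0.5` and `1-2` intact), remove
   Swedish stopwords, stem (Snowball Swedish), tokenize and pad.
2. **Two text classifiers** — NLP1 scores p(non-informative); texts with
   p > 0.5 are deferred. NLP2 assigns one of 16 daily-dosage classes
   (0.5, 1, …, 9, 10–11, 12–13, 14–15, 16–17, 18–19, 20+ pills/day); a
   best-class probability below 0.5 defers the text as well. Both are
   small dense networks (embedding → flatten → hidden → output) trained
   with back-propagation, implemented in numpy and bit-reproducible given
   a seed.
3. **Fallback cascade** for deferred texts — first *carry-forward* (the
   person's most recent resolved dosage of the same ATC within 365 days),
   then a 100-tree random forest over six structured predictors (age,
   sex, prescriber specialty, county, Nordic article number, dispensation
   sequence number within a trailing 6-month window), majority-voted with
   ties toward the lower dosage class. After the cascade every
   dispensation has a pills/day value.
4. **Treatment periods** — expected supply days = pills / (pills/day),
   clamped to 1–90 days (dosage updated so pills are conserved), extended
   by a 7/5 non-perfect-adherence coefficient, then joined with a
   running-end rule: a refill on or before the current supply end is
   *stockpiled* (appended at the running end); a later refill opens a new
   period. Output periods are stratified by mg/day (pills/day × tablet
   strength).
5. **Validation metrics** — accuracy with Wilson and Wald 95% CIs,
   prevalence-weighted g-means `Σᵢ wᵢ √(recallᵢ · specificityᵢ)`,
   overall cascade accuracy, confusion matrices and error-size bins
   (≤20%, 20–50%, >50%).
6. **Usage patterns** — incident users via a 1-year wash-out,
   Kaplan–Meier time to treatment discontinuation by sex and age group,
   and methylphenidate dose categories (low ≤30, medium 31–60,
   high >60 mg/day).

Because register data are access-restricted, the package ships a seeded
synthetic register generator (`sigdose.synth`) that emulates Swedish-style
sigs with gold labels and longitudinal person histories with known true
timelines; an independent regex audit (`sigdose.audit`) re-derives every
gold label from the generated text.

## Worked example

```bash
sigdose run-all --seed 1 --n-persons 300 --out run
```

trains both classifiers on 8,000 synthetic sigs, applies the full cascade
to a 300-person synthetic register, builds periods and prints:

```json
{
  "nlp1_accuracy": 1.0,
  "nlp1_ci": [0.9955887965808424, 1.0],
  "nlp2_accuracy": 0.979757085020243,
  "nlp2_ci": [0.9668707652654642, 0.9876947890280963],
  "nlp1_gmeans": 1.0,
  "nlp2_gmeans": 0.9887677817664919,
  "overall_accuracy": 0.9778699861687413
}
```

NLP1 separated informative from non-informative sigs perfectly on this
register; NLP2 recovered the dosage class of 98.0% of the texts it was
confident about; and after carry-forward and the forest filled in the
rest, 97.8% of prescriptions classified informative ended with the
correct daily dosage. `sigdose audit run` shows the stage accounting —
every input record is either filtered (returned / other indication) or
resolved by exactly one source:

```json
{
  "records_in": 857,
  "removed_returned": 5,
  "excluded_indication": 3,
  "entries": 867,
  "resolved_by_source": {"nlp2": 722, "carry_forward": 97, "forest": 48},
  "resolved_total": 867
}
```

`run/periods.csv` holds one row per dose stratum (person, ATC, stratum
start/end, mg/day, pills/day); `run/summary.json` adds incident-user
counts, Kaplan–Meier strata and dose-category proportions.

A register fixture alone:

```bash
sigdose synth --n-persons 100 --seed 1 --out fixture/
```

writes `records.csv`, `gold.csv` and `truth_timelines.csv`.

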