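# Methods

## Classification model

A radiology order is represented by its billing codes, encounter setting,
and three text fields: a standardized radiology procedure name (not
editable by the ordering provider) and two clinician-editable free-text
fields, Reason for Exam and Clinical History. The classifier is a
deterministic rule cascade:

1. **Scope filter.** An order is a candidate only if its CPT codes
   intersect the in-scope chest-CT set `{71250, G0297, S8023, 71271}`
   (71250 is included because interval LDCTs for screening are billed under
   the generic chest-CT-without-contrast code), the encounter is
   outpatient, and none of the three text fields contains an imported-exam
   marker ("Exam imported from outside", "Imported study"). Failing orders
   are `excluded` with the first applicable reason (CPT, then setting, then
   import); screening status is not assessed for them.
2. **Screening-term search** over all three fields: `low dose`, `ldct`,
   `lcs`, and `scr-`. The search runs on masked, normalized text (below).
3. **Veto-term search** over the two clinician-editable fields only:
   diagnostic terms (presenting signs/symptoms of occult lung cancer) and
   Fleischner terms (nodule-surveillance language). The standardized
   procedure name is deliberately not searched for veto terms — it is a
   fixed catalogue string that cannot express a patient's symptoms.
4. **Decision.** Any veto hit → `non_screening`, regardless of screening
   language (a screening call is defined as screening terms present *and*
   veto terms absent, so the "without" clause is a hard veto; this also
   matches the observed failure mode in which providers write screening
   language on symptom-prompted orders). Otherwise any screening hit →
   `screening`. Otherwise `unable` — the only cell the cascade leaves open.

LCS-specific billing codes (G0297, S8023, 71271) affect scope only and
never auto-classify a scan as screening: quantifying the unreliability of
those codes is the point of the validation, so letting them decide the call
would be circular.

### Text normalization and matching semantics

Normalization lowercases, maps hyphens and slashes to spaces (clinical text
uses "low-dose", "low dose" and "w/o" interchangeably), collapses
whitespace, and strips; it is idempotent and preserves non-ASCII. Tokens
are maximal runs of letters/digits. A term ending in `-` matches any token
with that prefix, so `scr-` covers "screen", "screening", "scr" but never
the infixes in "describe" or "sarcoidosis". All other terms — single- or
multi-word — match literally with token boundaries at both ends; `ldct` and
`lcs` therefore match whole tokens only. Whether the original study matched
its `scr-` wildcard as token prefix or raw substring is not recoverable
from its description; token prefix is this package's documented choice, and
the whole term list is configurable per site.

Before screening terms are sought, four boilerplate exception phrases
(order-form questions and disclaimers that contain screening-like tokens,
e.g. "HCC screening.") are masked with same-length placeholder runs.
Same-length masking keeps character offsets of all other term hits valid
against the normalized original, which the audit trail (`TermHit` spans)
relies on. Phrase matching tolerates missing terminal punctuation. Masking
and normalization are both idempotent, a property the test suite checks.

The shipped diagnostic-term list (cough, hemoptysis, chest pain, weight
loss, dyspnea, shortness of breath, wheezing, hoarseness, fatigue,
pneumonia, fever, night sweats) is a documented starting set of common
presenting symptoms of occult lung cancer; real deployments are expected to
extend it iteratively as chart review surfaces new wordings, which is why
every term set is replaceable through a YAML override file. Fleischner
spelling variants default to four plausible forms ("fleischner",
"fleishner", "fleichner", "fleischer").

## Deduplication

Extracts commonly contain the same study twice. Orders sharing
(patient id, exam date, CPT code set, procedure name) collapse to the first
occurrence; every removal is logged. This is the most conservative key that
cannot merge two genuinely different same-day studies (e.g. a chest CT and
an LDCT billed under different codes).

## Validation statistics

With a screening call as "positive" and the chart-review indication as
truth: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN). Confidence intervals are exact Clopper–Pearson, computed
in the beta-quantile form that inverts the two-sided binomial test
(lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k); lower = 0 at k = 0,
upper = 1 at k = n). Exact rather than Wilson/normal intervals were chosen
because several validation denominators are small (n = 22–24), where normal
approximations under-cover. A metric with a zero denominator is reported as
flagged-undefined (NaN), never coerced to 0 or 1.

`unable` scans are handled by an explicit policy: `exclude_unable` (the
primary analysis — dropped with counts reported) or
`unable_as_nonscreening` (retained in the algorithm-non-screening row).
PPV is invariant to this choice because unable scans never enter the
screening row; NPV, sensitivity and specificity can change.

The administrative-codes baseline treats every in-scope scan as "screening
per codes"; its PPV is the gold-screening fraction. Its sensitivity,
specificity and NPV are reported as undefined: the codes produce no
negative calls, so those denominators are empty. Baseline-vs-algorithm PPV
is compared with the two-sample proportion chi-squared test with Yates
continuity correction (the R `prop.test` default), implemented as the
corrected chi-squared test on the 2×2 table; a flag disables the
correction.

Survey-weighted variants replace each cell count with the sum of sampling
weights. For the CI of a weighted proportion, the Kish effective sample
size n_eff = (Σw)²/Σw² of the denominator group feeds the same
beta-quantile interval with continuous shape parameters. With equal weights
this reduces exactly to the unweighted computation (point estimates are
ratios of sums, hence scale-invariant). This design-effect adjustment is a
documented, swappable choice; it captures weight-variance inflation but not
clustering or stratification of a full complex design.

Display rounding is whole-percent, half-up; underlying values are kept at
full precision.

## Synthetic data generator

The generator emulates a reviewed validation extract, not a health system:
each order draws a true indication from a configurable composition over
(screening, diagnostic, surveillance, uninformative), free text from small
versioned template pools whose term content matches the indication, and a
gold label **from the indication, never from the text**. Two noise channels
decouple text from truth:

* with probability ε₁ (`misleading_screening_rate`), a diagnostic order's
  text is replaced by screening-only language — the provider intended
  screening wording although symptoms prompted the order. These become the
  classifier's false positives (text with both term classes would be
  vetoed and could never produce one).
* with probability ε₂ (`misleading_symptom_rate`), a screening order gains
  an appended symptom phrase; the veto rule turns these into false
  negatives.

Under the exclude-unable policy this yields closed-form expectations
(`expected_metrics`): sensitivity = 1−ε₂ and
PPV = p_s(1−ε₂) / (p_s(1−ε₂) + p_d·ε₁), which the test suite recovers
through the full simulate → classify → validate pipeline within
Monte-Carlo error at n = 2000.

Defaults describe a ~335-order reviewed extract: composition
(0.44, 0.25, 0.09, 0.22), ε₁ = 0.15, ε₂ = 0.05, 73% of uninformative
orders truly non-screening, 10% of rows drawn as out-of-scope
(ED/inpatient, imported, or non-chest-CT code, chosen uniformly among the
three mechanisms), constant unit weights (a lognormal option exists for
weighted analyses). These were fixed once from the accounting a validation
study of this kind reports (reviewed-set size, unclassifiable fraction and
its gold composition, observed FN fraction among gold-screening scans, FP
pressure among gold-non-screening scans) and are not tuned thereafter.

What passing tests on synthetic data do **not** show: robustness to
spelling errors, negations beyond the four exception phrases, local order-
entry idioms, or any term outside the configured lists — real free text is
far messier than the template pools, and the generator makes no attempt at
linguistic realism. Synthetic results validate the plumbing and the
statistics, not the lexicon's field coverage; the lexicon must be tuned
against chart review in any new health system.

## Numerical and interface choices

* Determinism: one `numpy` generator seeded from `GeneratorConfig.seed`
  drives all draws in a fixed per-row order, so a seed fixes the dataset
  byte-for-byte; classification is pure and batch-order independent.
* Term-hit reporting: hits are returned left-to-right; when two patterns
  match the same character span only one hit is reported.
* Dates are ISO 8601 calendar dates with no timezone semantics; files are
  UTF-8 with replacement on decode errors (logged), since clinical
  extracts are frequently mis-encoded.
* Malformed input rows are collected and reported together with row
  numbers, never silently dropped; missing required columns fail fast as a
  schema error.
* Degenerate statistical inputs: `clopper_pearson` rejects n = 0 and
  k ∉ [0, n]; the proportion test rejects the same domain violations and
  propagates the underlying error for tables with an empty margin.
* Scale of the shipped analyses: printed-table reproduction is exact
  arithmetic on a few hundred counts; simulation-based checks use
  n = 2000 orders and 2000 interval-coverage replicates, sizes at which
  Monte-Carlo error is well below the asserted tolerances while the whole
  suite runs in seconds.

## Known limitations

* The classifier is a term-list method: no negation handling beyond the
  masked exception phrases, no stemming, no spell correction beyond the
  configured variant lists, no ML weighting. That is deliberate — the
  method's value is that it is auditable; every call carries the term hits
  that produced it.
* `unable` scans are ~a fifth of real extracts; both policies for them are
  implemented, but choosing one is an analysis decision the package cannot
  make for the user.
* Encounter setting and LCS eligibility are input columns; the package does
  not link encounters or compute pack-year eligibility.
* The weighted CI adjustment accounts for unequal weighting only, not full
  complex-design variance.
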