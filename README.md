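# ldctscreen

Identify lung cancer screening (LCS) low-dose CT exams among chest imaging
studies, using radiology-order billing codes **and** order free text — and
quantify how much better that does than billing codes alone.

## The problem

LCS with annual low-dose chest CT (LDCT) is indicated for asymptomatic
high-risk patients. In routine health data, screening exams are usually
ascertained from administrative CPT codes — but the same codes capture
chest CTs ordered for signs/symptoms (cough, hemoptysis, weight loss) and
for pulmonary-nodule surveillance under Fleischner guidelines. Counting
those as "screening" inflates estimated screening rates, downstream
procedure rates, and apparent harms, because symptomatic patients have a
higher pre-test probability of disease. Manual chart review fixes this but
does not scale.

`ldctscreen` implements a rule-based, auditable classifier over the three
text fields of a radiology order — the standardized procedure name and the
two clinician-editable fields (Reason for Exam, Clinical History):

1. **Scope:** keep outpatient studies with an in-scope chest-CT CPT code
   (71250, G0297, S8023, 71271); exclude ED/inpatient encounters and exams
   imported from outside facilities.
2. **Screening terms** (`low dose`, `ldct`, `lcs`, `scr-` as a token
   prefix) are sought in all three fields, after masking boilerplate
   exception phrases such as "Is this procedure to screen for malignancy?".
3. **Diagnostic terms** (signs/symptoms) and **Fleischner terms** (nodule
   surveillance) are sought in the two free-text fields.
4. A scan is called `screening` iff it has screening terms **and no**
   diagnostic or Fleischner terms (the veto rule); in-scope scans with no
   term hits at all are `unable` (to classify) and handled by an explicit
   analysis policy.

The package also provides the validation machinery (sensitivity,
specificity, PPV, NPV with exact Clopper–Pearson 95% CIs; survey-weighted
variants via Kish effective sample size; Yates-corrected two-proportion
comparison against the codes-only baseline) and a seeded synthetic order
generator with known gold labels, so the whole pipeline is testable without
clinical data.

It is intended for health-services and screening-epidemiology researchers
working with EHR radiology-order extracts.

## Worked example

Simulate a 335-order extract, classify it, and validate against the
generator's gold labels:

```bash
ldctscreen simulate --output orders.csv --seed 42 --n 335
ldctscreen classify --input orders.csv --output calls.csv
ldctscreen validate --calls calls.csv --baseline cpt
```

prints

```
contingency (exclude_unable): tp=119 fp=8 fn=13 tn=84
excluded=30 unable_dropped=81 unable_included=0 unknown_gold=0
 sensitivity: 90% (95%CI 84-95%) [119/132]
 specificity: 91% (95%CI 84-96%) [84/92]
         ppv: 94% (95%CI 88-97%) [119/127]
         npv: 87% (95%CI 78-93%) [84/97]
CPT-code baseline (all in-scope scans called screening):
         ppv: 49% (95%CI 43-54%) [148/305]
  PPV codes vs algorithm: chi2=75.618, p=3.44e-18
```

Reading this: of 335 simulated orders, 30 were out of scope (ED/inpatient,
imported, or non-chest-CT code) and 81 carried no informative text and were
dropped under the `exclude_unable` policy. Among the 224 classifiable
scans, 94% of those the algorithm called screening were truly screening
(PPV), versus 49% if every in-scope scan were taken as screening per its
billing code alone — the gap the text rules exist to close. Each command
also writes a JSON run manifest next to its output.

The same operations are available as a library:

```python
from ldctscreen import load_lexicon, classify_order, clopper_pearson

lex = load_lexicon()
# order = RadiologyOrder(...); classify_order(order, lex).call
clopper_pearson(87, 90)   # (0.9057, 0.9931)
```

The shipped term lexicon (see `src/ldctscreen/data/default_lexicon.yml`) is
fully overridable per site via `--lexicon overrides.yml`.

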