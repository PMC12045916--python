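# Default term lexicon, version 1.
# Term syntax: a trailing "-" marks a token-prefix pattern ("scr-" matches any
# token beginning with "scr": screen, screening, scr). All other terms match
# as literals bounded by token edges after normalization (lowercase, hyphens
# and slashes mapped to spaces, whitespace collapsed).
version: 1

screening_terms:
  - "low dose"
  - "ldct"
  - "lcs"
  - "scr-"

# Phrases whose occurrence masks any screening-term match inside them.
# Matched after normalization; terminal punctuation is optional.
scr_exception_phrases:
  - "Is this procedure to screen for malignancy?"
  - "This study is not intended for lung cancer screening."
  - "HCC screening."
  - "Not for initial screening."

# Common presenting signs/symptoms of occult lung cancer in the ambulatory
# setting. A configurable starting list, expected to be extended per site.
diagnostic_terms:
  - "cough"
  - "hemoptysis"
  - "chest pain"
  - "weight loss"
  - "dyspnea"
  - "shortness of breath"
  - "wheezing"
  - "hoarseness"
  - "fatigue"
  - "pneumonia"
  - "fever"
  - "night sweats"

# "Fleischner" and plausible misspellings; nodule-surveillance marker.
fleischner_terms:
  - "fleischner"
  - "fleishner"
  - "fleichner"
  - "fleischer"

imported_markers:
  - "Exam imported from outside"
  - "Imported study"

# Chest CT CPT codes in scope: 71250 (chest CT without contrast, also used
# for interval LDCTs) plus the LCS-specific codes.
in_scope_cpt:
  - "71250"
  - "G0297"
  - "S8023"
  - "71271"

lcs_specific_cpt:
  - "G0297"
  - "S8023"
  - "71271"
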