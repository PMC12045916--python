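"""Four-step classifier mapping each radiology order to
excluded / screening / non_screening / unable, with an evidence trail.

Steps, in order:

1. *Scope.* Orders whose CPT codes miss the in-scope chest-CT set, orders
   from ED or inpatient encounters, and orders marked as imported from an
   outside facility are excluded (screening status is not assessed for them).
2. *Screening terms* are sought in all three text fields — the standardized
   procedure name and the two clinician-editable fields (reason for exam,
   clinical history) — after exception-phrase masking.
3. *Diagnostic terms* (signs/symptoms) and *nodule-surveillance terms*
   (Fleischner and variants) are sought in the two clinician-editable fields.
4. Any diagnostic or surveillance hit vetoes screening: such orders are
   called non_screening regardless of screening language. Otherwise a
   screening hit yields screening. In-scope orders with no hits at all are
   unable (to classify).

LCS-specific CPT codes never auto-classify a scan as screening — billing
codes decide scope only; the text decides the call.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .lexicon import TermHit, TermLexicon, mask_exceptions, match_terms, normalize_text
from .orders import RadiologyOrder

__all__ = [
    "Call",
    "ExclusionReason",
    "ClassificationResult",
    "BatchSummary",
    "scope_filter",
    "classify_order",
    "classify_batch",
]

logger = logging.getLogger(__name__)

#: Field names whose text is searched for screening terms.
SCREENING_FIELDS = ("procedure_name", "reason_for_exam", "clinical_history")
#: Field names searched for diagnostic and surveillance terms (the two
#: clinician-editable fields only; the procedure name is standardized text
#: and never carries symptom language).
FREE_TEXT_FIELDS = ("reason_for_exam", "clinical_history")


class Call(str, Enum):
    EXCLUDED = "excluded"
    SCREENING = "screening"
    NON_SCREENING = "non_screening"
    UNABLE = "unable"


class ExclusionReason(str, Enum):
    NONE = "none"
    CPT_OUT_OF_SCOPE = "cpt_out_of_scope"
    ED_OR_INPATIENT = "ed_or_inpatient"
    IMPORTED = "imported"


@dataclass(frozen=True)
class ClassificationResult:
    """Per-order outcome with the term hits that justify it."""

    scan_id: str
    call: Call
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    screening_hits: tuple[TermHit, ...] = ()
    diagnostic_hits: tuple[TermHit, ...] = ()
    fleischner_hits: tuple[TermHit, ...] = ()

    def __post_init__(self) -> None:
        if (self.call is Call.EXCLUDED) != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValueError("call is excluded iff exclusion_reason is set")
        if self.call is Call.SCREENING:
            if not self.screening_hits or self.diagnostic_hits or self.fleischner_hits:
                raise ValueError("screening call requires screening hits and no veto hits")
        if self.call is Call.NON_SCREENING and not (self.diagnostic_hits or self.fleischner_hits):
            raise ValueError("non_screening call requires diagnostic or fleischner hits")
        if self.call is Call.UNABLE and (
            self.screening_hits or self.diagnostic_hits or self.fleischner_hits
        ):
            raise ValueError("unable call requires empty hit lists")


@dataclass
class BatchSummary:
    total: int = 0
    by_call: Counter = field(default_factory=Counter)
    by_exclusion: Counter = field(default_factory=Counter)


def scope_filter(order: RadiologyOrder, lexicon: TermLexicon) -> ExclusionReason:
    """Decide whether an order is even a candidate screening study.

    Checked in order: CPT scope, encounter setting, imported-exam markers
    (case-insensitive, in any of the three text fields).
    """
    if not (order.cpt_codes & lexicon.in_scope_cpt):
        return ExclusionReason.CPT_OUT_OF_SCOPE
    if order.setting in ("ed", "inpatient"):
        return ExclusionReason.ED_OR_INPATIENT
    for field_name in SCREENING_FIELDS:
        text = normalize_text(getattr(order, field_name))
        for marker in lexicon.imported_markers:
            if normalize_text(marker) in text:
                return ExclusionReason.IMPORTED
    return ExclusionReason.NONE


def classify_order(order: RadiologyOrder, lexicon: TermLexicon) -> ClassificationResult:
    """Classify one order per the four-step algorithm.

    Diagnostic/surveillance language vetoes screening language: the
    screening call is defined as screening terms present *and* veto terms
    absent.
    """
    reason = scope_filter(order, lexicon)
    if reason is not ExclusionReason.NONE:
        return ClassificationResult(order.scan_id, Call.EXCLUDED, reason)

    screening_hits: list[TermHit] = []
    for field_name in SCREENING_FIELDS:
        masked = mask_exceptions(normalize_text(getattr(order, field_name)), lexicon)
        screening_hits += match_terms(masked, lexicon.screening_terms, field_name)

    diagnostic_hits: list[TermHit] = []
    fleischner_hits: list[TermHit] = []
    for field_name in FREE_TEXT_FIELDS:
        text = normalize_text(getattr(order, field_name))
        diagnostic_hits += match_terms(text, lexicon.diagnostic_terms, field_name)
        fleischner_hits += match_terms(text, lexicon.fleischner_terms, field_name)

    if diagnostic_hits or fleischner_hits:
        return ClassificationResult(
            order.scan_id,
            Call.NON_SCREENING,
            screening_hits=tuple(screening_hits),
            diagnostic_hits=tuple(diagnostic_hits),
            fleischner_hits=tuple(fleischner_hits),
        )
    if screening_hits:
        return ClassificationResult(order.scan_id, Call.SCREENING, screening_hits=tuple(screening_hits))
    return ClassificationResult(order.scan_id, Call.UNABLE)


def classify_batch(
    orders: Sequence[RadiologyOrder], lexicon: TermLexicon
) -> tuple[list[ClassificationResult], BatchSummary]:
    """Classify every order (order-preserving) and tally calls and exclusion
    reasons. Expects deduplicated input."""
    results = [classify_order(o, lexicon) for o in orders]
    summary = BatchSummary(total=len(results))
    for r in results:
        summary.by_call[r.call.value] += 1
        if r.call is Call.EXCLUDED:
            summary.by_exclusion[r.exclusion_reason.value] += 1
    logger.info(
        "classified %d orders: %s (exclusions: %s)",
        summary.total,
        dict(summary.by_call),
        dict(summary.by_exclusion),
    )
    return results, summary
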