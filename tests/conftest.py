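from datetime import date

import pytest

from ldctscreen import (
    Call,
    ClassificationResult,
    ExclusionReason,
    RadiologyOrder,
    TermHit,
    load_lexicon,
)


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


def make_order(scan_id="s1", **kwargs) -> RadiologyOrder:
    defaults = dict(
        patient_id="p1",
        exam_date=date(2020, 6, 1),
        cpt_codes=frozenset({"71250"}),
        setting="outpatient",
    )
    defaults.update(kwargs)
    return RadiologyOrder(scan_id=scan_id, **defaults)


_HIT = TermHit(term="(synthetic)", field="", span=(0, 0))


def make_result(scan_id: str, call: Call | str) -> ClassificationResult:
    """A minimal ClassificationResult for a given call, with placeholder hits
    satisfying the result-type invariants."""
    call = Call(call)
    if call is Call.EXCLUDED:
        return ClassificationResult(scan_id, call, ExclusionReason.ED_OR_INPATIENT)
    if call is Call.SCREENING:
        return ClassificationResult(scan_id, call, screening_hits=(_HIT,))
    if call is Call.NON_SCREENING:
        return ClassificationResult(scan_id, call, diagnostic_hits=(_HIT,))
    return ClassificationResult(scan_id, call)


def calls_from_counts(tp, fp, fn, tn, unable_nonscreening=0, unable_screening=0):
    """Reconstruct per-scan calls and gold labels realizing a printed
    validation table (algorithm call x chart-review label)."""
    calls, gold = [], {}
    layout = [
        (tp, Call.SCREENING, "screening"),
        (fp, Call.SCREENING, "non_screening"),
        (fn, Call.NON_SCREENING, "screening"),
        (tn, Call.NON_SCREENING, "non_screening"),
        (unable_nonscreening, Call.UNABLE, "non_screening"),
        (unable_screening, Call.UNABLE, "screening"),
    ]
    i = 0
    for count, call, label in layout:
        for _ in range(count):
            sid = f"scan{i:04d}"
            calls.append(make_result(sid, call))
            gold[sid] = label
            i += 1
    return calls, gold
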