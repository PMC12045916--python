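"""Synthetic radiology-order generator with known gold labels.

Emulates the structure of outpatient chest-CT order extracts: each order has
a true indication (screening / diagnostic / nodule surveillance /
uninformative text), free text drawn from small versioned template pools per
indication, and two "misleading text" noise channels mirroring the failure
modes seen in real orders:

* ``misleading_screening_rate`` (eps1) — a truly diagnostic order whose
  provider wrote screening language only (the false-positive mechanism):
  its text is drawn from screening templates while the gold label stays
  non-screening.
* ``misleading_symptom_rate`` (eps2) — a truly screening order that also
  carries symptom language (the false-negative mechanism): a symptom phrase
  is appended, which the classifier's veto turns into a non-screening call.

Gold labels come from the generating indication, never from the generated
text, so noise genuinely decouples text from truth. Surveillance and
diagnostic indications are both gold non-screening; uninformative orders get
a gold label from an independent coin weighted toward non-screening.
Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .lexicon import TermLexicon, load_lexicon
from .orders import RadiologyOrder

__all__ = ["GeneratorConfig", "GeneratorConfigError", "generate_orders", "INDICATIONS"]

INDICATIONS = ("screening", "diagnostic", "surveillance", "uninformative")

# (procedure_name, reason_for_exam, clinical_history) pools per indication.
# Small and human-readable by design so tests are reviewable.
SCREENING_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("LDCT LUNG CANCER SCREENING", "annual lung cancer screening", "eligible for LCS, annual exam"),
    ("CT THORAX LDCT SCREENING", "low dose CT for lung cancer screening", ""),
    ("LDCT LUNG CANCER SCREENING", "annual LCS", "screening due this year"),
    ("CT CHEST WO CONTRAST", "lung ca screening, low-dose", "LDCT baseline exam"),
)

DIAGNOSTIC_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("CT CHEST WO CONTRAST", "cough x 6 weeks", "persistent cough, r/o malignancy"),
    ("CT CHEST WO CONTRAST", "hemoptysis", "new hemoptysis this week"),
    ("CT CHEST WO CONTRAST", "weight loss and fatigue", "10 lb unintentional weight loss"),
    ("CT CHEST WO CONTRAST", "chest pain", "atypical chest pain, evaluate"),
    ("CT CHEST WO CONTRAST", "shortness of breath", "worsening dyspnea on exertion"),
)

SURVEILLANCE_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("CT CHEST WO CONTRAST", "nodule follow up per Fleischner", "6 mm nodule on prior CT"),
    ("CT CHEST WO CONTRAST", "Fleischner follow-up of pulmonary nodule", ""),
    ("CT CHEST WO CONTRAST", "12 month fleishner interval CT", "stable nodule, continue interval imaging"),
)

UNINFORMATIVE_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("CT CHEST WO CONTRAST", "", ""),
    ("CT CHEST WO CONTRAST", "follow up", ""),
    ("CT CHEST WO CONTRAST", "chest ct", "ordered at clinic visit"),
    ("CT CHEST WO CONTRAST", "evaluate", "compare with prior"),
)

# Screening-language-only text written on symptom-prompted orders (eps1).
MISLEADING_SCREENING_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("CT CHEST WO CONTRAST", "lung cancer screening", ""),
    ("LDCT LUNG CANCER SCREENING", "annual screening CT", ""),
)

# Symptom phrases appended to screening orders (eps2).
SYMPTOM_TAGS: tuple[str, ...] = ("; cough", "; chest pain", "; also reports fatigue")

_TEMPLATES: Mapping[str, tuple[tuple[str, str, str], ...]] = {
    "screening": SCREENING_TEMPLATES,
    "diagnostic": DIAGNOSTIC_TEMPLATES,
    "surveillance": SURVEILLANCE_TEMPLATES,
    "uninformative": UNINFORMATIVE_TEMPLATES,
}

_DATE_START = date(2015, 8, 1)
_DATE_DAYS = (date(2021, 8, 31) - _DATE_START).days


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic order generation.

    Defaults emulate a validation extract of a few hundred reviewed
    outpatient chest CTs: ~44% true screening, ~22% orders with
    uninformative text, a ~5% rate of symptom language on true screening
    orders and a ~15% rate of screening-only language on symptom-prompted
    orders, with 73% of uninformative orders truly non-screening.
    """

    n_orders: int = 335
    composition: tuple[float, float, float, float] = (0.44, 0.25, 0.09, 0.22)
    misleading_screening_rate: float = 0.15
    misleading_symptom_rate: float = 0.05
    excluded_rate: float = 0.10
    uninformative_nonscreening_prob: float = 0.73
    weight_distribution: Mapping[str, float | str] = field(
        default_factory=lambda: {"name": "constant", "value": 1.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_orders < 1:
            raise GeneratorConfigError(f"n_orders must be >= 1, got {self.n_orders}")
        comp = tuple(self.composition)
        if len(comp) != len(INDICATIONS):
            raise GeneratorConfigError(f"composition needs {len(INDICATIONS)} proportions, got {len(comp)}")
        if any(p < 0 for p in comp) or abs(sum(comp) - 1.0) > 1e-9:
            raise GeneratorConfigError(f"composition must be non-negative and sum to 1, got {comp}")
        for name in (
            "misleading_screening_rate",
            "misleading_symptom_rate",
            "excluded_rate",
            "uninformative_nonscreening_prob",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1], got {rate}")
        dist = dict(self.weight_distribution)
        if dist.get("name") not in ("constant", "lognormal"):
            raise GeneratorConfigError(f"unknown weight_distribution {dist.get('name')!r}")


def _draw_weight(rng: np.random.Generator, dist: Mapping[str, float | str]) -> float:
    if dist.get("name") == "lognormal":
        return float(rng.lognormal(mean=float(dist.get("mean", 0.0)), sigma=float(dist.get("sigma", 0.5))))
    return float(dist.get("value", 1.0))


def _check_templates(lexicon: TermLexicon) -> None:
    """Template pools must carry exactly the term classes their indication
    promises; guards against lexicon overrides that silently break the
    generator's contract."""
    from .lexicon import mask_exceptions, match_terms, normalize_text

    def hits(texts: Sequence[str], terms) -> int:
        n = 0
        for t in texts:
            n += len(match_terms(mask_exceptions(normalize_text(t), lexicon), terms))
        return n

    for pool, want_scr, want_veto in (
        (SCREENING_TEMPLATES + MISLEADING_SCREENING_TEMPLATES, True, False),
        (DIAGNOSTIC_TEMPLATES, False, True),
        (SURVEILLANCE_TEMPLATES, False, True),
        (UNINFORMATIVE_TEMPLATES, False, False),
    ):
        for tpl in pool:
            free = tpl[1:]
            n_scr = hits(tpl, lexicon.screening_terms)
            n_veto = hits(free, lexicon.diagnostic_terms) + hits(free, lexicon.fleischner_terms)
            if want_scr and not n_scr:
                raise GeneratorConfigError(f"screening template lacks a screening term: {tpl}")
            if want_veto and not n_veto:
                raise GeneratorConfigError(f"template lacks its veto term: {tpl}")
            if not want_veto and n_veto:
                raise GeneratorConfigError(f"template unexpectedly carries a veto term: {tpl}")
            if not want_scr and not want_veto and n_scr:
                raise GeneratorConfigError(f"uninformative template carries a screening term: {tpl}")


def generate_orders(
    config: GeneratorConfig, lexicon: TermLexicon | None = None
) -> list[RadiologyOrder]:
    """Generate ``config.n_orders`` synthetic orders with gold labels.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical dataset.
    """
    config.validate()
    lexicon = lexicon or load_lexicon()
    _check_templates(lexicon)
    rng = np.random.default_rng(config.seed)
    n_patients = max(1, int(round(0.88 * config.n_orders)))
    comp = np.asarray(config.composition, dtype=float)
    comp = comp / comp.sum()

    orders: list[RadiologyOrder] = []
    for i in range(config.n_orders):
        indication = INDICATIONS[int(rng.choice(len(INDICATIONS), p=comp))]
        if indication == "screening":
            gold = "screening"
        elif indication == "uninformative":
            gold = (
                "non_screening"
                if rng.random() < config.uninformative_nonscreening_prob
                else "screening"
            )
        else:
            gold = "non_screening"

        pool = _TEMPLATES[indication]
        procedure, reason, history = pool[int(rng.integers(len(pool)))]
        if indication == "diagnostic" and rng.random() < config.misleading_screening_rate:
            mpool = MISLEADING_SCREENING_TEMPLATES
            procedure, reason, history = mpool[int(rng.integers(len(mpool)))]
        if indication == "screening" and rng.random() < config.misleading_symptom_rate:
            reason = reason + SYMPTOM_TAGS[int(rng.integers(len(SYMPTOM_TAGS)))]

        setting = "outpatient"
        cpt = frozenset({"71250"})
        if indication == "screening" and rng.random() < 0.02:
            cpt = frozenset({"G0297"})
        if rng.random() < config.excluded_rate:
            mechanism = int(rng.integers(3))
            if mechanism == 0:
                setting = "ed" if rng.random() < 0.5 else "inpatient"
            elif mechanism == 1:
                history = (history + " Exam imported from outside").strip()
            else:
                cpt = frozenset({"71260"})  # contrast chest CT: out of scope

        orders.append(
            RadiologyOrder(
                scan_id=f"S{i:06d}",
                patient_id=f"P{int(rng.integers(n_patients)):06d}",
                exam_date=_DATE_START + timedelta(days=int(rng.integers(_DATE_DAYS + 1))),
                cpt_codes=cpt,
                setting=setting,
                procedure_name=procedure,
                reason_for_exam=reason,
                clinical_history=history,
                sampling_weight=_draw_weight(rng, config.weight_distribution),
                gold_label=gold,
            )
        )
    return orders


def expected_metrics(config: GeneratorConfig) -> dict[str, float]:
    """Closed-form expected classifier accuracy on generated data under the
    exclude-unable policy, derived by enumerating template categories:
    screening orders are called screening unless symptom-tagged (rate eps2);
    diagnostic orders are called screening only when misleadingly worded
    (rate eps1); surveillance orders are always called non-screening;
    uninformative orders are unable. Used as the independent oracle for
    parameter-recovery checks."""
    ps, pd_, pv, _pu = (np.asarray(config.composition) / np.sum(config.composition)).tolist()
    e1 = config.misleading_screening_rate
    e2 = config.misleading_symptom_rate
    tp = ps * (1 - e2)
    fn = ps * e2
    fp = pd_ * e1
    tn = pd_ * (1 - e1) + pv
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }
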