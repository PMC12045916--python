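"""Term lexicon: the term sets the screening classifier matches, plus the
text-normalization, exception-masking, and term-matching semantics.

Matching model
--------------
Free text is first *normalized*: lowercased, hyphens and slashes mapped to
spaces, whitespace collapsed. Tokens are maximal runs of letters/digits.
A term ending in ``-`` (e.g. ``scr-``) matches any token with that prefix;
every other term matches literally, bounded by token edges, so ``lcs`` never
fires inside ``sarcoidosis`` and ``low dose`` also covers ``low-dose``.

Before screening terms are sought, known *exception phrases* (boilerplate
such as "Is this procedure to screen for malignancy?") are masked with a
same-length placeholder so that character offsets of hits elsewhere in the
text remain valid against the normalized original.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "TermLexicon",
    "TermHit",
    "LexiconError",
    "load_lexicon",
    "normalize_text",
    "mask_exceptions",
    "match_terms",
]

MASK_CHAR = "\x00"

_TOKEN_CHAR = r"[a-z0-9]"
_WS_RE = re.compile(r"\s+")


class LexiconError(ValueError):
    """Raised for invalid lexicon configuration (unknown keys, empty sets)."""


@dataclass(frozen=True)
class TermHit:
    """One term match: which pattern hit, in which order field, at what
    character span of the normalized field text."""

    term: str
    field: str
    span: tuple[int, int]


@dataclass(frozen=True)
class TermLexicon:
    """All term sets the classifier matches.

    ``screening_terms``, ``diagnostic_terms`` and ``fleischner_terms`` use the
    term syntax described in the module docstring. ``scr_exception_phrases``
    and ``imported_markers`` are verbatim phrases (normalization applied at
    match time). ``lcs_specific_cpt`` must be a subset of ``in_scope_cpt``.
    """

    screening_terms: frozenset[str]
    scr_exception_phrases: tuple[str, ...]
    diagnostic_terms: frozenset[str]
    fleischner_terms: frozenset[str]
    imported_markers: frozenset[str]
    in_scope_cpt: frozenset[str]
    lcs_specific_cpt: frozenset[str]
    version: int = field(default=1, compare=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "version":
                continue
            values = getattr(self, f.name)
            if f.name != "lcs_specific_cpt" and not values:
                raise LexiconError(f"lexicon field {f.name!r} must be non-empty")
            if any(not str(v) for v in values):
                raise LexiconError(f"lexicon field {f.name!r} contains an empty pattern")
        if not self.lcs_specific_cpt <= self.in_scope_cpt:
            extra = sorted(self.lcs_specific_cpt - self.in_scope_cpt)
            raise LexiconError(f"lcs_specific_cpt not a subset of in_scope_cpt: {extra}")


def _load_defaults() -> dict:
    text = resources.files("ldctscreen.data").joinpath("default_lexicon.yml").read_text("utf-8")
    return yaml.safe_load(text)


def load_lexicon(overrides: Mapping[str, Sequence[str]] | None = None) -> TermLexicon:
    """Build a :class:`TermLexicon` from the shipped defaults, with any field
    replaced wholesale by an override.

    Parameters
    ----------
    overrides
        Mapping from lexicon field name to a replacement list of strings.
        Unknown keys and overrides that empty a term set raise
        :class:`LexiconError`.
    """
    raw = _load_defaults()
    version = int(raw.pop("version", 1))
    known = {f.name for f in fields(TermLexicon)} - {"version"}
    if overrides:
        unknown = set(overrides) - known
        if unknown:
            raise LexiconError(f"unknown lexicon override key(s): {sorted(unknown)}")
        for key, value in overrides.items():
            raw[key] = list(value)
    kwargs: dict = {}
    for name in known:
        values = [str(v) for v in raw.get(name, [])]
        if name == "scr_exception_phrases":
            kwargs[name] = tuple(values)  # ordered: masked first-to-last
        else:
            kwargs[name] = frozenset(values)
    return TermLexicon(version=version, **kwargs)


def normalize_text(raw: str | None) -> str:
    """Normalize free text for matching: lowercase, map hyphens/slashes to
    spaces, collapse whitespace runs, strip. ``None`` becomes ``""``.
    Idempotent."""
    if raw is None:
        return ""
    text = str(raw).lower().replace("-", " ").replace("/", " ")
    return _WS_RE.sub(" ", text).strip()


def _phrase_pattern(phrase: str) -> re.Pattern[str] | None:
    norm = normalize_text(phrase)
    core = norm.rstrip(".?!").strip()
    if not core:
        return None
    # token boundary at the start; terminal punctuation optional
    return re.compile(rf"(?<!{_TOKEN_CHAR})" + re.escape(core) + r"[.?!]?")


def mask_exceptions(text: str, lexicon: TermLexicon) -> str:
    """Replace every occurrence of each exception phrase with a same-length
    run of a placeholder character that cannot match any term. The input must
    already be normalized. Idempotent; offsets outside masked regions are
    unchanged."""
    masked = text
    for phrase in lexicon.scr_exception_phrases:
        pat = _phrase_pattern(phrase)
        if pat is None:
            continue
        masked = pat.sub(lambda m: MASK_CHAR * (m.end() - m.start()), masked)
    return masked


def _term_pattern(term: str) -> re.Pattern[str]:
    t = normalize_text(term)
    if term.rstrip().endswith("-"):
        core = re.escape(t.rstrip("- "))
        return re.compile(rf"(?<!{_TOKEN_CHAR}){core}{_TOKEN_CHAR}*")
    return re.compile(rf"(?<!{_TOKEN_CHAR})" + re.escape(t) + rf"(?!{_TOKEN_CHAR})")


def match_terms(text: str, terms: Iterable[str], field_name: str = "") -> list[TermHit]:
    """Find every term occurrence in normalized ``text``.

    Returns hits in left-to-right order with ties broken by term string; at
    most one hit is reported per character span.
    """
    hits: list[TermHit] = []
    for term in sorted(terms):
        for m in _term_pattern(term).finditer(text):
            hits.append(TermHit(term=term, field=field_name, span=(m.start(), m.end())))
    hits.sort(key=lambda h: (h.span, h.term))
    out: list[TermHit] = []
    seen: set[tuple[int, int]] = set()
    for h in hits:
        if h.span not in seen:
            seen.add(h.span)
            out.append(h)
    return out
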