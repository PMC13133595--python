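"""Expert-rule detector: lexicon and generic-term matching in outcome texts.

The detector searches an instrument lexicon (full names and acronyms) and a
fixed list of 11 generic terms inside normalized outcome text, at word
boundaries.  Short all-alphabetic acronyms additionally require the original
surface to be upper case or to carry digits, which prevents common clinical
words rendered in lower case (e.g. "pain") from triggering acronym hits.
"""

from __future__ import annotations

import csv
import enum
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .registry_model import OutcomeDescription

_DASHES = "‐‑‒–—―−"


class MatcherConfigError(ValueError):
    """Raised when the matcher is configured with nothing to search for."""


class HitSource(str, enum.Enum):
    INSTRUMENT_NAME = "instrument_name"
    INSTRUMENT_ACRONYM = "instrument_acronym"
    GENERIC_TERM = "generic_term"


@dataclass(frozen=True)
class LexiconEntry:
    instrument_id: str
    canonical_name: str
    acronyms: tuple[str, ...]
    kind: str  # "PROM" | "PREM"
    condition_tag: str = ""


@dataclass
class InstrumentLexicon:
    entries: list[LexiconEntry]

    def __post_init__(self) -> None:
        ids = [e.instrument_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate instrument_id in lexicon")
        for e in self.entries:
            if not e.canonical_name:
                raise ValueError(f"empty canonical_name for {e.instrument_id}")
            if any(not a for a in e.acronyms):
                raise ValueError(f"empty acronym string for {e.instrument_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def surface_forms(self) -> list[tuple[str, str, HitSource]]:
        """All (surface, instrument_id, source) triples."""
        forms = []
        for e in self.entries:
            forms.append((e.canonical_name, e.instrument_id, HitSource.INSTRUMENT_NAME))
            for a in e.acronyms:
                forms.append((a, e.instrument_id, HitSource.INSTRUMENT_ACRONYM))
        return forms


#: default generic open terms (8 PROM + 3 PREM).  "QoLd" is shipped verbatim
#: as published; it is plausibly a typo for "QoL" and the alias is available
#: behind ``include_qol_alias``.
DEFAULT_PROM_TERMS = (
    "quality of life",
    "QoLd",
    "patient-reported outcome",
    "psychometric",
    "patient perspective",
    "questionnaire",
    "health related quality of life",
    "hrql",
)
DEFAULT_PREM_TERMS = ("satisfaction", "experience", "quality of care")


@dataclass
class GenericTermList:
    prom_terms: tuple[str, ...] = DEFAULT_PROM_TERMS
    prem_terms: tuple[str, ...] = DEFAULT_PREM_TERMS
    include_qol_alias: bool = False

    def all_terms(self) -> tuple[str, ...]:
        terms = self.prom_terms + self.prem_terms
        if self.include_qol_alias:
            terms = terms + ("qol",)
        return terms

    def __len__(self) -> int:
        return len(self.all_terms())


@dataclass(frozen=True)
class Hit:
    source: HitSource
    matched_text: str
    start: int
    end: int
    ref: str  # instrument_id or generic term


@dataclass
class MatchResult:
    outcome_key: tuple[str, int]
    matched: bool
    hits: list[Hit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# normalization

def normalize_text(text: str) -> tuple[str, list[int]]:
    """Fold text for matching and return an offset map to original indices.

    Applies NFKC normalization, case folding, dash unification and
    whitespace collapsing.  ``offset_map[i]`` is the index in the original
    string of the character that produced normalized position ``i``; a span
    [s, e) maps back to ``[offset_map[s], offset_map[e-1] + 1)``.
    """
    out: list[str] = []
    offsets: list[int] = []
    pending_space = False
    for i, ch in enumerate(text):
        if ch.isspace():
            pending_space = bool(out)
            continue
        folded = unicodedata.normalize("NFKC", ch).casefold()
        for sub in folded:
            if sub in _DASHES:
                sub = "-"
            if sub.isspace():
                pending_space = bool(out)
                continue
            if pending_space:
                out.append(" ")
                offsets.append(offsets[-1] + 1 if offsets else i)
                pending_space = False
            out.append(sub)
            offsets.append(i)
    return "".join(out), offsets


def _surface_pattern(surface: str) -> re.Pattern:
    """Compile a word-boundary regex for a normalized surface form.

    Internal hyphens are optional (match '-', whitespace, or nothing);
    spaces match a single collapsed space.
    """
    norm, _ = normalize_text(surface)
    parts = []
    for ch in norm:
        if ch == "-":
            parts.append(r"[-\s]?")
        elif ch == " ":
            parts.append(r"\s")
        else:
            parts.append(re.escape(ch))
    body = "".join(parts)
    return re.compile(r"(?<![a-z0-9])" + body + r"(?![a-z0-9])")


def _alpha_len(s: str) -> int:
    return sum(1 for c in s if c.isalpha())


def _acronym_case_ok(original: str) -> bool:
    # short acronym guard: original must be upper case or carry a digit
    return original.isupper() or any(c.isdigit() for c in original)


class _CompiledMatcher:
    """Compiled surface patterns for a lexicon + generic-term configuration."""

    def __init__(self, lexicon: InstrumentLexicon, terms: GenericTermList):
        if len(lexicon) == 0 and len(terms) == 0:
            raise MatcherConfigError("empty lexicon and empty generic-term list")
        self._patterns: list[tuple[re.Pattern, str, HitSource, bool]] = []
        for surface, ref, source in lexicon.surface_forms():
            guard = source is HitSource.INSTRUMENT_ACRONYM and _alpha_len(surface) <= 4
            self._patterns.append((_surface_pattern(surface), ref, source, guard))
        for term in terms.all_terms():
            self._patterns.append((_surface_pattern(term), term, HitSource.GENERIC_TERM, False))

    def find_hits(self, text: str) -> list[Hit]:
        norm, offsets = normalize_text(text)
        candidates: list[Hit] = []
        for pattern, ref, source, guard in self._patterns:
            for m in pattern.finditer(norm):
                if m.start() == m.end():
                    continue
                ostart = offsets[m.start()]
                oend = offsets[m.end() - 1] + 1
                original = text[ostart:oend]
                if guard and not _acronym_case_ok(original):
                    continue
                candidates.append(Hit(source, original, ostart, oend, ref))
        return _deduplicate(candidates)


def _deduplicate(hits: list[Hit]) -> list[Hit]:
    """Keep longest spans; instrument hits beat generic terms on overlap."""
    priority = {
        HitSource.INSTRUMENT_NAME: 0,
        HitSource.INSTRUMENT_ACRONYM: 1,
        HitSource.GENERIC_TERM: 2,
    }
    ordered = sorted(hits, key=lambda h: (-(h.end - h.start), priority[h.source], h.start, h.ref))
    kept: list[Hit] = []
    for hit in ordered:
        if any(hit.start < k.end and k.start < hit.end for k in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# public operations

def match_text(
    text: str,
    lexicon: InstrumentLexicon,
    terms: GenericTermList | None = None,
    outcome_key: tuple[str, int] = ("", 0),
) -> MatchResult:
    terms = terms if terms is not None else GenericTermList()
    matcher = _CompiledMatcher(lexicon, terms)
    hits = matcher.find_hits(text)
    return MatchResult(outcome_key=outcome_key, matched=bool(hits), hits=hits)


def match_outcome(
    outcome: OutcomeDescription,
    lexicon: InstrumentLexicon,
    terms: GenericTermList | None = None,
) -> MatchResult:
    """Run the expert rule over one outcome's combined title + description."""
    return match_text(outcome.full_text, lexicon, terms, outcome_key=outcome.key)


def flag_corpus(
    outcomes: Sequence[OutcomeDescription],
    lexicon: InstrumentLexicon,
    terms: GenericTermList | None = None,
) -> tuple[list[MatchResult], dict[str, int]]:
    """Flag every outcome; returns per-outcome results and summary counts."""
    terms = terms if terms is not None else GenericTermList()
    matcher = _CompiledMatcher(lexicon, terms)
    results = []
    for outcome in outcomes:
        hits = matcher.find_hits(outcome.full_text)
        results.append(MatchResult(outcome_key=outcome.key, matched=bool(hits), hits=hits))
    n_matched = sum(r.matched for r in results)
    return results, {"matched": n_matched, "unmatched": len(results) - n_matched}


# ---------------------------------------------------------------------------
# lexicon IO

def read_lexicon_csv(path: str | Path) -> InstrumentLexicon:
    """Read a lexicon CSV: instrument_id,canonical_name,acronyms,kind,condition_tag
    with acronyms semicolon-separated."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            acronyms = tuple(a.strip() for a in row["acronyms"].split(";") if a.strip())
            entries.append(
                LexiconEntry(
                    instrument_id=row["instrument_id"].strip(),
                    canonical_name=row["canonical_name"].strip(),
                    acronyms=acronyms,
                    kind=row["kind"].strip(),
                    condition_tag=row.get("condition_tag", "").strip(),
                )
            )
    return InstrumentLexicon(entries)


def load_default_lexicon() -> InstrumentLexicon:
    """Packaged fixture lexicon (~40 oncology instruments)."""
    return read_lexicon_csv(Path(__file__).parent / "data" / "default_lexicon.csv")


def write_matches_tsv(results: Iterable[MatchResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("study_id\toutcome_index\tmatched\tn_hits\thits\n")
        for r in results:
            hits = ";".join(
                f"{h.source.value}:{h.ref}:{h.start}-{h.end}" for h in r.hits
            )
            fh.write(
                f"{r.outcome_key[0]}\t{r.outcome_key[1]}\t"
                f"{int(r.matched)}\t{len(r.hits)}\t{hits}\n"
            )
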