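"""Instrument mention extraction and normalization.

Which instrument does an outcome name?  Spans are exchanged in the BIO
token-tagging scheme; the default extractor is rule-assisted (lexicon-seeded
span finding plus instrument-like surface heuristics); candidate mentions
separated by a short gap are merged before normalization, which maps each
mention onto the canonical lexicon by character-trigram cosine similarity.
"""

from __future__ import annotations

import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import math

from .lexicon_matcher import (
    GenericTermList,
    HitSource,
    InstrumentLexicon,
    _CompiledMatcher,
)

OutcomeKey = tuple[str, int]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")

DEFAULT_SIMILARITY_THRESHOLD = 0.85
DEFAULT_MERGE_GAP_TOKENS = 2


class NerError(ValueError):
    pass


@dataclass(frozen=True)
class EntityMention:
    outcome_key: OutcomeKey
    surface_text: str
    start: int
    end: int
    normalized_instrument_id: str | None = None
    similarity: float = 0.0


@dataclass(frozen=True)
class BioSequence:
    tokens: tuple[str, ...]
    tags: tuple[str, ...]
    token_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise NerError("tokens and tags differ in length")
        prev = "O"
        for tag in self.tags:
            if tag not in ("B", "I", "O"):
                raise NerError(f"invalid tag {tag!r}")
            if tag == "I" and prev == "O":
                raise NerError("I tag without preceding B or I")
            prev = tag


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Whitespace tokenization with punctuation split; yields (token, start, end)."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def spans_to_bio(text: str, spans: Sequence[tuple[int, int]]) -> BioSequence:
    """Tag tokens covered by each span: first token B, continuations I, rest O."""
    spans = sorted(spans)
    for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise NerError(f"overlapping spans: ({s1},{e1}) and ({s2},{_e2})")
    for s, e in spans:
        if not (0 <= s < e <= len(text)):
            raise NerError(f"span ({s},{e}) outside text of length {len(text)}")
    tokens = tokenize(text)
    tags = []
    for _tok, ts, te in tokens:
        tag = "O"
        for s, e in spans:
            if ts < e and s < te:  # token overlaps span
                # B iff this is the first token overlapping the span
                prior = [t for t in tokens if t[1] < ts and t[1] < e and s < t[2]]
                tag = "B" if not prior else "I"
                break
        tags.append(tag)
    return BioSequence(
        tokens=tuple(t for t, _, _ in tokens),
        tags=tuple(tags),
        token_spans=tuple((s, e) for _, s, e in tokens),
    )


def bio_to_spans(bio: BioSequence) -> list[tuple[int, int]]:
    """Recover character spans from a BIO sequence (inverse of spans_to_bio
    for token-aligned spans)."""
    spans = []
    start = end = None
    for (ts, te), tag in zip(bio.token_spans, bio.tags):
        if tag == "B":
            if start is not None:
                spans.append((start, end))
            start, end = ts, te
        elif tag == "I":
            end = te
        else:
            if start is not None:
                spans.append((start, end))
                start = end = None
    if start is not None:
        spans.append((start, end))
    return spans


# ---------------------------------------------------------------------------
# extraction

#: words that often terminate an instrument's full name
_INSTRUMENT_TAIL = {
    "scale", "questionnaire", "index", "inventory", "survey", "score",
    "checklist", "system", "composite", "module", "form",
}
_ACRONYM_LIKE = re.compile(r"^[A-Z][A-Z0-9]*(?:[-&][A-Z0-9]+)*$")


def rule_assisted_extractor(lexicon: InstrumentLexicon) -> Callable[[str], list[tuple[int, int]]]:
    """Default extractor: lexicon hits plus instrument-like pattern spans."""
    matcher = _CompiledMatcher(
        lexicon, GenericTermList(prom_terms=(), prem_terms=())
    ) if len(lexicon) else None

    def extract(text: str) -> list[tuple[int, int]]:
        spans: list[tuple[int, int]] = []
        if matcher is not None:
            spans.extend(
                (h.start, h.end)
                for h in matcher.find_hits(text)
                if h.source in (HitSource.INSTRUMENT_NAME, HitSource.INSTRUMENT_ACRONYM)
            )
        # heuristic: capitalized run ending in an instrument-ish tail word,
        # or an all-caps acronym-like token carrying a digit or hyphen
        tokens = tokenize(text)
        for i, (tok, ts, te) in enumerate(tokens):
            if len(tok) >= 3 and _ACRONYM_LIKE.match(tok) and any(
                c.isdigit() or c == "-" for c in tok
            ):
                spans.append((ts, te))
            if tok[:1].isupper() and tok.lower() in _INSTRUMENT_TAIL:
                j = i
                while j > 0 and tokens[j - 1][0][:1].isupper():
                    j -= 1
                if j < i:
                    spans.append((tokens[j][1], te))
        return _drop_nested(spans)

    return extract


def _drop_nested(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(set(spans), key=lambda s: (s[0], -(s[1] - s[0])))
    kept: list[tuple[int, int]] = []
    for s, e in spans:
        if kept and s < kept[-1][1]:
            if e <= kept[-1][1]:
                continue
            kept[-1] = (kept[-1][0], e)  # overlap -> widen
        else:
            kept.append((s, e))
    return kept


def merge_adjacent_spans(
    text: str, spans: Sequence[tuple[int, int]], max_gap_tokens: int = DEFAULT_MERGE_GAP_TOKENS
) -> list[tuple[int, int]]:
    """Merge candidate spans separated by at most ``max_gap_tokens`` tokens.

    Addresses fragmented multiword names (e.g. a weak extractor tagging the
    head and tail of one long instrument name separately).
    """
    if not spans:
        return []
    spans = sorted(spans)
    tokens = tokenize(text)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        gap_tokens = sum(1 for _, ts, te in tokens if merged[-1][1] <= ts and te <= s)
        if gap_tokens <= max_gap_tokens:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_mentions(
    text: str,
    extractor: Callable[[str], list[tuple[int, int]]],
    outcome_key: OutcomeKey = ("", 0),
    max_gap_tokens: int = DEFAULT_MERGE_GAP_TOKENS,
) -> list[EntityMention]:
    """Run an extractor and merge nearby candidates into unnormalized mentions."""
    spans = merge_adjacent_spans(text, extractor(text), max_gap_tokens)
    return [
        EntityMention(outcome_key=outcome_key, surface_text=text[s:e], start=s, end=e)
        for s, e in spans
    ]


# ---------------------------------------------------------------------------
# normalization

def _similarity_key(text: str) -> str:
    folded = unicodedata.normalize("NFKC", text).casefold()
    folded = re.sub(r"[‐‑‒–—―−-]", " ", folded)
    return re.sub(r"\s+", " ", folded).strip()


def _trigrams(s: str) -> Counter:
    if len(s) < 3:
        return Counter({s: 1}) if s else Counter()
    return Counter(s[i : i + 3] for i in range(len(s) - 2))


def trigram_cosine(a: str, b: str) -> float:
    """Character-trigram cosine similarity on similarity-normalized text."""
    ta, tb = _trigrams(_similarity_key(a)), _trigrams(_similarity_key(b))
    if not ta or not tb:
        return 0.0
    dot = sum(ta[g] * tb[g] for g in ta.keys() & tb.keys())
    norm = math.sqrt(sum(v * v for v in ta.values())) * math.sqrt(
        sum(v * v for v in tb.values())
    )
    return dot / norm if norm else 0.0


def normalize_mention(
    mention: EntityMention,
    lexicon: InstrumentLexicon,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> EntityMention:
    """Assign the best-matching instrument when similarity clears the threshold.

    Similarity is the maximum trigram cosine over all lexicon surface forms
    (canonical names and acronyms); ties go to the lexicographically
    smallest instrument_id.
    """
    if not 0.0 < threshold <= 1.0:
        raise NerError(f"threshold must lie in (0, 1], got {threshold}")
    if len(lexicon) == 0:
        raise NerError("cannot normalize against an empty lexicon")
    best_id: str | None = None
    best_sim = -1.0
    for surface, instrument_id, _source in lexicon.surface_forms():
        sim = trigram_cosine(mention.surface_text, surface)
        if sim > best_sim or (sim == best_sim and best_id and instrument_id < best_id):
            best_sim, best_id = sim, instrument_id
    assigned = best_id if best_sim >= threshold else None
    return EntityMention(
        outcome_key=mention.outcome_key,
        surface_text=mention.surface_text,
        start=mention.start,
        end=mention.end,
        normalized_instrument_id=assigned,
        similarity=max(best_sim, 0.0),
    )


# ---------------------------------------------------------------------------
# frequency table

def instrument_frequencies(
    mentions: Iterable[EntityMention],
    study_of: Mapping[OutcomeKey, str] | None = None,
) -> list[dict]:
    """Study-level instrument usage counts.

    An instrument counts once per study; proportions are over the set of
    studies with at least one assigned instrument.  ``study_of`` maps
    outcome keys to study ids (defaults to the key's study component).
    """
    studies_by_instrument: dict[str, set[str]] = {}
    studies_with_any: set[str] = set()
    for m in mentions:
        if m.normalized_instrument_id is None:
            continue
        study = study_of[m.outcome_key] if study_of else m.outcome_key[0]
        studies_by_instrument.setdefault(m.normalized_instrument_id, set()).add(study)
        studies_with_any.add(study)
    denom = len(studies_with_any)
    rows = [
        {
            "instrument_id": iid,
            "n_studies": len(studies),
            "proportion": len(studies) / denom if denom else 0.0,
        }
        for iid, studies in studies_by_instrument.items()
    ]
    rows.sort(key=lambda r: (-r["n_studies"], r["instrument_id"]))
    return rows


# ---------------------------------------------------------------------------
# annotation exchange

def write_annotations_jsonl(
    annotated: Iterable[tuple[str, Sequence[tuple[int, int]]]], path: str | Path
) -> None:
    """Write {text, spans:[{start,end,label}]} JSON lines."""
    with open(path, "w") as fh:
        for text, spans in annotated:
            fh.write(
                json.dumps(
                    {
                        "text": text,
                        "spans": [
                            {"start": s, "end": e, "label": "INSTRUMENT"} for s, e in spans
                        ],
                    }
                )
                + "\n"
            )


def read_annotations_jsonl(path: str | Path) -> list[tuple[str, list[tuple[int, int]]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                (obj["text"], [(s["start"], s["end"]) for s in obj.get("spans", [])])
            )
    return out


def write_frequencies_tsv(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("instrument_id\tn_studies\tproportion\n")
        for r in rows:
            fh.write(f"{r['instrument_id']}\t{r['n_studies']}\t{r['proportion']:.4f}\n")
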