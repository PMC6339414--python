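"""Lexicon-based detection of frailty findings in clinical free text.

The pipeline is deliberately rule-based and deterministic: sentence
segmentation on simple punctuation, whitespace/case normalization with an
offset map back to the source, greedy longest-match term lookup at word
boundaries, nearest-cue qualifier and course resolution within the
sentence, and cue-window negation detection.  Terms whose surface already
asserts a qualifier ("unable to run") override contextual cues.

Negation normally flips the assertion status of a finding.  For
frequency-axis concepts a preceding "no"/"denies"/"never" additionally
sets the *absent* qualifier value, because an explicitly denied deficit
("denies fatigue") is scoreable evidence of intactness for the
instrument rules, while remaining marked negated at the mention level.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .ontology import Ontology

UNQUALIFIED = "unqualified"
ASSERTED = "asserted"
NEGATED = "negated"

_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9/'\-]*")
_SENTENCE_SPLIT_RE = re.compile(r"[.;\n]")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class TermMatch:
    surface: str
    concept_id: str
    start: int  # character offsets into the ORIGINAL document, half-open
    end: int


@dataclass(frozen=True)
class Finding:
    concept_id: str
    qualifier: str = UNQUALIFIED
    course: Optional[str] = None
    assertion: str = ASSERTED
    provenance: Optional[TermMatch] = None

    def key(self) -> tuple:
        return (self.concept_id, self.qualifier, self.course, self.assertion)


@dataclass
class ExtractionConfig:
    qualifier_window: int = 5
    negation_window: int = 5
    ability_cues: dict[str, list[str]] = field(default_factory=dict)
    frequency_cues: dict[str, list[str]] = field(default_factory=dict)
    course_cues: dict[str, list[str]] = field(default_factory=dict)
    negation_cues: list[str] = field(default_factory=list)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ExtractionConfig":
        if path is None:
            path = resources.files("ccfo") / "data" / "cues.yaml"
        with open(str(path), encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            qualifier_window=int(raw.get("qualifier_window", 5)),
            negation_window=int(raw.get("negation_window", 5)),
            ability_cues={k: list(v) for k, v in raw.get("ability_cues", {}).items()},
            frequency_cues={k: list(v) for k, v in raw.get("frequency_cues", {}).items()},
            course_cues={k: list(v) for k, v in raw.get("course_cues", {}).items()},
            negation_cues=list(raw.get("negation_cues", [])),
        )

    def cue_table(self, axis: str) -> dict[str, list[str]]:
        if axis == "ability":
            return self.ability_cues
        if axis == "frequency":
            return self.frequency_cues
        return {}


def normalize(text: str) -> tuple[str, list[int]]:
    """Lowercase and collapse whitespace runs; return an offset map.

    ``offset_map[i]`` is the index in the original text of the character
    that produced normalized character ``i`` (for a collapsed whitespace
    run, the first whitespace character of the run).
    """
    out: list[str] = []
    offsets: list[int] = []
    in_ws = False
    for i, ch in enumerate(text):
        if ch.isspace():
            if not in_ws and out:
                out.append(" ")
                offsets.append(i)
            in_ws = True
        else:
            out.append(ch.lower())
            offsets.append(i)
            in_ws = False
    # trim a trailing space
    if out and out[-1] == " ":
        out.pop()
        offsets.pop()
    return "".join(out), offsets


@dataclass(frozen=True)
class _Sentence:
    norm: str
    offsets: list[int]  # normalized index -> original index
    matches: list[TermMatch]  # with normalized-local offsets
    tokens: list[tuple[str, int, int]]  # (token, start, end) in normalized text


def _lexicon_pattern(ont: Ontology) -> re.Pattern:
    surfaces = sorted(ont.terms, key=len, reverse=True)
    alts = "|".join(re.escape(s) for s in surfaces)
    # custom word boundary: surfaces may start/end on non-word chars like "w/c"
    return re.compile(rf"(?<![a-z0-9])(?:{alts})(?![a-z0-9])")


def _sentences(ont: Ontology, text: str) -> list[_Sentence]:
    pattern = _lexicon_pattern(ont) if ont.terms else None
    sents: list[_Sentence] = []
    pos = 0
    spans = []
    for m in _SENTENCE_SPLIT_RE.finditer(text):
        spans.append((pos, m.start()))
        pos = m.end()
    spans.append((pos, len(text)))
    for s, e in spans:
        raw = text[s:e]
        if not raw.strip():
            continue
        norm, local = normalize(raw)
        offsets = [s + i for i in local]
        matches: list[TermMatch] = []
        if pattern is not None:
            last_end = 0
            for m in pattern.finditer(norm):
                if m.start() < last_end:  # enforce non-overlap, leftmost-longest
                    continue
                matches.append(
                    TermMatch(m.group(0), ont.terms[m.group(0)].concept_id, m.start(), m.end())
                )
                last_end = m.end()
        tokens = [(t.group(0), t.start(), t.end()) for t in _TOKEN_RE.finditer(norm)]
        sents.append(_Sentence(norm, offsets, matches, tokens))
    return sents


def match_terms(ont: Ontology, text: str) -> list[TermMatch]:
    """Greedy longest-match lexicon lookup; offsets refer to the source text.

    Excluded ambiguous surfaces are absent from the lexicon and never match;
    matches within a document are non-overlapping and sorted by position.
    """
    out: list[TermMatch] = []
    for sent in _sentences(ont, text):
        for m in sent.matches:
            start = sent.offsets[m.start]
            end = sent.offsets[m.end - 1] + 1
            out.append(TermMatch(m.surface, m.concept_id, start, end))
    return sorted(out, key=lambda m: m.start)


def _token_index_range(sent: _Sentence, start: int, end: int) -> tuple[int, int]:
    """Indices of the first and last token overlapping [start, end)."""
    first = last = None
    for i, (_, ts, te) in enumerate(sent.tokens):
        if te > start and ts < end:
            if first is None:
                first = i
            last = i
    if first is None:  # no token overlap; anchor to nearest position
        first = last = 0
    return first, last


def _nearest_cue(
    sent: _Sentence,
    match: TermMatch,
    cue_table: dict[str, list[str]],
    window: Optional[int],
) -> Optional[str]:
    """Level of the cue nearest to the match; preceding cue wins ties."""
    cue_map: dict[tuple[str, ...], str] = {}
    for level, cues in cue_table.items():
        for cue in cues:
            cue_map[tuple(cue.split())] = level
    if not cue_map:
        return None
    mfirst, mlast = _token_index_range(sent, match.start, match.end)
    toks = [t for t, _, _ in sent.tokens]
    best: Optional[tuple[int, int, str]] = None  # (distance, tie_rank, level)
    max_len = max(len(k) for k in cue_map)
    for i in range(len(toks)):
        for n in range(max_len, 0, -1):
            gram = tuple(toks[i : i + n])
            if len(gram) < n or gram not in cue_map:
                continue
            j = i + n - 1
            if i >= mfirst and j <= mlast:
                continue  # cue inside the matched term itself
            if j < mfirst:
                dist, tie = mfirst - j, 0  # preceding cue wins distance ties
            elif i > mlast:
                dist, tie = i - mlast, 1
            else:
                continue  # straddles the match; ignore
            if window is not None and dist > window:
                continue
            cand = (dist, tie, cue_map[gram])
            if best is None or cand[:2] < best[:2]:
                best = cand
            break
    return best[2] if best else None


def resolve_qualifier(
    ont: Ontology,
    match: TermMatch,
    sentence_text: str,
    config: Optional[ExtractionConfig] = None,
) -> tuple[str, Optional[str]]:
    """(qualifier level, course level or None) for a match in its sentence.

    Standalone variant used on a single sentence string; the match offsets
    must refer to that string.
    """
    config = config or ExtractionConfig.load()
    sents = _sentences(ont, sentence_text)
    if not sents:
        return UNQUALIFIED, None
    sent = sents[0]
    local = TermMatch(
        match.surface,
        match.concept_id,
        sentence_text.lower().find(match.surface),
        sentence_text.lower().find(match.surface) + len(match.surface),
    )
    return _resolve_for(ont, sent, local, config)


def _resolve_for(
    ont: Ontology, sent: _Sentence, match: TermMatch, config: ExtractionConfig
) -> tuple[str, Optional[str]]:
    concept = ont.concepts.get(match.concept_id)
    axis = concept.axis if concept else "none"
    course = _nearest_cue(sent, match, config.course_cues, None)
    term = ont.terms.get(match.surface)
    if term is not None and term.intrinsic:
        return term.intrinsic, course
    cue_table = dict(config.cue_table(axis))
    # "absent" contrasts with every axis (an explicitly absent finding)
    if axis == "ability":
        cue_table.setdefault("absent", config.frequency_cues.get("absent", []))
    qualifier = _nearest_cue(sent, match, cue_table, config.qualifier_window)
    return (qualifier or UNQUALIFIED), course


def detect_assertion(
    match: TermMatch,
    sentence_text: str,
    config: Optional[ExtractionConfig] = None,
) -> str:
    """asserted/negated: negated iff a negation cue precedes in-window."""
    config = config or ExtractionConfig.load()
    norm, _ = normalize(sentence_text)
    tokens = [(t.group(0), t.start(), t.end()) for t in _TOKEN_RE.finditer(norm)]
    start = norm.find(match.surface.lower())
    if start < 0:
        return ASSERTED
    sent = _Sentence(norm, list(range(len(norm))), [], tokens)
    local = TermMatch(match.surface, match.concept_id, start, start + len(match.surface))
    return _assertion_for(sent, local, config)


def _assertion_for(sent: _Sentence, match: TermMatch, config: ExtractionConfig) -> str:
    mfirst, _ = _token_index_range(sent, match.start, match.end)
    cues = {tuple(c.split()) for c in config.negation_cues}
    toks = [t for t, _, _ in sent.tokens]
    for i in range(mfirst):
        for n in (2, 1):
            gram = tuple(toks[i : i + n])
            if len(gram) == n and gram in cues and i + n - 1 < mfirst:
                if mfirst - (i + n - 1) <= config.negation_window:
                    return NEGATED
    return ASSERTED


def extract_findings(
    ont: Ontology,
    document: str,
    config: Optional[ExtractionConfig] = None,
) -> list[Finding]:
    """normalize -> match -> qualify -> assert, per sentence, in order."""
    config = config or ExtractionConfig.load()
    findings: list[Finding] = []
    for sent in _sentences(ont, document):
        for m in sent.matches:
            qualifier, course = _resolve_for(ont, sent, m, config)
            assertion = _assertion_for(sent, m, config)
            concept = ont.concepts.get(m.concept_id)
            if (
                assertion == NEGATED
                and concept is not None
                and concept.axis == "frequency"
            ):
                qualifier = "absent"
            provenance = TermMatch(
                m.surface, m.concept_id, sent.offsets[m.start], sent.offsets[m.end - 1] + 1
            )
            findings.append(Finding(m.concept_id, qualifier, course, assertion, provenance))
    return findings


# -- JSONL plumbing ---------------------------------------------------------


def findings_to_jsonl(doc_id: str, findings: Iterable[Finding]) -> str:
    lines = []
    for f in findings:
        rec = {
            "doc_id": doc_id,
            "ccfo_id": f.concept_id,
            "qualifier": f.qualifier,
            "course": f.course,
            "assertion": f.assertion,
            "start": f.provenance.start if f.provenance else None,
            "end": f.provenance.end if f.provenance else None,
            "surface": f.provenance.surface if f.provenance else None,
        }
        lines.append(json.dumps(rec, sort_keys=True))
    return "".join(line + "\n" for line in lines)


def findings_from_jsonl(text: str) -> list[tuple[str, Finding]]:
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        prov = None
        if rec.get("start") is not None:
            prov = TermMatch(rec.get("surface", ""), rec["ccfo_id"], rec["start"], rec["end"])
        out.append(
            (
                rec.get("doc_id", ""),
                Finding(
                    rec["ccfo_id"],
                    rec.get("qualifier", UNQUALIFIED),
                    rec.get("course"),
                    rec.get("assertion", ASSERTED),
                    prov,
                ),
            )
        )
    return out
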