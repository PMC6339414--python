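"""Synthetic clinical-note snippets with gold-standard finding annotations.

Notes are short telegraphic sentences ("toileting: unable.", "denies
fatigue.", "fit and well daily.") built from the ontology's own term
lexicon plus qualifier/course/negation cues drawn from the extraction
cue config.  Because the grammar stays inside the extractor's cue and
term coverage, the gold annotations are exact by construction and the
extractor is expected to reproduce them with perfect precision and
recall — which is what makes the corpus useful as an end-to-end oracle.
The grammar emulates snippet-sized narrative, not real note formatting
(no headers, no section structure, no misspellings).

Distractor sentences contain only excluded ambiguous terms ("dressing
changed", "supine position") and contribute no gold findings.

All sampling is driven by a single integer seed; identical specs render
byte-identical notes.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

from .extraction import ASSERTED, Finding, NEGATED, TermMatch, UNQUALIFIED
from .ontology import Ontology, Term


class GenerationError(ValueError):
    """The note spec cannot be rendered (e.g. a concept with no terms)."""


@dataclass(frozen=True)
class PlannedFinding:
    concept_id: str
    qualifier: str = UNQUALIFIED
    course: Optional[str] = None
    negated: bool = False


@dataclass(frozen=True)
class NoteSpec:
    findings: Optional[tuple[PlannedFinding, ...]] = None
    profile: str = "mixed"  # independent | frail | mixed
    n_findings: int = 4
    negation_rate: float = 0.0
    distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.negation_rate <= 1.0):
            raise ValueError("negation_rate must lie in [0, 1]")
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise ValueError("distractor_rate must lie in [0, 1]")


@dataclass(frozen=True)
class GoldNote:
    text: str
    gold: tuple[Finding, ...]
    spec: NoteSpec


#: plans behind the named profiles; the independent plan covers every
#: Katz item so such notes score the full 6.
INDEPENDENT_PLAN = (
    PlannedFinding("112441", "able"),
    PlannedFinding("112442", "able"),
    PlannedFinding("112444", "able"),
    PlannedFinding("112445", "able"),
    PlannedFinding("1122", "able"),
    PlannedFinding("112721"),
    PlannedFinding("112722"),
)
FRAIL_PLAN = (
    PlannedFinding("112441", "unable"),
    PlannedFinding("112442", "unable"),
    PlannedFinding("112443", "unable"),
    PlannedFinding("112444", "unable"),
    PlannedFinding("112445", "unable"),
    PlannedFinding("1122", "unable"),
    PlannedFinding("112711"),
    PlannedFinding("112712"),
    PlannedFinding("1121221"),
    PlannedFinding("1124713", "unable"),
)

_TEMPLATES: dict[str, tuple[str, ...]] = {
    UNQUALIFIED: ("{term} noted", "pt with {term}", "{term} on exam"),
    "able": ("{term}: able", "independent with {term}", "able to manage {term}"),
    "with-difficulty": ("{term} with difficulty", "needs help with {term}"),
    "unable": ("{term}: unable", "unable to manage {term}"),
    "high-frequency": ("{term} daily", "reports {term} often"),
    "mid-frequency": ("{term} sometimes", "occasionally {term}"),
    "absent": ("never {term}",),
    "negated": ("denies {term}", "no {term}"),
    "intrinsic": ("{term} today", "{term} per pt"),
}
_COURSE_WORDS = {"chronic": "chronic", "short-duration": "transient", "sudden-onset": "sudden"}
_DISTRACTORS = (
    "dressing changed",
    "supine position maintained",
    "pt working with staff",
    "eating lunch at this time",
    "strength of recommendation discussed",
    "incontinence supplies ordered",
)
_FILLERS = ("vitals stable", "plan reviewed", "seen in clinic")

_SAMPLE_QUALIFIERS = {
    "ability": (UNQUALIFIED, "able", "with-difficulty", "unable"),
    "frequency": (UNQUALIFIED, "high-frequency", "mid-frequency", "absent"),
    "none": (UNQUALIFIED,),
}


def _neutral_terms(ont: Ontology, concept_id: str) -> list[Term]:
    return [t for t in ont.terms_for(concept_id) if t.intrinsic is None]


def _intrinsic_terms(ont: Ontology, concept_id: str, level: str) -> list[Term]:
    return [t for t in ont.terms_for(concept_id) if t.intrinsic == level]


def _render(
    ont: Ontology, plan: PlannedFinding, rng: random.Random
) -> tuple[str, int, str, Finding]:
    """One sentence for one planned finding.

    Returns (sentence, term char offset within sentence, surface, gold
    finding with sentence-local provenance).
    """
    concept = ont.concepts.get(plan.concept_id)
    if concept is None:
        raise GenerationError(f"unknown concept {plan.concept_id!r}")
    all_terms = ont.terms_for(plan.concept_id)
    if not all_terms:
        raise GenerationError(f"concept {concept.name!r} has no lexicon terms")

    axis = concept.axis
    course_word = _COURSE_WORDS.get(plan.course) if plan.course else None

    if plan.negated:
        pool = _neutral_terms(ont, plan.concept_id)
        if not pool:
            raise GenerationError(f"no neutral term to negate for {concept.name!r}")
        term = rng.choice(sorted(pool, key=lambda t: t.surface))
        template = rng.choice(_TEMPLATES["negated"])
        # "no"/"denies" double as absent cues on qualifier-bearing axes
        gold_quali = "absent" if axis in ("ability", "frequency") else UNQUALIFIED
        gold = Finding(plan.concept_id, gold_quali, None, NEGATED)
    else:
        qualifier = plan.qualifier
        intr = _intrinsic_terms(ont, plan.concept_id, qualifier)
        neutral = _neutral_terms(ont, plan.concept_id)
        if qualifier != UNQUALIFIED and intr and (not neutral or rng.random() < 0.5):
            term = rng.choice(sorted(intr, key=lambda t: t.surface))
            template = rng.choice(_TEMPLATES["intrinsic"])
        else:
            if not neutral:
                raise GenerationError(
                    f"no neutral term for {concept.name!r} at level {qualifier!r}"
                )
            if qualifier != UNQUALIFIED and qualifier not in _SAMPLE_QUALIFIERS.get(
                axis, ()
            ) + ("absent",):
                raise GenerationError(
                    f"qualifier {qualifier!r} not renderable for axis {axis!r}"
                )
            term = rng.choice(sorted(neutral, key=lambda t: t.surface))
            template = rng.choice(_TEMPLATES[qualifier])
        gold = Finding(plan.concept_id, qualifier, plan.course, ASSERTED)

    surface = term.surface
    rendered_term = f"{course_word} {surface}" if course_word else surface
    sentence = template.format(term=rendered_term)
    offset = sentence.index(surface)
    return sentence, offset, surface, gold


def generate_note(spec: NoteSpec, ont: Ontology) -> GoldNote:
    """Render a note for a NoteSpec; reproducible under a fixed seed."""
    rng = random.Random(spec.seed)
    plans = list(spec.findings) if spec.findings is not None else _plan_for_profile(
        spec, ont, rng
    )
    plans = [
        replace(p, negated=True, course=None)
        if (not p.negated and rng.random() < spec.negation_rate)
        else p
        for p in plans
    ]

    sentences: list[tuple[str, Optional[tuple[int, str, Finding]]]] = []
    for plan in plans:
        sentence, offset, surface, gold = _render(ont, plan, rng)
        sentences.append((sentence, (offset, surface, gold)))
    if rng.random() < spec.distractor_rate:
        pos = rng.randrange(len(sentences) + 1)
        sentences.insert(pos, (rng.choice(_DISTRACTORS), None))
    if rng.random() < 0.3:
        sentences.append((rng.choice(_FILLERS), None))

    text_parts: list[str] = []
    gold_out: list[Finding] = []
    cursor = 0
    for sentence, info in sentences:
        if info is not None:
            offset, surface, gold = info
            start = cursor + offset
            gold_out.append(
                replace(
                    gold,
                    provenance=TermMatch(surface, gold.concept_id, start, start + len(surface)),
                )
            )
        text_parts.append(sentence + ".")
        cursor += len(sentence) + 2  # ". " joiner
    return GoldNote(" ".join(text_parts), tuple(gold_out), spec)


def _plan_for_profile(
    spec: NoteSpec, ont: Ontology, rng: random.Random
) -> list[PlannedFinding]:
    if spec.profile == "independent":
        return list(INDEPENDENT_PLAN)
    if spec.profile == "frail":
        return list(FRAIL_PLAN)
    if spec.profile != "mixed":
        raise GenerationError(f"unknown profile {spec.profile!r}")
    eligible = sorted(
        c.ccfo_id
        for c in ont.concepts.values()
        if c.role == "document-expected" and _neutral_terms(ont, c.ccfo_id)
    )
    plans = []
    for cid in rng.sample(eligible, k=min(spec.n_findings, len(eligible))):
        axis = ont.concepts[cid].axis
        qualifier = rng.choice(_SAMPLE_QUALIFIERS.get(axis, (UNQUALIFIED,)))
        course = rng.choice((None, None, None, "chronic", "short-duration", "sudden-onset"))
        plans.append(PlannedFinding(cid, qualifier, course))
    return plans


def generate_corpus(
    n: int,
    ont: Ontology,
    base_spec: NoteSpec = NoteSpec(),
    profiles: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[GoldNote], dict]:
    """n notes plus a corpus-level gold summary (finding counts per concept).

    ``profiles`` optionally gives sampling weights over note profiles;
    otherwise every note uses ``base_spec.profile``. Per-note seeds derive
    from ``seed``, so the corpus is reproducible as a whole.
    """
    rng = random.Random(seed)
    notes: list[GoldNote] = []
    counts: Counter[str] = Counter()
    names = sorted(profiles) if profiles else None
    for _ in range(max(0, n)):
        profile = (
            rng.choices(names, weights=[profiles[p] for p in names])[0]
            if names
            else base_spec.profile
        )
        spec = replace(base_spec, profile=profile, seed=rng.randrange(2**31))
        note = generate_note(spec, ont)
        notes.append(note)
        counts.update(f.concept_id for f in note.gold)
    summary = {
        "n_notes": len(notes),
        "n_gold_findings": sum(len(nt.gold) for nt in notes),
        "findings_per_concept": dict(counts),
    }
    return notes, summary
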