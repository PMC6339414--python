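"""Concept-level frailty scores and group-wise Rockwood aggregation.

Nine concepts central to frailty assessment carry rater-averaged Rockwood
Clinical Frailty Scale scores per qualifier level (fractional averages
such as 7.44 are kept as reals).  A patient's findings are summarized by
aggregating scored, asserted findings into seven concept groups (subtree
descent from each group's root) and taking the maximum Rockwood score
within each group — the feature profile used as model input downstream.

Findings whose concept-qualifier pairing has no recorded score (blank
table cells, able/absent-deficit pairings, negated mentions) are
*unscored* and never enter a maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .extraction import ASSERTED, Finding, UNQUALIFIED
from .ontology import Ontology

UNSCORED = "unscored"
NO_EVIDENCE = "no-evidence"


@dataclass(frozen=True)
class FrailtyProfile:
    #: group -> max Rockwood among scored findings, or None for no evidence
    group_scores: dict[str, Optional[float]]
    overall: Optional[float]
    n_findings: dict[str, int] = field(default_factory=dict)


def rockwood_for(ont: Ontology, concept_id: str, qualifier: str) -> float | str:
    """Rockwood score for a concept-qualifier pairing, or ``"unscored"``.

    Unqualified findings on single-level concepts use the "only-level"
    record; pairings without a recorded score (including blank cells for
    levels the raters never scored) are unscored.
    """
    if concept_id not in ont.concepts:
        raise KeyError(f"unknown CCFOID: {concept_id!r}")
    level = "only-level" if qualifier in (UNQUALIFIED, "only-level") else qualifier
    rec = ont.scores.get((concept_id, level))
    if rec is None or rec.rockwood is None:
        return UNSCORED
    return rec.rockwood


def concept_relevance(ont: Ontology, concept_id: str) -> dict:
    """Fix-ability/relevance ratings and the derived cardiac-specific flag.

    A concept is cardiac-specific when raters called it both highly
    relevant to cardiac decisions and highly likely to be fixed by the
    intervention. Concepts without any score record report "unscored".
    """
    if concept_id not in ont.concepts:
        raise KeyError(f"unknown CCFOID: {concept_id!r}")
    recs = [r for (cid, _), r in ont.scores.items() if cid == concept_id]
    if not recs:
        return {"will_fix": UNSCORED, "relevance": UNSCORED, "cardiac_specific": UNSCORED}
    will_fix = next((r.will_fix for r in recs if r.will_fix), None)
    relevance = next((r.relevance for r in recs if r.relevance), None)
    return {
        "will_fix": will_fix,
        "relevance": relevance,
        "cardiac_specific": will_fix == "H" and relevance == "H",
    }


def aggregate_profile(findings: list[Finding], ont: Ontology) -> FrailtyProfile:
    """Group-wise maximum Rockwood over scored, asserted findings.

    Every group in the ontology's group map is reported; groups whose
    subtree holds no scored finding carry ``None`` (no evidence).  The
    overall score is the maximum over groups with evidence.
    """
    group_scores: dict[str, Optional[float]] = {g: None for g in ont.group_map}
    counts: dict[str, int] = {g: 0 for g in ont.group_map}
    for f in findings:
        if f.assertion != ASSERTED:
            continue
        score = rockwood_for(ont, f.concept_id, f.qualifier)
        if score == UNSCORED:
            continue
        group = ont.group_of(f.concept_id)
        if group is None:
            continue
        counts[group] += 1
        prev = group_scores[group]
        group_scores[group] = score if prev is None else max(prev, score)
    with_evidence = [s for s in group_scores.values() if s is not None]
    return FrailtyProfile(
        group_scores=group_scores,
        overall=max(with_evidence) if with_evidence else None,
        n_findings=counts,
    )
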