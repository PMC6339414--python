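"""Finding-driven scoring of Katz ADL, Barthel index and SF-36.

Each instrument is a list of items (SF-36: question blocks grouped into
eight sections); each item owns rule rows mapping finding patterns —
(concept or concept subtree, qualifier set, optional course), optionally
conjoined with a second pattern — to a point value.  The rows ship as a
TSV data file so the rule set is inspectable and testable apart from the
engine.

Evaluation semantics:

* findings are deduplicated, and negated mentions are dropped unless they
  carry the *absent* qualifier (an explicitly denied deficit is evidence);
* an item is *covered* when at least one of its rows matches; conflicting
  evidence resolves pessimistically — among matching rows the lowest
  point value wins;
* Katz and Barthel totals are sums over covered items (uncovered items
  contribute nothing and reduce coverage);
* each SF-36 section is the question-count-weighted average over its
  covered blocks, in [0, 100]; a section with no covered block has no
  score rather than zero.

The printed Barthel rules sum to a maximum of 19 although the published
scale tops out at 20; results report the published bounds alongside the
rule-sum maximum and are never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .extraction import Finding, NEGATED, UNQUALIFIED
from .ontology import Ontology

#: qualifier-set tokens usable in rule rows
_PRESENT = {
    UNQUALIFIED, "able", "with-difficulty", "unable", "high-frequency", "mid-frequency",
}
_ANY = _PRESENT | {"absent"}


@dataclass(frozen=True)
class _Antecedent:
    concept: str  # CCFOID, with trailing "*" meaning subtree
    qualifiers: frozenset[str]
    course: Optional[str] = None

    def matches(self, finding: Finding, ont: Ontology) -> bool:
        if self.concept.endswith("*"):
            root = self.concept[:-1]
            if not ont.descends_from(finding.concept_id, root):
                return False
        elif finding.concept_id != self.concept:
            return False
        if finding.qualifier not in self.qualifiers:
            return False
        if self.course is not None and finding.course != self.course:
            return False
        return True


@dataclass(frozen=True)
class ScoringRule:
    instrument: str
    item: str
    weight: int
    points: float
    antecedents: tuple[_Antecedent, ...]


@dataclass
class InstrumentResult:
    instrument: str
    total: object  # float for Katz/Barthel; dict[section, float|None] for SF-36
    scale_min: float
    scale_max: float
    coverage: float
    contributing: list[Finding] = field(default_factory=list)
    item_points: dict[str, Optional[float]] = field(default_factory=dict)
    rule_sum_max: Optional[float] = None


def _parse_qual(spec: str) -> frozenset[str]:
    out: set[str] = set()
    for tok in spec.split("|"):
        tok = tok.strip()
        if tok == "present":
            out |= _PRESENT
        elif tok == "any":
            out |= _ANY
        elif tok == "uq":
            out.add(UNQUALIFIED)
        elif tok in _ANY:
            out.add(tok)
        else:
            raise ValueError(f"unknown qualifier token {tok!r}")
    return frozenset(out)


def load_rules(path: str | Path | None = None) -> list[ScoringRule]:
    """Parse the shipped (or a user-supplied) instrument rule table."""
    if path is None:
        path = resources.files("ccfo") / "data" / "instrument_rules.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    rules: list[ScoringRule] = []
    for _, row in df.iterrows():
        ants = [
            _Antecedent(row["concept1"], _parse_qual(row["qual1"]), row["course1"] or None)
        ]
        if row.get("concept2"):
            ants.append(_Antecedent(row["concept2"], _parse_qual(row["qual2"])))
        rules.append(
            ScoringRule(
                row["instrument"],
                row["item"],
                int(row["weight"]),
                float(row["points"]),
                tuple(ants),
            )
        )
    return rules


def validate_rules(rules: list[ScoringRule], ont: Ontology) -> list[str]:
    report = []
    for r in rules:
        if r.points < 0:
            report.append(f"{r.instrument}/{r.item}: negative points")
        for a in r.antecedents:
            cid = a.concept.rstrip("*")
            if cid not in ont.concepts:
                report.append(f"{r.instrument}/{r.item}: unknown concept {cid}")
    return report


def _scoreable(findings: list[Finding]) -> list[Finding]:
    out, seen = [], set()
    for f in findings:
        if f.assertion == NEGATED and f.qualifier != "absent":
            continue
        key = (f.concept_id, f.qualifier, f.course)
        if key in seen:
            continue  # duplicates score once
        seen.add(key)
        out.append(f)
    return out


def _score_items(
    rules: list[ScoringRule], findings: list[Finding], ont: Ontology
) -> tuple[dict[str, Optional[float]], dict[str, int], list[Finding]]:
    """Per-item minimum matched points (None = uncovered), weights, evidence."""
    findings = _scoreable(findings)
    items: dict[str, Optional[float]] = {}
    weights: dict[str, int] = {}
    used: list[Finding] = []
    used_keys: set[tuple] = set()
    for rule in rules:
        items.setdefault(rule.item, None)
        weights[rule.item] = rule.weight
        support = []
        for ant in rule.antecedents:
            sat = [f for f in findings if ant.matches(f, ont)]
            if not sat:
                support = []
                break
            support.extend(sat)
        if not support:
            continue
        prev = items[rule.item]
        items[rule.item] = rule.points if prev is None else min(prev, rule.points)
        for f in support:
            if f.key() not in used_keys:
                used_keys.add(f.key())
                used.append(f)
    return items, weights, used


def _select(rules: list[ScoringRule], instrument_prefix: str) -> list[ScoringRule]:
    return [r for r in rules if r.instrument.split(":")[0] == instrument_prefix]


def score_katz(
    findings: list[Finding], ont: Ontology, rules: Optional[list[ScoringRule]] = None
) -> InstrumentResult:
    """Katz ADL count: 6 = highly functioning, 0 = very dependent."""
    rules = _select(rules or load_rules(), "katz")
    items, _, used = _score_items(rules, findings, ont)
    total = sum(p for p in items.values() if p is not None)
    covered = sum(1 for p in items.values() if p is not None)
    return InstrumentResult(
        instrument="katz",
        total=total,
        scale_min=0,
        scale_max=6,
        coverage=covered / len(items) if items else 0.0,
        contributing=used,
        item_points=items,
        rule_sum_max=6,
    )


def score_barthel(
    findings: list[Finding], ont: Ontology, rules: Optional[list[ScoringRule]] = None
) -> InstrumentResult:
    """Barthel index from the printed rules; published scale 0-20."""
    rules = _select(rules or load_rules(), "barthel")
    items, _, used = _score_items(rules, findings, ont)
    total = sum(p for p in items.values() if p is not None)
    covered = sum(1 for p in items.values() if p is not None)
    return InstrumentResult(
        instrument="barthel",
        total=total,
        scale_min=0,
        scale_max=20,  # published bounds; printed rules reach at most 19
        coverage=covered / len(items) if items else 0.0,
        contributing=used,
        item_points=items,
        rule_sum_max=19,
    )


def score_sf36(
    findings: list[Finding], ont: Ontology, rules: Optional[list[ScoringRule]] = None
) -> InstrumentResult:
    """Eight SF-36 section scores in [0, 100]; higher = better health."""
    rules = _select(rules or load_rules(), "sf36")
    sections: dict[str, list[ScoringRule]] = {}
    for r in rules:
        sections.setdefault(r.instrument.split(":", 1)[1], []).append(r)
    totals: dict[str, Optional[float]] = {}
    item_points: dict[str, Optional[float]] = {}
    used: list[Finding] = []
    used_keys: set[tuple] = set()
    n_blocks = 0
    n_covered = 0
    for section, sec_rules in sections.items():
        items, weights, sec_used = _score_items(sec_rules, findings, ont)
        for f in sec_used:
            if f.key() not in used_keys:
                used_keys.add(f.key())
                used.append(f)
        pts = wts = 0.0
        for item, p in items.items():
            item_points[f"{section}/{item}"] = p
            n_blocks += 1
            if p is not None:
                n_covered += 1
                pts += p
                wts += weights[item]
        totals[section] = pts / wts if wts else None
    return InstrumentResult(
        instrument="sf36",
        total=totals,
        scale_min=0,
        scale_max=100,
        coverage=n_covered / n_blocks if n_blocks else 0.0,
        contributing=used,
        item_points=item_points,
        rule_sum_max=None,
    )
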