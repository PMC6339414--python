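"""Core data model for the cardiac-centered frailty ontology (CCFO).

The ontology is a small hierarchy of *clinical finding* concepts, each
carrying an opaque hierarchical identifier (CCFOID) and, where an exact
mapping exists, a SNOMED-CT identifier (SCTID).  Concepts expected to
surface in clinical documents own a lexicon of *terms*: surface strings
that indicate the author was thinking of the concept (terms are not
synonyms of the concept name).  Twelve qualifier-value concepts model the
ability (able / with difficulty / unable), frequency (high / mid),
absence, and clinical-course (chronic / short duration / sudden onset)
modifiers that attach to findings.  Concept-qualifier pairings central to
frailty assessment carry Rockwood Clinical Frailty Scale scores (1 very
fit .. 9 terminally ill) together with low/medium/high ratings of
cardiac-intervention fix-ability and relevance to cardiac decisions.

The fixture of record is plain TSV (one directory holding ``concepts.tsv``,
``terms.tsv``, ``scores.tsv``, ``excluded_terms.txt``, ``groups.tsv``);
OWL and the XLSX supplement are import/export dialects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

ROLES = {"document-expected", "hierarchical-group", "qualifier-value", "demographic"}
AXES = {"ability", "frequency", "absent", "course", "none"}

#: Qualifier levels, by axis, in deficit-to-intact order where ordered.
ABILITY_LEVELS = ("unable", "with-difficulty", "able")
FREQUENCY_LEVELS = ("high-frequency", "mid-frequency", "absent")
COURSE_LEVELS = ("chronic", "short-duration", "sudden-onset")

QUALIFIER_VALUES_ROOT_NAME = "qualifier values"


class OntologyError(ValueError):
    """Base class for fixture problems."""


class ParseError(OntologyError):
    """A fixture file could not be parsed; the message names the spot."""


class IntegrityError(OntologyError):
    """The fixture parsed but violates a structural invariant."""


@dataclass(frozen=True)
class Concept:
    ccfo_id: str
    name: str
    sctid: Optional[str] = None
    parent_id: Optional[str] = None
    role: str = "document-expected"
    #: qualifier axis the concept takes in text ("ability", "frequency",
    #: "none"), or for qualifier-value concepts the axis they belong to.
    axis: str = "none"
    #: for qualifier-value concepts only: the level this value denotes.
    level: Optional[str] = None

    @property
    def is_root(self) -> bool:
        return self.parent_id is None


@dataclass(frozen=True)
class Term:
    surface: str
    concept_id: str
    #: qualifier level the surface itself asserts (e.g. "unable to run"),
    #: overriding contextual cues; None for neutral surfaces.
    intrinsic: Optional[str] = None


@dataclass(frozen=True)
class ScoreRecord:
    concept_id: str
    level: str  # qualifier level, or "only-level" for single-level concepts
    rockwood: Optional[float] = None
    will_fix: Optional[str] = None  # L / M / H
    relevance: Optional[str] = None  # L / M / H or verbatim tie code


@dataclass
class Ontology:
    concepts: dict[str, Concept] = field(default_factory=dict)
    terms: dict[str, Term] = field(default_factory=dict)  # surface -> Term
    scores: dict[tuple[str, str], ScoreRecord] = field(default_factory=dict)
    excluded_terms: list[str] = field(default_factory=list)
    group_map: dict[str, str] = field(default_factory=dict)  # group -> root CCFOID

    # -- basic queries ----------------------------------------------------

    def __contains__(self, ccfo_id: str) -> bool:
        return ccfo_id in self.concepts

    def concept(self, ccfo_id: str) -> Concept:
        try:
            return self.concepts[ccfo_id]
        except KeyError:
            raise KeyError(f"unknown CCFOID: {ccfo_id!r}") from None

    def concept_by_name(self, name: str) -> Concept:
        for c in self.concepts.values():
            if c.name == name:
                return c
        raise KeyError(f"no concept named {name!r}")

    def children(self, ccfo_id: str) -> list[Concept]:
        return [c for c in self.concepts.values() if c.parent_id == ccfo_id]

    def roots(self) -> list[Concept]:
        return [c for c in self.concepts.values() if c.is_root]

    def terms_for(self, ccfo_id: str) -> list[Term]:
        return [t for t in self.terms.values() if t.concept_id == ccfo_id]

    def qualifier_values(self) -> list[Concept]:
        return [c for c in self.concepts.values() if c.role == "qualifier-value"]

    def descends_from(self, ccfo_id: str, ancestor_id: str) -> bool:
        """True if *ccfo_id* equals or lies in the subtree of *ancestor_id*."""
        cur: Optional[str] = ccfo_id
        seen = set()
        while cur is not None and cur not in seen:
            if cur == ancestor_id:
                return True
            seen.add(cur)
            parent = self.concepts.get(cur)
            cur = parent.parent_id if parent else None
        return False

    def group_of(self, ccfo_id: str) -> Optional[str]:
        """Aggregation group whose subtree contains the concept, if any."""
        for group, root in self.group_map.items():
            if self.descends_from(ccfo_id, root):
                return group
        return None


# -- operations -----------------------------------------------------------


def concept_for_term(ont: Ontology, surface: str) -> Optional[Concept]:
    """The unique concept a normalized surface string indicates, or None.

    Excluded ambiguous surfaces (and the empty string) never resolve.
    """
    surface = surface.strip().lower()
    if not surface or surface in ont.excluded_terms:
        return None
    term = ont.terms.get(surface)
    return ont.concepts.get(term.concept_id) if term else None


def ancestors(ont: Ontology, ccfo_id: str) -> list[Concept]:
    """Parent-to-root chain for a concept (empty for roots)."""
    chain: list[Concept] = []
    cur = ont.concept(ccfo_id).parent_id
    seen = {ccfo_id}
    while cur is not None:
        if cur in seen:
            raise IntegrityError(f"cycle through CCFOID {cur}")
        seen.add(cur)
        node = ont.concept(cur)
        chain.append(node)
        cur = node.parent_id
    return chain


def summary_counts(ont: Ontology) -> dict:
    """Headline counts plus the terms-per-concept histogram.

    The histogram is over document-expected concepts only, keyed by the
    number of lexicon terms the concept owns.
    """
    doc = [c for c in ont.concepts.values() if c.role == "document-expected"]
    hist: dict[int, int] = {}
    for c in doc:
        n = len(ont.terms_for(c.ccfo_id))
        hist[n] = hist.get(n, 0) + 1
    return {
        "n_concepts": len(ont.concepts),
        "n_terms": len(ont.terms),
        "n_document_expected": len(doc),
        "n_qualifier_values": len(ont.qualifier_values()),
        "terms_per_concept_histogram": dict(sorted(hist.items())),
    }


def validate_ontology(ont: Ontology) -> list[str]:
    """Structural-invariant check; each entry names the violation and id.

    Violations are data, not exceptions: an empty list means valid.
    """
    report: list[str] = []
    if not ont.concepts:
        report.append("empty ontology: no root concept")
        return report
    if not ont.roots():
        report.append("no root concept (every concept has a parent)")

    for cid, c in ont.concepts.items():
        if c.role not in ROLES:
            report.append(f"unknown role {c.role!r} on CCFOID {cid}")
        if c.axis not in AXES:
            report.append(f"unknown axis {c.axis!r} on CCFOID {cid}")
        if c.parent_id is not None and c.parent_id not in ont.concepts:
            report.append(f"dangling parent {c.parent_id!r} on CCFOID {cid}")

    # cycles
    for cid in ont.concepts:
        cur, seen = cid, set()
        while cur is not None:
            if cur in seen:
                report.append(f"cycle in parent chain at CCFOID {cur}")
                break
            seen.add(cur)
            node = ont.concepts.get(cur)
            cur = node.parent_id if node else None

    # qualifier values descend from the qualifier-values root
    qv_roots = {
        c.ccfo_id for c in ont.roots() if c.name == QUALIFIER_VALUES_ROOT_NAME
    }
    for c in ont.qualifier_values():
        if not any(ont.descends_from(c.ccfo_id, r) for r in qv_roots):
            report.append(
                f"qualifier value CCFOID {c.ccfo_id} outside the qualifier-values root"
            )

    for surface, term in ont.terms.items():
        if not surface:
            report.append("empty term surface")
        if surface != surface.strip().lower():
            report.append(f"term surface not normalized: {surface!r}")
        if term.concept_id not in ont.concepts:
            report.append(f"term {surface!r} maps to unknown CCFOID {term.concept_id}")
        if surface in ont.excluded_terms:
            report.append(
                f"term {surface!r} conflicts with the excluded-ambiguous-term list"
            )

    for (cid, level), rec in ont.scores.items():
        if cid not in ont.concepts:
            report.append(f"score record for unknown CCFOID {cid}")
        if rec.rockwood is not None and not (1.0 <= rec.rockwood <= 9.0):
            report.append(
                f"rockwood {rec.rockwood} outside [1, 9] for CCFOID {cid}/{level}"
            )

    # Rockwood non-decreasing across able -> with-difficulty -> unable
    by_concept: dict[str, dict[str, float]] = {}
    for (cid, level), rec in ont.scores.items():
        if rec.rockwood is not None:
            by_concept.setdefault(cid, {})[level] = rec.rockwood
    for cid, levels in by_concept.items():
        ladder = [levels[lv] for lv in ("able", "with-difficulty", "unable") if lv in levels]
        if any(a > b for a, b in zip(ladder, ladder[1:])):
            report.append(f"rockwood not monotone across ability levels for CCFOID {cid}")

    for group, root in ont.group_map.items():
        if root not in ont.concepts:
            report.append(f"group {group!r} rooted at unknown CCFOID {root}")

    return report


# -- tabular fixture IO ---------------------------------------------------

_CONCEPT_COLS = ["ccfo_id", "sctid", "name", "parent_id", "role"]
_TERM_COLS = ["surface", "ccfo_id"]
_SCORE_COLS = ["ccfo_id", "level", "rockwood", "will_fix", "relevance"]


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path.name}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    return df


def load_tabular(fixture_dir: str | Path) -> Ontology:
    """Load the TSV fixture directory into a validated :class:`Ontology`."""
    d = Path(fixture_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"fixture directory not found: {d}")

    ont = Ontology()

    cdf = _read_tsv(d / "concepts.tsv", _CONCEPT_COLS)
    for i, row in cdf.iterrows():
        cid = _opt(row["ccfo_id"])
        name = _opt(row["name"])
        if cid is None or name is None:
            raise ParseError(f"concepts.tsv line {i + 2}: ccfo_id and name required")
        if cid in ont.concepts:
            raise IntegrityError(f"duplicate CCFOID {cid} (concepts.tsv line {i + 2})")
        ont.concepts[cid] = Concept(
            ccfo_id=cid,
            name=name,
            sctid=_opt(row.get("sctid")),
            parent_id=_opt(row.get("parent_id")),
            role=_opt(row.get("role")) or "document-expected",
            axis=_opt(row.get("axis")) or "none",
            level=_opt(row.get("level")),
        )
    if not ont.concepts or not any(c.is_root for c in ont.concepts.values()):
        raise IntegrityError("concepts.tsv: no root concept")

    excl = d / "excluded_terms.txt"
    if excl.exists():
        ont.excluded_terms = [
            ln.strip().lower()
            for ln in excl.read_text(encoding="utf-8").splitlines()
            if ln.strip()
        ]

    tdf = _read_tsv(d / "terms.tsv", _TERM_COLS)
    for i, row in tdf.iterrows():
        surface = (_opt(row["surface"]) or "").lower()
        cid = _opt(row["ccfo_id"])
        if not surface or cid is None:
            raise ParseError(f"terms.tsv line {i + 2}: surface and ccfo_id required")
        if surface in ont.terms:
            raise IntegrityError(
                f"terms.tsv line {i + 2}: surface {surface!r} maps to two concepts"
            )
        ont.terms[surface] = Term(surface, cid, _opt(row.get("intrinsic")))

    spath = d / "scores.tsv"
    if spath.exists():
        sdf = _read_tsv(spath, _SCORE_COLS)
        for i, row in sdf.iterrows():
            cid = _opt(row["ccfo_id"])
            level = _opt(row["level"]) or "only-level"
            rock = _opt(row.get("rockwood"))
            try:
                rockwood = float(rock) if rock is not None else None
            except ValueError:
                raise ParseError(f"scores.tsv line {i + 2}: bad rockwood {rock!r}")
            ont.scores[(cid, level)] = ScoreRecord(
                cid, level, rockwood, _opt(row.get("will_fix")), _opt(row.get("relevance"))
            )

    gpath = d / "groups.tsv"
    if gpath.exists():
        gdf = _read_tsv(gpath, ["group", "root_ccfo_id"])
        for _, row in gdf.iterrows():
            ont.group_map[str(row["group"])] = str(row["root_ccfo_id"])

    return ont


def export_tabular(ont: Ontology, fixture_dir: str | Path) -> Path:
    """Write the TSV fixture; inverse of :func:`load_tabular`."""
    if not ont.concepts:
        raise IntegrityError("refusing to export an empty ontology")
    d = Path(fixture_dir)
    d.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "ccfo_id": c.ccfo_id,
                "sctid": c.sctid,
                "name": c.name,
                "parent_id": c.parent_id,
                "role": c.role,
                "axis": c.axis,
                "level": c.level,
            }
            for c in ont.concepts.values()
        ]
    ).to_csv(d / "concepts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"surface": t.surface, "ccfo_id": t.concept_id, "intrinsic": t.intrinsic}
            for t in ont.terms.values()
        ],
        columns=["surface", "ccfo_id", "intrinsic"],
    ).to_csv(d / "terms.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "ccfo_id": r.concept_id,
                "level": r.level,
                "rockwood": r.rockwood,
                "will_fix": r.will_fix,
                "relevance": r.relevance,
            }
            for r in ont.scores.values()
        ],
        columns=_SCORE_COLS,
    ).to_csv(d / "scores.tsv", sep="\t", index=False)
    (d / "excluded_terms.txt").write_text(
        "".join(f"{s}\n" for s in ont.excluded_terms), encoding="utf-8"
    )
    pd.DataFrame(
        [{"group": g, "root_ccfo_id": r} for g, r in ont.group_map.items()],
        columns=["group", "root_ccfo_id"],
    ).to_csv(d / "groups.tsv", sep="\t", index=False)
    return d


def load_ontology(fixture_path: str | Path, format: str = "tabular") -> Ontology:
    """Load an ontology in the named format and fail fast on violations."""
    if format == "tabular":
        ont = load_tabular(fixture_path)
    elif format == "owl":
        from . import owl

        ont = owl.load_owl(fixture_path)
    elif format == "xlsx-supplement":
        from . import xlsx

        ont = xlsx.load_supplement_xlsx(fixture_path)
    else:
        raise ValueError(f"unknown fixture format {format!r}")
    report = validate_ontology(ont)
    if report:
        raise IntegrityError("; ".join(report[:10]))
    return ont


def export_ontology(ont: Ontology, path: str | Path, format: str = "tabular") -> Path:
    if format == "tabular":
        return export_tabular(ont, path)
    if format == "owl":
        from . import owl

        return owl.export_owl(ont, path)
    raise ValueError(f"unknown export format {format!r}")


def fixture_dir() -> Path:
    """Directory of the packaged in-paper fixture."""
    return Path(resources.files("ccfo") / "data")


def load_in_paper_ontology() -> Ontology:
    """The fixture reconstructed from content printed in the source tables."""
    return load_ontology(fixture_dir(), format="tabular")
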