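"""OWL (RDF/XML) import/export for the ontology.

One ``owl:Class`` per concept, ``rdfs:subClassOf`` from the parent link,
and annotation properties for SCTID, role, qualifier axis/level, lexicon
terms, score records, excluded terms and aggregation groups.  The class
IRIs are minted from the CCFOID so the export can sit side by side with
the published CCFO file on BioPortal.  OWL is an exchange dialect only;
the TSV fixture remains the model of record.
"""

from __future__ import annotations

from pathlib import Path

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL

from .ontology import Concept, IntegrityError, Ontology, ScoreRecord, Term

CCFO = Namespace("http://purl.bioontology.org/ontology/CCFO#")


def _iri(ccfo_id: str):
    return CCFO[f"CCFOID_{ccfo_id}"]


def export_owl(ont: Ontology, path: str | Path) -> Path:
    if not ont.concepts:
        raise IntegrityError("refusing to export an empty ontology")
    g = Graph()
    g.bind("ccfo", CCFO)
    onto = CCFO["ontology"]
    g.add((onto, RDF.type, OWL.Ontology))
    for surface in ont.excluded_terms:
        g.add((onto, CCFO.excludedTerm, Literal(surface)))
    for group, root in ont.group_map.items():
        node = BNode()
        g.add((onto, CCFO.aggregationGroup, node))
        g.add((node, CCFO.groupName, Literal(group)))
        g.add((node, CCFO.groupRoot, Literal(root)))

    for c in ont.concepts.values():
        iri = _iri(c.ccfo_id)
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(c.name)))
        g.add((iri, CCFO.ccfoId, Literal(c.ccfo_id)))
        g.add((iri, CCFO.role, Literal(c.role)))
        g.add((iri, CCFO.axis, Literal(c.axis)))
        if c.level:
            g.add((iri, CCFO.level, Literal(c.level)))
        if c.sctid:
            g.add((iri, CCFO.sctid, Literal(c.sctid)))
        if c.parent_id:
            g.add((iri, RDFS.subClassOf, _iri(c.parent_id)))

    for t in ont.terms.values():
        node = BNode()
        g.add((_iri(t.concept_id), CCFO["term"], node))
        g.add((node, CCFO.surface, Literal(t.surface)))
        if t.intrinsic:
            g.add((node, CCFO.intrinsic, Literal(t.intrinsic)))

    for rec in ont.scores.values():
        node = BNode()
        g.add((_iri(rec.concept_id), CCFO.score, node))
        g.add((node, CCFO.level, Literal(rec.level)))
        if rec.rockwood is not None:
            g.add((node, CCFO.rockwood, Literal(rec.rockwood)))
        if rec.will_fix:
            g.add((node, CCFO.willFix, Literal(rec.will_fix)))
        if rec.relevance:
            g.add((node, CCFO.relevance, Literal(rec.relevance)))

    path = Path(path)
    g.serialize(destination=str(path), format="xml")
    return path


def load_owl(path: str | Path) -> Ontology:
    g = Graph()
    g.parse(str(path), format="xml")
    ont = Ontology()

    onto = CCFO["ontology"]
    ont.excluded_terms = sorted(str(o) for o in g.objects(onto, CCFO.excludedTerm))
    for node in g.objects(onto, CCFO.aggregationGroup):
        name = g.value(node, CCFO.groupName)
        root = g.value(node, CCFO.groupRoot)
        if name is not None and root is not None:
            ont.group_map[str(name)] = str(root)

    for iri in g.subjects(RDF.type, OWL.Class):
        cid = g.value(iri, CCFO.ccfoId)
        if cid is None:
            continue
        cid = str(cid)
        if cid in ont.concepts:
            raise IntegrityError(f"duplicate CCFOID {cid} in OWL file")
        parent = g.value(iri, RDFS.subClassOf)
        parent_id = str(g.value(parent, CCFO.ccfoId)) if parent is not None else None
        level = g.value(iri, CCFO.level)
        sctid = g.value(iri, CCFO.sctid)
        ont.concepts[cid] = Concept(
            ccfo_id=cid,
            name=str(g.value(iri, RDFS.label) or cid),
            sctid=str(sctid) if sctid is not None else None,
            parent_id=parent_id,
            role=str(g.value(iri, CCFO.role) or "document-expected"),
            axis=str(g.value(iri, CCFO.axis) or "none"),
            level=str(level) if level is not None else None,
        )
        for tnode in g.objects(iri, CCFO["term"]):
            surface = g.value(tnode, CCFO.surface)
            if surface is None:
                continue
            intrinsic = g.value(tnode, CCFO.intrinsic)
            ont.terms[str(surface)] = Term(
                str(surface), cid, str(intrinsic) if intrinsic is not None else None
            )
        for snode in g.objects(iri, CCFO.score):
            level = str(g.value(snode, CCFO.level) or "only-level")
            rock = g.value(snode, CCFO.rockwood)
            wf = g.value(snode, CCFO.willFix)
            rel = g.value(snode, CCFO.relevance)
            ont.scores[(cid, level)] = ScoreRecord(
                cid,
                level,
                float(rock) if rock is not None else None,
                str(wf) if wf is not None else None,
                str(rel) if rel is not None else None,
            )
    if not ont.concepts:
        raise IntegrityError(f"{path}: no CCFO classes found")
    return ont
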