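"""Reader for the published concept-list workbook (XLSX supplement).

Expects a workbook with the same logical tables as the TSV fixture:
sheets named ``concepts``, ``terms``, and optionally ``scores``,
``excluded_terms`` and ``groups``, each with a header row matching the
TSV columns.  Cells are coerced to strings; blank cells become missing
values.
"""

from __future__ import annotations

from pathlib import Path

from openpyxl import load_workbook

from .ontology import Concept, IntegrityError, Ontology, ParseError, ScoreRecord, Term


def _rows(ws):
    it = ws.iter_rows(values_only=True)
    header = next(it, None)
    if header is None:
        raise ParseError(f"sheet {ws.title!r}: empty")
    cols = [str(h).strip() if h is not None else "" for h in header]
    for values in it:
        if all(v is None or str(v).strip() == "" for v in values):
            continue
        row = {}
        for key, v in zip(cols, values):
            s = str(v).strip() if v is not None else ""
            row[key] = s or None
        yield row


def load_supplement_xlsx(path: str | Path) -> Ontology:
    wb = load_workbook(str(path), read_only=True, data_only=True)
    names = {n.lower(): n for n in wb.sheetnames}
    if "concepts" not in names or "terms" not in names:
        raise ParseError(f"{path}: workbook needs 'concepts' and 'terms' sheets")

    ont = Ontology()
    for row in _rows(wb[names["concepts"]]):
        cid = row.get("ccfo_id")
        if cid is None:
            raise ParseError("concepts sheet: row without ccfo_id")
        if cid in ont.concepts:
            raise IntegrityError(f"duplicate CCFOID {cid} in concepts sheet")
        ont.concepts[cid] = Concept(
            ccfo_id=cid,
            name=row.get("name") or cid,
            sctid=row.get("sctid"),
            parent_id=row.get("parent_id"),
            role=row.get("role") or "document-expected",
            axis=row.get("axis") or "none",
            level=row.get("level"),
        )
    for row in _rows(wb[names["terms"]]):
        surface = (row.get("surface") or "").lower()
        cid = row.get("ccfo_id")
        if not surface or cid is None:
            raise ParseError("terms sheet: row without surface/ccfo_id")
        if surface in ont.terms:
            raise IntegrityError(f"surface {surface!r} maps to two concepts")
        ont.terms[surface] = Term(surface, cid, row.get("intrinsic"))
    if "scores" in names:
        for row in _rows(wb[names["scores"]]):
            cid = row.get("ccfo_id")
            level = row.get("level") or "only-level"
            rock = row.get("rockwood")
            ont.scores[(cid, level)] = ScoreRecord(
                cid, level, float(rock) if rock else None,
                row.get("will_fix"), row.get("relevance"),
            )
    if "excluded_terms" in names:
        for values in wb[names["excluded_terms"]].iter_rows(values_only=True):
            if values and values[0] is not None:
                s = str(values[0]).strip().lower()
                if s and s != "surface":
                    ont.excluded_terms.append(s)
    if "groups" in names:
        for row in _rows(wb[names["groups"]]):
            if row.get("group") and row.get("root_ccfo_id"):
                ont.group_map[row["group"]] = row["root_ccfo_id"]
    wb.close()
    if not ont.concepts:
        raise IntegrityError(f"{path}: no concepts found")
    return ont
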