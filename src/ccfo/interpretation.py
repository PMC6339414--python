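"""Interpretation criteria for raw frailty-instrument scores.

Ten instruments commonly quoted in clinical documents (Morse/annual fall
scale, Tinetti, Braden, FIM, Katz ADL, the 0-100 Barthel variant,
per-item IADL, the Lawton IADL total scale, FAQ and the ADL screen) are
mapped from raw score to the printed category, a coarse frailty
indication, and a Rockwood band.

Notes on the table:

* the 0-100 Barthel row is the published 0-100 variant and is distinct
  from the 0-20 finding-driven scoring rules in :mod:`ccfo.scoring`;
* a bare "IADL: n" mention resolves to the Lawton 0-8 total scale (the
  per-item 0/1/2 reading is available as instrument ``iadl-item``);
* the ADL-screen row is internally inconsistent as printed and is kept
  verbatim, flagged *interpret with caution*: scores other than its two
  printed anchors interpret as unmapped;
* Lawton prints a direction but no thresholds; its frailty indication is
  a tercile-of-scale convention, not a published cut-point.

The Rockwood banding (least-frail category -> 1-3, intermediate -> 4-6,
most-frail -> 7-9) is a convention of this package; the source relates
instrument scores to the Rockwood scale without printing a per-instrument
crosswalk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

FRAIL = "frail-indicative"
INTERMEDIATE = "intermediate"
NOT_FRAIL = "not-frail-indicative"
UNMAPPED = "unmapped"

_BANDS = {"low": (1, 3), "middle": (4, 6), "high": (7, 9)}


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float
    label: str
    order: int  # 0 = least frail; -1 = continuous (no printed categories)


@dataclass(frozen=True)
class InstrumentCriteria:
    instrument: str
    aliases: tuple[str, ...]
    scale_min: float
    scale_max: float
    intervals: tuple[Interval, ...]
    direction: str  # lower-is-frailer | higher-is-frailer
    caution: bool = False
    continuous: bool = False


@dataclass(frozen=True)
class InterpretedScore:
    instrument: str
    raw: float
    category: str
    indication: str  # frail-indicative | intermediate | not-frail-indicative | unmapped
    order: int = -1
    n_categories: int = 0


def load_criteria(path: str | Path | None = None) -> dict[str, InstrumentCriteria]:
    if path is None:
        path = resources.files("ccfo") / "data" / "interpretation_criteria.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, InstrumentCriteria] = {}
    for name, rows in df.groupby("instrument", sort=False):
        first = rows.iloc[0]
        flags = set()
        for f in rows.get("flags", pd.Series(dtype=str)):
            flags |= {t for t in str(f).split("|") if t}
        out[name] = InstrumentCriteria(
            instrument=name,
            aliases=tuple(first["aliases"].split("|")),
            scale_min=float(first["scale_min"]),
            scale_max=float(first["scale_max"]),
            intervals=tuple(
                Interval(float(r["lo"]), float(r["hi"]), r["label"], int(r["order"]))
                for _, r in rows.iterrows()
            ),
            direction=first["direction"],
            caution="caution" in flags,
            continuous="continuous" in flags,
        )
    return out


_CRITERIA: Optional[dict[str, InstrumentCriteria]] = None


def criteria() -> dict[str, InstrumentCriteria]:
    global _CRITERIA
    if _CRITERIA is None:
        _CRITERIA = load_criteria()
    return _CRITERIA


def resolve_instrument(name: str) -> InstrumentCriteria:
    name = name.strip().lower()
    table = criteria()
    if name in table:
        return table[name]
    for crit in table.values():
        if name in (a.lower() for a in crit.aliases):
            return crit
    raise KeyError(f"unknown instrument {name!r}")


def scale_metadata(instrument: str) -> dict:
    """Printed bounds and thresholds for an instrument."""
    crit = resolve_instrument(instrument)
    return {
        "instrument": crit.instrument,
        "min": crit.scale_min,
        "max": crit.scale_max,
        "thresholds": [(iv.lo, iv.hi, iv.label) for iv in crit.intervals],
        "direction": crit.direction,
        "caution": crit.caution,
    }


def _tercile_indication(crit: InstrumentCriteria, raw: float) -> str:
    span = crit.scale_max - crit.scale_min
    pos = (raw - crit.scale_min) / span if span else 0.0
    if crit.direction == "lower-is-frailer":
        pos = 1.0 - pos  # pos = frailness
    if pos <= 1 / 3:
        return NOT_FRAIL
    if pos >= 2 / 3:
        return FRAIL
    return INTERMEDIATE


def interpret_score(instrument: str, raw: float) -> InterpretedScore:
    """Category and frailty indication for an in-bounds raw score."""
    crit = resolve_instrument(instrument)
    if not (crit.scale_min <= raw <= crit.scale_max):
        raise ValueError(
            f"{crit.instrument}: score {raw} outside bounds "
            f"[{crit.scale_min}, {crit.scale_max}]"
        )
    n = len({iv.order for iv in crit.intervals if iv.order >= 0})
    for iv in crit.intervals:
        if iv.lo <= raw <= iv.hi:
            if crit.continuous:
                return InterpretedScore(
                    crit.instrument, raw, iv.label, _tercile_indication(crit, raw), -1, 0
                )
            if iv.order == 0:
                indication = NOT_FRAIL
            elif iv.order == n - 1:
                indication = FRAIL
            else:
                indication = INTERMEDIATE
            return InterpretedScore(crit.instrument, raw, iv.label, indication, iv.order, n)
    # only caution-flagged instruments have gaps between printed anchors
    return InterpretedScore(
        crit.instrument, raw, "unmapped (interpret with caution)", UNMAPPED, -1, n
    )


def map_to_rockwood(interpreted: InterpretedScore) -> Optional[tuple[int, int]]:
    """Rockwood band (inclusive 1-9 range) for an interpreted score.

    Least-frail category -> (1, 3); most-frail -> (7, 9); everything
    between -> (4, 6). Unmapped interpretations have no band.
    """
    if interpreted.indication == NOT_FRAIL:
        return _BANDS["low"]
    if interpreted.indication == FRAIL:
        return _BANDS["high"]
    if interpreted.indication == INTERMEDIATE:
        return _BANDS["middle"]
    return None


_NUMBER_RE = r"(\d+(?:\.\d+)?)"
_SEP_RE = r"(?:\s*(?::|=|-|of|score|scored|total|today|is|was)\s*)*\s*"


def parse_instrument_mention(text: str) -> list[tuple[str, float]]:
    """Recognize instrument-name-plus-score mentions in free text.

    Matches any known instrument alias followed (within a short separator)
    by a number inside that instrument's scale bounds; out-of-bounds
    numbers are ignored.
    """
    table = criteria()
    alias_map: dict[str, InstrumentCriteria] = {}
    for crit in table.values():
        for a in crit.aliases:
            alias_map[a.lower()] = crit
    alias_pat = "|".join(
        re.escape(a) for a in sorted(alias_map, key=len, reverse=True)
    )
    pattern = re.compile(
        rf"(?<![a-z0-9])({alias_pat}){_SEP_RE}{_NUMBER_RE}", re.IGNORECASE
    )
    out: list[tuple[str, float]] = []
    for m in pattern.finditer(text):
        crit = alias_map[m.group(1).lower()]
        value = float(m.group(2))
        if crit.scale_min <= value <= crit.scale_max:
            out.append((crit.instrument, value))
    return out
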