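# ccfo — cardiac-centered frailty ontology toolkit

Frailty — diminished reserve across mobility, self-care, energy, mood and
cognition — drives decisions between open cardiac surgery, transcatheter
procedures and medical management, yet it is documented in free-text
clinical notes far more often than in structured instrument scores.
`ccfo` is an executable toolkit around a compact cardiac-centered frailty
ontology for clinical-NLP researchers and informaticists who need to turn
narrative notes into comparable frailty measurements:

* **Ontology model** — a hierarchy of *clinical finding* concepts with
  opaque CCFOIDs, SNOMED-CT identifiers where an exact mapping exists, a
  term lexicon (terms indicate that the author was thinking of a concept;
  they are not synonyms), 12 qualifier values on four axes
  (able / with difficulty / unable; high / mid frequency; absent;
  chronic / short duration / sudden onset), and per concept-qualifier
  Rockwood Clinical Frailty Scale scores (1 very fit … 9 terminally ill)
  with low/medium/high ratings of cardiac relevance and fix-ability.
  Plain-TSV fixture of record; OWL (RDF/XML) and XLSX are exchange
  dialects.
* **Concept extraction** — deterministic lexicon NER: longest-match term
  lookup, nearest-cue qualifier and course resolution within the
  sentence, cue-window negation, with character-offset provenance.
* **Instrument scoring** — data-driven rule sets computing the Katz ADL
  count (0–6), the Barthel index (published scale 0–20; the printed rules
  reach 19) and the eight SF-36 sections (0–100) directly from extracted
  findings, with per-item coverage.
* **Instrument interpretation** — printed score criteria for ten
  instruments (Morse, Tinetti, Braden, FIM, Katz, 0–100 Barthel, IADL,
  Lawton, FAQ, ADL screen): category, frailty indication, Rockwood band.
* **Frailty profile** — group-wise maximum Rockwood aggregation over
  seven concept groups, the feature row used by downstream outcome
  models.
* **Synthetic notes** — a seeded generator of gold-annotated,
  snippet-style notes for end-to-end testing without any clinical data.

## Worked example

```python
import ccfo

ont = ccfo.load_in_paper_ontology()
note = ("Pt is wheelchair bound. Needs help with bathing; toileting: unable. "
        "Denies pain. Fatigue daily.")
findings = ccfo.extract_findings(ont, note)
for f in findings:
    print(f.concept_id, ont.concepts[f.concept_id].name, f.qualifier, f.assertion)
```

```
1121223 wheelchair bound finding unqualified asserted
112441 able to perform bathing activity finding with-difficulty asserted
112444 able to perform toileting activity finding unable asserted
1111 alteration in comfort: pain finding absent negated
132222 lack of energy finding high-frequency asserted
```

The denied pain mention keeps its negated assertion but carries the
*absent* qualifier, so it counts as evidence of intactness. Scoring and
aggregating the same findings:

```python
print(ccfo.score_barthel(findings, ont).total)        # 2.0  (bathing 1 + mobility 1)
print(ccfo.score_sf36(findings, ont).total["pain"])   # 100.0 (pain denied)
print(ccfo.aggregate_profile(findings, ont).overall)  # 6.0  (wheelchair-bound Rockwood)
```

Barthel earns 1 point for with-difficulty bathing and 1 for the
wheelchair-bound rung of the mobility ladder; unable toileting scores 0;
the remaining items have no evidence, which the result's `coverage`
field reflects. The frailty profile takes the per-group maximum of the
concept-level Rockwood scores — here 6, from the wheelchair-bound
finding in the ability-to-move group.

The same operations are exposed on the command line:

```sh
ccfo simulate --n 10 --seed 7 --profile independent --out notes/
ccfo score notes/note_0000.txt
ccfo interpret --instrument braden --score 8
```

## Layout

```
src/ccfo/ontology.py           data model, TSV fixture IO, validation
src/ccfo/owl.py                OWL (RDF/XML) import/export
src/ccfo/xlsx.py               concept-list workbook reader
src/ccfo/synthetic_fixture.py  synthetic stand-in at the published full size
src/ccfo/extraction.py         lexicon NER + qualifier/negation resolution
src/ccfo/scoring.py            Katz / Barthel / SF-36 rule engine
src/ccfo/interpretation.py     raw-score criteria for ten instruments
src/ccfo/frailty.py            Rockwood lookup and group-wise aggregation
src/ccfo/synthetic.py          gold-annotated note generator
src/ccfo/data/                 fixture and rule tables (TSV/YAML)
docs/methods.md                model, parameters, design notes, limitations
```
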