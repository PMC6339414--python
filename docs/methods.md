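# Methods

## The ontology model

The toolkit models frailty documentation as *clinical findings* in the
OGMS sense: a finding is the clinician's recorded conclusion, not the
patient's body state. Concepts form a tree rooted at *clinical finding*
(history, instrument and physical-examination branches plus a
demographics branch), a small *diagnosis* root for anxiety/depression
mentions, and a *qualifier values* root. Identifiers (CCFOIDs) are
prefix-structured strings but are treated as opaque: the hierarchy comes
from an explicit parent column, never from digit-prefix parsing. SNOMED-CT
identifiers are carried as annotations only, and only where the ontology
means exactly what SNOMED-CT means — upper-level classes such as
*clinical finding* or *physical function finding* deliberately carry none.

Each document-expected concept declares the qualifier axis it takes in
text: **ability** (able / with difficulty / unable), **frequency**
(high / mid / absent) or **none** (single-level findings such as
bed-ridden). Any finding may additionally take a clinical-course value
(chronic / short duration / sudden onset). The *absent* value contrasts
with every axis, mirroring its use in the instrument rules (an
absent-qualified transfer finding is scoreable Barthel evidence).

The fixture of record is plain TSV (concepts, terms, scores, excluded
terms, aggregation groups) for easy diffing and testing; OWL (RDF/XML)
and an XLSX concept-list workbook are import/export dialects that
round-trip through the same in-memory model.

Three printed identifier collisions are resolved in the fixture
(dyspnea-on-exertion keeps 131 and comorbid-condition-count moves to
1326; continence moves to 11272 beside incontinence 11271; ability-to-
drive-a-car moves to 112411 under community-living 11241), and "supine"
stays on the excluded-ambiguous-term list rather than in the bed-ridden
lexicon. Rater-tie relevance codes ("TIED L+H", "TIED M+") are stored
verbatim; collapsing them would erase documented disagreement.

### The synthetic full-size fixture

The shipped in-paper fixture (97 concepts, 145 terms) contains every
concept, identifier, term and score printed in the source tables. The
complete 156-concept ontology is distributed as a spreadsheet supplement
that this repository does not ship; `synthetic_fixture.py` builds a
clearly-labelled synthetic stand-in by padding the in-paper fixture with
filler concepts/terms until the published shape is reached (156 concepts,
86 document-expected, 12 qualifier values, terms-per-concept distribution
24/29/7/8/6/5/0/3/4 over 1..8/>8 terms). The published totals are not
mutually consistent: that distribution forces at least 258 terms over the
86 document-expected concepts, while the headline total printed alongside
it is 246. The stand-in reproduces the distribution, and therefore
carries 258 terms; the corresponding 246-term check in the acceptance
suite fails by construction and is retained as a documented discrepancy.

## Extraction

Extraction is rule-based and fully deterministic:

1. **Sentence segmentation** on `.`, `;` and newlines. The source
   material is snippet-sized, so sentence-local context suffices.
2. **Normalization**: lowercase, whitespace runs collapsed, punctuation
   kept as token boundaries, with a total monotone offset map back to
   the original text (all reported spans index the source document).
3. **Term matching**: greedy leftmost-longest match over the lexicon at
   word boundaries (boundaries admit `/` so "w/c" matches). Excluded
   ambiguous surfaces ("dressing", "supine", "working", "eating",
   "strength", "incontinence") are not in the lexicon and can never
   match; multi-word terms containing them ("difficulty dressing") still
   can.
4. **Qualifier/course resolution**: terms that assert their own level
   ("unable to run", "steady gait") win outright; otherwise the nearest
   in-sentence cue on the concept's axis within a 5-token window is
   used, a preceding cue winning exact-distance ties (qualifiers and
   negations typically precede in clinical English). Course cues
   (chronic/longstanding; brief/transient; sudden/acute) resolve
   independently. Cue lexicons and windows ship as editable YAML.
5. **Assertion**: a finding is negated iff a negation cue ("no",
   "denies", "without", "not") precedes it within 5 tokens in the same
   sentence. On frequency-axis concepts, "no"/"denies"/"never" also set
   the *absent* qualifier, so "denies fatigue" yields a finding that is
   negated at the mention level yet scoreable as evidence of intactness.

The nearest-cue tie-break and the 5-token windows are package
conventions chosen to match common clinical-NLP practice; the source
does not specify how its systems adjudicated competing cues.

## Instrument scoring

Katz, Barthel and SF-36 are computed from findings via a rule table
(TSV): each row maps one or two (concept-or-subtree, qualifier set,
optional course) patterns to a point value within an item. Semantics:

* duplicates collapse before scoring (rules are stated over findings
  present, not mention counts);
* conflicting evidence is resolved pessimistically — among matching rows
  of an item the lowest point value wins (clinically conservative and
  deterministic);
* "both kinds" of continence requires explicit urinary and bowel
  evidence (child concepts); a kind-unspecified incontinence mention
  satisfies the either-kind penalty rule only;
* items with no matching row are *uncovered*: they contribute nothing to
  Katz/Barthel totals and lower coverage; an SF-36 section whose blocks
  are all uncovered reports no score rather than zero, and covered
  blocks are averaged with weights equal to their question counts (a
  three-question block contributes its printed 0–300 total at weight 3).

The printed Barthel rules sum to at most 19 against a published 0–20
scale; results expose both (`rule_sum_max` vs `scale_max`) and never
rescale. The printed SF-36 grids are partial: some qualifier
combinations (e.g. mid-frequency pain with unable daily-routine) match
no row. A consequence, surfaced by property testing, is that improving
one finding of a conjoined pair can newly cover a low-valued block and
move an evidence-weighted section average toward it; monotonicity under
qualifier improvement therefore holds per item and, for sections, holds
whenever the covered-block set is unchanged.

## Interpretation of raw instrument scores

Criteria for ten instruments ship as a TSV of closed integer intervals
taken from the printed prose (Morse ≥45 high fall risk; Tinetti <19 high
risk out of 28; Braden 19–23 no risk down to ≤9 very high risk; the
seven FIM levels; Katz 6/0 anchors; the 0–100 Barthel variant at 70;
IADL per-item 2/1/0; Lawton 0–8; FAQ ≥5; the ADL screen). Where the
printed criteria leave gaps, the package completes them as explicit
conventions: Katz 1–5 is "partially dependent", Tinetti 25–28 "low fall
risk". Bounds the source omits come from the published instruments
(Morse max 125, Braden min 6, FAQ max 30). The ADL-screen row is
internally inconsistent as printed and is stored verbatim with a
caution flag — unanchored scores interpret as unmapped rather than being
silently corrected. A bare "IADL: n" resolves to the Lawton 0–8 total
scale, the more common reading of an unadorned mention.

Rockwood banding — least-frail category to 1–3, most-frail to 7–9,
everything between to 4–6, terciles of scale position for instruments
with no printed categories — is a package convention; the source states
the score-to-Rockwood relation exists without printing a crosswalk.

## Frailty profile

Concept-qualifier pairings from the score table carry rater-averaged
Rockwood values kept as reals (7.44 stays 7.44). Asserted findings are
aggregated over seven groups (seen-by-professional, physical
examination, activity-exercise pattern, ability to move, activities of
daily living, eating/feeding/drinking, social and personal history),
membership by subtree descent; each group reports the maximum Rockwood
among its scored findings, or no-evidence. Pairings without a printed
score (blank cells, able/absent-deficit levels) are unscored and never
interpolated; negated findings never contribute.

## Synthetic notes

The generator renders planned findings as telegraphic single-finding
sentences built from the ontology's own lexicon and the extractor's cue
vocabulary, so gold annotations (concept, qualifier, course, assertion,
character span) are exact by construction and extraction is expected to
reproduce them with recall = precision = 1.0. Named profiles cover the
instrument loops: *independent* renders the full Katz antecedent set
(such notes score 6), *frail* the fully dependent set, *mixed* samples
concepts and axis-valid qualifiers at random. Per-note negation and
distractor probabilities default to 0; distractor sentences contain only
excluded ambiguous terms and add no gold. A single integer seed fixes
all sampling; identical specs are byte-identical.

What the generator does **not** emulate: real note formatting (headers,
templates, abbreviations beyond the lexicon), misspellings, cue phrasings
outside the configured vocabulary, co-referential or cross-sentence
context, and realistic concept co-occurrence. Perfect loop metrics
therefore certify the internal consistency of lexicon, cues, extractor
and scorer — not expected performance on clinical text.

## Problem sizes and numerics

Default test and acceptance runs use a 200-note mixed corpus (4 findings
per note, negation rate 0.2, distractor rate 0.3), exhaustive
enumeration for the Katz oracle (3^5 qualifier ladders × 3 continence
states) and brute-force subsets up to 6 findings for aggregation —
small enough to hand-check, large enough to exercise every rule row.
All scores are exact rational arithmetic over small integers apart from
SF-36 averages and fractional Rockwood means, where standard float
division is used; no tolerances are needed beyond float equality on
sums of halves and quarters.

## Known limitations

* Term and cue lexicons reflect only printed content plus minimal
  additions needed to make every rule antecedent reachable from text;
  real-world coverage would require corpus-driven expansion.
* Negation handling is a preceding-cue window, not scope parsing;
  post-coordinated negation ("fatigue was not observed") is missed.
* Only Katz, Barthel and SF-36 have finding-driven rule sets; the other
  reviewed instruments are interpretation-only by design.
* The statistical systems reported alongside the ontology (snippet
  classifier, mortality network) are out of scope; the frailty profile
  is the feature such models consume, nothing more.
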