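# nomenmatch

Fuzzy alignment of botanical scientific names to a reference checklist of
accepted names and synonyms.

Anyone digitizing herbarium labels, old floras or vegetation relevés faces
the same two problems: scientific names are typed with typos ("Achillea
milefolius"), and they are often outdated synonyms of the currently
accepted name. `nomenmatch` solves both with a reusable library plus a
small CLI:

- an **interactive near-match** that corrects a partial query string
  ("officialis", "lantus alt") to the closest substring of any reference
  name, never touching the blanks the user typed and changing the length by
  at most one character;
- a **batch list resolver** that normalizes, parses and fuzzily matches
  whole lists of names — binomials and trinomials with up to two
  infraspecific levels — against the checklist, resolving synonyms to their
  accepted names and reporting a score for every match.

## The matching model

Every name is parsed into components: genus, species epithet, species
authority, then up to two *(rank indicator, epithet, authority)* groups
(`subsp.`, `var.`, `f.`, `cv.`).  Each Latin component of the input is
compared to the reference both **orthographically** — a modified
Damerau–Levenshtein distance (MDLD) in which two adjacent blocks of up to
two characters may be swapped at the cost of the block length, so
*canadsiens* → *canadensis* costs 2 rather than the Levenshtein 4 — and
**phonetically**, via an uppercase key that collapses common mis-hearings
of Latin (*Huperzia* → `HIPIRSA`, *selago* → `SILAGA`).  A candidate must
pass at least one of the two tests per component.

Each component is scored

```
ComponentScore = 1 − ED / maxED
```

with `maxED` the length of the longer string; an infraspecific component
loses 0.3 when its rank indicator is wrong (`var.` where the reference has
`subsp.`).  The *TaxonScore* is the mean of the component scores, author
citations contribute a character-bigram Dice similarity (*AuthorScore*),
and the final score is

```
ReturnedScore = (TaxonScore × 0.9 + AuthorScore × 0.1) × 100
```

A name identical to a reference entry short-circuits to 100.  Results are
classified **exact**, **unambiguous**, **ambiguous** (top candidates within
5 points of each other; the user should choose) or **none** (nothing at or
above the score threshold, default 70).

The parser is case-sensitive by default but drops to a case-insensitive
mode for all-uppercase/lowercase input, and the notorious single-letter
tokens `f.`, `v.`, `s.`, `c.` — author abbreviation (filius) or rank
indicator? — are resolved by pattern rules, flagged when undecidable, and
re-examined after matching against the authorities of the candidate
matches.

## Worked example

```python
from nomenmatch import build_thesaurus, match_name, nearest_query_match

thesaurus = build_thesaurus([
    ("Achillea millefolium L.", "accepted", ""),
    ("Calendula officinalis L.", "accepted", ""),
    ("Galega officinalis L.", "accepted", ""),
    ("Achillea sudetica Opiz", "synonym", "Achillea millefolium L."),
])

r = match_name("Achillea milefolius L.", thesaurus)
print(r.status, round(r.candidates[0].score, 2), r.accepted_name)
# unambiguous 91.82 Achillea millefolium L.

r = match_name("Achillea sudetica Opiz", thesaurus)
print(r.status, r.synonym_name, "->", r.accepted_name)
# exact Achillea sudetica Opiz -> Achillea millefolium L.

c = nearest_query_match("officialis", thesaurus)
print(c.corrected, c.edit_cost, len(c.matched_entries))
# officinalis 1 2
```

The 91.82 decomposes as: genus ED 0 (score 1.0), species MDLD 2 over
maxED 11 (score 0.8182), authority identical (1.0) — so
`(mean(1.0, 0.8182) × 0.9 + 1.0 × 0.1) × 100 ≈ 91.82`.

From the shell:

```bash
nomenmatch synth --n-accepted 200 --seed 1 --checklist-out checklist.csv
nomenmatch build --checklist checklist.csv --out thesaurus.tsv
nomenmatch match --thesaurus thesaurus.tsv --input names.txt --out results.csv
nomenmatch query --thesaurus thesaurus.tsv "officialis"
```

`match` prints the summary tallies (exact / unambiguous / ambiguous / none)
and writes a four-column CSV: `original_name, accepted_name, synonym,
score` — the synonym column is filled only when the hit was a synonym, and
ambiguous rows carry the top candidate with an asterisked score.

No real checklist ships with the package: `nomenmatch.synthdata` generates
seeded pseudo-Latin checklists and corrupted query lists so every
experiment is reproducible and closed-loop.

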