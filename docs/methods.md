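# Methods

This note documents the models, rules and numerical choices behind
`nomenmatch`, and what the synthetic-data experiments do and do not show.

## Normalization

Input strings are reduced to the character inventory a botanical name can
legally contain, in a fixed order: (a) quote-like and emphasis characters
(`? ! # " ' " "`) are deleted and underscores become blanks (deleting them
would glue `Genus_species` into one token); (b) digits are deleted (the
reference side carries no years); (c) diacritics fold to ASCII via Unicode
canonical decomposition, with `ø→o`, `ß→ss`, `œ→oe`, `æ→ae` special-cased
because they do not decompose; (d) a blank is inserted after every dot not
already followed by one — except before `)` and `,`, so `(L.)` survives;
(e) the uncertainty tokens `cf.`/`aff.` (dot optional, case-insensitive)
are dropped as standalone tokens, with `cfr.` behind an off-by-default
option; (f) blanks collapse and trim.  Any remaining character outside
`[A-Za-z .()&,-]` becomes a blank.  The function is total and idempotent.
`s.n.`-style collector markers are left alone; hybrid signs (`×`) and
`sp./spp.` placeholders are not treated specially.

## Parsing

Token classification: first token = genus; the second token is the species
epithet when it is purely alphabetic and longer than one letter (capitalized
epithets are accepted and lowered, since real-world lists violate the
capitalization convention); everything up to the first recognized rank
indicator is the species authority (parenthesized basionym authors, `ex`,
`&`, `in` stay inside it); then at most two *(rank indicator, epithet,
authority)* groups.  Third and later groups are absorbed into the preceding
authority.

Rank indicators are recognized from alias tables — subspecies
`{subsp, ssp, subspecies}`, variety `{var, varietas, v}`, form
`{f, fo, forma}`, cultivar `{cv}` — after dot-stripping and case-folding,
and tokens of three or more letters also match at Levenshtein distance 1
(`susp` → subspecies).  The length-3 floor exists because at distance 1
every single letter would collide with the one-letter aliases `f`/`v`
(`L.` must remain an authority).  A distance tie between two ranks is never
guessed: the token is left unresolved with a warning.  Users may register
extra aliases per rank; these are consulted first.  The single letters `s`
and `c` participate only when registered this way — they are too common in
author strings to be trusted by default — while `f` and `v` are active out
of the box.

**The filius problem.**  A dotted single letter in `{v, f, s, c}` sitting
after the species epithet can be an author fragment (`L. f.` = Linnaeus
filius) or a rank indicator.  In case-sensitive mode: preceded by an author
token (capitalized word or closing parenthesis) *and* followed by a
capitalized token → authority; followed by a lowercase epithet-like token
(and not the former) → rank indicator; conflicting or absent signals → the
token is provisionally read as a rank indicator and the parse is flagged.
In case-insensitive mode the signals do not exist, so such tokens always
flag.  Flagged names get a post-match verification: if the best candidate
agrees at the infraspecific level (MDLD < 2) nothing happens; otherwise, if
the flagged token occurs in the authority of a candidate that passed the
species-epithet match and the following words agree (equal, or same first
letter at MDLD 1), the token is re-read as authority and the tail
re-parsed.

Case-insensitive mode engages when every alphabetic character has the same
case, or on user request.  It recapitalizes: genus initial-capital,
epithets lowercase, authorities title-cased per token with
`ex/in/et` kept lowercase.

## String metrics

*Levenshtein* is the textbook rolling-row DP.  *MDLD* extends it with a
swap of two adjacent blocks of up to `block_limit` (default 2) characters
each, costing the length of the longer block; swapped blocks are consumed
whole (not re-editable), making the recurrence a strict generalisation of
the optimal-string-alignment Damerau–Levenshtein, which it equals at
`block_limit 1`.  Unequal block lengths are permitted at cost
`max(k1, k2)`.  MDLD never exceeds Levenshtein.

*Author similarity* is a Dice coefficient over the multisets of character
bigrams of the case-folded, punctuation-stripped, blank-collapsed author
strings; equal non-empty strings score 1, strings sharing no bigram score
0.  Punctuation is stripped before bigram extraction so that abbreviation
dots do not manufacture similarity between unrelated authors (`L.` vs
`Mill.` must be 0).  When exactly one side has an authority the score is 0;
when both are empty it is 1, so bare binomial against bare binomial stays
perfect.

*Phonetic key*: uppercase, first letter preserved, then — iterated to a
fixed point — drop `H` after the first position, digraphs `AE→I, IA→A,
OE→I, OI→A`, vowels `E→I, O→A, U→I`, consonants `Z→S, K→C`, and collapse
letter runs.  The fixed-point iteration guarantees idempotence (a vowel
substitution can create a new digraph).  The table is a reconstruction
around two hard pins, `Huperzia → HIPIRSA` and `selago → SILAGA`; the
remaining rules are test-pinned so any refinement is visible.

## Matching and scoring

Candidate generation is staged: genera passing MDLD ≤ 2 (with a
length-difference pre-filter) *or* phonetic-key equality; within survivors,
species epithets with MDLD ≤ 3 or key equality; infraspecific epithets
likewise.  The caps are fixed (not length-dependent) and configurable;
they are sized for epithets averaging 8–11 characters.  Authorities never
filter.  A linear scan over the checklist is deliberate: at the ~24k-name
scale of a national flora an index structure buys nothing.

Scores follow `ComponentScore = 1 − ED/maxED` per component (ED always the
MDLD, even for phonetic-only hits), a 0.3 deduction — floored at 0 to keep
scores in [0, 1] — for a wrong rank indicator (none when the input rank is
unknown), `TaxonScore` = mean of the component scores, and
`ReturnedScore = (TaxonScore × 0.9 + AuthorScore × 0.1) × 100`.  A level
present on only one side (binomial vs trinomial) contributes a component
score of 0 to the mean but does not eliminate the candidate — a
conservative choice that lets a corrupted trinomial still find its binomial
parent while ranking the exact-depth entry first.

Classification: *exact* when the normalized input equals a reference full
name (case-insensitively when the input is uniform-case or the option is
forced); *none* when no candidate reaches the threshold (default 70, range
1–100; at 100 only perfect matches survive); *unambiguous* when the top
candidate is alone or leads by at least the ambiguity margin (default 5
returned-score points); *ambiguous* otherwise, retaining all candidates.
Ties are broken by entry id, so runs are reproducible.  Synonym hits
resolve to their accepted entry in one hop.

## Query near-match

The interactive corrector scans every window of length `len(query) ± 1` of
every reference name with a blank-locked banded edit distance: blanks align
only to blanks, and are never inserted, substituted or deleted.  Costs are
capped (default 2 edits, configurable) with early exit.  Among equal-cost
corrections the one contained in the most entries wins, then lexicographic
order.  Comparison is case-insensitive throughout; the corrected string is
reported case-folded.

## Synthetic data

The generator emulates an ICN-style checklist: pseudo-Latin genera and
epithets from syllable inventories (mean epithet length 8–11), authorities
drawn from a pool that includes parenthesized basionyms and filius-style
`f.` citations, a configurable infraspecific fraction (default 0.2) and
synonym fraction (default 0.3, echoing the roughly 55:45
accepted-to-synonym ratio of a real national checklist), all reproducible
from a seed and collision-checked for unique full names.  Corruption
operators (substitution, insertion, deletion, transposition, whole-string
case-folding, rank-indicator swaps) log every edit together with the source
entry, so recovery experiments are exact.  Three list profiles mirror
common input styles: A (no authorities, `s.` as the subspecies indicator),
B (entirely uppercase), C (code-compliant).

What this does *not* show: synthetic epithets are uniformly random, so the
near-collision structure of real floras (congeneric epithet pairs like
*alpina*/*alpestris*, orthographic variants) is underrepresented; real
recovery rates will be lower than the synthetic ones.  Published
effectiveness percentages from real datasets are not reproduced here —
those lists are not publicly deposited — which is why the acceptance
checks are property-based (verbatim feedback must be 100 % exact, single
substitutions must recover their source ≥ 95 % of the time, threshold 100
must return only exact matches, disabling phonetics must never add
candidates).

## Problem sizes and determinism

The test suite builds checklists of 120–1,000 accepted names and runs
1,000-name recovery experiments; the exhaustive MDLD-vs-oracle check covers
all string pairs of length ≤ 5 over a three-letter alphabet, with the
block-limit-1 equivalence to Damerau–Levenshtein exhaustive at length ≤ 4
plus a seeded length-≤ 6 sample.  All randomness is seeded; property tests
run derandomized.  `scripts/acceptance.py --seed N` drives every stochastic
input from the given seed.

## Known limitations

- Hybrid formulas (`×`), `sp.`/`spp.` placeholders and nomenclatural
  validation are out of scope.
- Homonymous accepted full names keep the first occurrence (warned);
  the storage policy for true homonyms in a real checklist is unresolved.
- The second infraspecific authority is delimited only by the next rank
  indicator; exotic authority strings containing rank-alias lookalikes
  (an author named *Forman* followed by an alphabetic token) can misparse.
- The phonetic encoder is a documented reconstruction, not a byte-level
  replica of any historical implementation.
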