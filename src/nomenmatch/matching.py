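"""Candidate generation, dual orthographic/phonetic matching and classification.

Matching a parsed input name against the thesaurus runs in stages: genera
that pass either an MDLD cap or phonetic-key equality survive stage 1;
within those, species epithets face the same dual test, then infraspecific
epithets (with the wrong-rank penalty).  Author citations never filter —
they only contribute their n-gram similarity to the final score.  A
component with no counterpart (the input is a trinomial, the candidate a
binomial, or vice versa) scores 0 but does not eliminate the candidate.

Names flagged by the parser as carrying an ambiguous rank token ("f." and
friends) get a second chance after matching: if the token shows up inside a
candidate's authority and the word following it agrees between input and
candidate, the token is re-read as part of the authority and the name
re-matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nameparse import ParsedName, ParseError, is_uniform_case, parse_name, reparse_as_authority
from .options import MatchOptions
from .scoring import (
    ComponentRecord,
    ScoreBreakdown,
    apply_rank_penalty,
    component_score,
    returned_score,
    taxon_score,
)
from .strmetrics import mdld, ngram_similarity
from .textnorm import normalize_string
from .thesaurus import ReferenceEntry, Thesaurus

__all__ = [
    "MatchCandidate",
    "MatchResult",
    "match_parsed_name",
    "species_level_candidates",
    "reparse_authority_check",
    "classify_result",
    "match_name",
]

STATUS_EXACT = "exact"
STATUS_UNAMBIGUOUS = "unambiguous"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NONE = "none"


@dataclass(frozen=True)
class MatchCandidate:
    entry_id: str
    breakdown: ScoreBreakdown
    #: per-component outcome of the dual test: orthographic | phonetic | both
    matched_via: dict[str, str] = field(default_factory=dict)

    @property
    def score(self) -> float:
        return self.breakdown.returned_score


@dataclass(frozen=True)
class MatchResult:
    raw_input: str
    normalized: str
    status: str
    candidates: tuple[MatchCandidate, ...] = ()
    chosen: str = ""
    accepted_name: str = ""
    synonym_name: str = ""
    note: str = ""


def _author_similarity(input_auth: str, entry_auth: str) -> float:
    if not input_auth and not entry_auth:
        return 1.0
    if not input_auth or not entry_auth:
        return 0.0
    return ngram_similarity(input_auth, entry_auth)


def _dual_test(
    a: str,
    b: str,
    key_a: str,
    key_b: str,
    cap: int,
    options: MatchOptions,
) -> tuple[bool, int, str]:
    """Run the orthographic + phonetic test on one component pair.

    Returns (passed, ed, via).  The orthographic test is an MDLD cap with a
    cheap length-difference pre-filter; the phonetic test is key equality
    (only when phonetics are enabled).
    """
    a, b = a.lower(), b.lower()
    ed = mdld(a, b, options.mdld_block_limit)
    ortho = abs(len(a) - len(b)) <= cap and ed <= cap
    phon = options.phonetic_enabled and bool(key_a) and key_a == key_b
    via = "both" if (ortho and phon) else "orthographic" if ortho else "phonetic" if phon else ""
    return (ortho or phon), ed, via


def _score_entry(
    parsed: ParsedName,
    entry: ReferenceEntry,
    options: MatchOptions,
    *,
    infra_strict: bool,
    genus_rec: tuple[int, str],
) -> MatchCandidate | None:
    """Score one stage-1 survivor; None if a dual test eliminates it."""
    ep = entry.parsed
    records: list[ComponentRecord] = []
    via: dict[str, str] = {}

    g_ed, g_via = genus_rec
    records.append(
        ComponentRecord("genus", g_ed, max(len(parsed.genus), len(ep.genus)),
                        component_score(g_ed, len(parsed.genus), len(ep.genus)),
                        phonetic_hit="phonetic" in g_via or g_via == "both")
    )
    via["genus"] = g_via

    in_sp, ref_sp = parsed.species_epithet, ep.species_epithet
    if in_sp and ref_sp:
        ok, ed, sp_via = _dual_test(in_sp, ref_sp, parsed.species_phonetic, ep.species_phonetic,
                                    options.epithet_ed_cap, options)
        if not ok:
            return None
        records.append(
            ComponentRecord("species", ed, max(len(in_sp), len(ref_sp)),
                            component_score(ed, len(in_sp), len(ref_sp)),
                            phonetic_hit=sp_via in ("phonetic", "both"))
        )
        via["species"] = sp_via
    elif in_sp or ref_sp:
        # present on one side only: scores 0, does not eliminate
        length = len(in_sp or ref_sp)
        records.append(ComponentRecord("species", length, length, 0.0))

    n_levels = max(len(parsed.infra), len(ep.infra))
    for k in range(n_levels):
        name = f"infra{k + 1}"
        in_part = parsed.infra[k] if k < len(parsed.infra) else None
        ref_part = ep.infra[k] if k < len(ep.infra) else None
        if in_part is not None and ref_part is not None:
            ok, ed, i_via = _dual_test(in_part.epithet, ref_part.epithet,
                                       in_part.epithet_phonetic, ref_part.epithet_phonetic,
                                       options.epithet_ed_cap, options)
            if not ok and infra_strict:
                return None
            score = component_score(ed, len(in_part.epithet), len(ref_part.epithet))
            penalized = apply_rank_penalty(score, in_part.rank, ref_part.rank)
            records.append(
                ComponentRecord(name, ed, max(len(in_part.epithet), len(ref_part.epithet)),
                                penalized, phonetic_hit=i_via in ("phonetic", "both"),
                                rank_penalty_applied=penalized != score)
            )
            via[name] = i_via
        else:
            part = in_part or ref_part
            assert part is not None
            length = len(part.epithet)
            records.append(ComponentRecord(name, length, length, 0.0))

    author = _author_similarity(parsed.all_authorities(), ep.all_authorities())
    taxon = taxon_score([r.component_score for r in records])
    breakdown = ScoreBreakdown(tuple(records), taxon, author, returned_score(taxon, author))
    return MatchCandidate(entry.entry_id, breakdown, via)


def _generate(
    parsed: ParsedName,
    thesaurus: Thesaurus,
    options: MatchOptions,
    *,
    threshold: int | None,
    infra_strict: bool,
) -> list[MatchCandidate]:
    genus = parsed.genus.lower()
    genus_cache: dict[str, tuple[bool, int, str]] = {}
    out: list[MatchCandidate] = []
    for entry_id in thesaurus.entries:
        entry = thesaurus.entries[entry_id]
        eg = entry.parsed.genus.lower()
        cached = genus_cache.get(eg)
        if cached is None:
            ok, ed, via = _dual_test(genus, eg, parsed.genus_phonetic, entry.parsed.genus_phonetic,
                                     options.genus_ed_cap, options)
            cached = genus_cache[eg] = (ok, ed, via)
        ok, ed, via = cached
        # phonetic equality must be re-checked per entry only if keys differ per
        # genus spelling; identical spellings share identical keys, so the cache
        # is sound.
        if not ok:
            continue
        cand = _score_entry(parsed, entry, options, infra_strict=infra_strict, genus_rec=(ed, via))
        if cand is None:
            continue
        if threshold is not None and cand.score < threshold:
            continue
        out.append(cand)
    out.sort(key=lambda c: (-c.score, c.entry_id))
    return out


def match_parsed_name(
    parsed: ParsedName, thesaurus: Thesaurus, options: MatchOptions | None = None
) -> list[MatchCandidate]:
    """All thesaurus candidates for ``parsed`` at or above the score threshold,
    sorted by returned score (ties broken by entry id)."""
    options = options or MatchOptions()
    return _generate(parsed, thesaurus, options, threshold=options.threshold, infra_strict=True)


def species_level_candidates(
    parsed: ParsedName, thesaurus: Thesaurus, options: MatchOptions | None = None
) -> list[MatchCandidate]:
    """Candidates that passed the genus and species-epithet stages.

    No score threshold and no infraspecific filtering — this is the pool the
    flagged-name verification inspects.
    """
    options = options or MatchOptions()
    return _generate(parsed, thesaurus, options, threshold=None, infra_strict=False)


def _strip_token(tok: str) -> str:
    return tok.rstrip(".").casefold()


def _words_agree(a: str, b: str, options: MatchOptions) -> bool:
    """Equal, or same first letter with an MDLD of 1."""
    sa, sb = _strip_token(a), _strip_token(b)
    if sa == sb:
        return True
    return bool(sa and sb) and sa[0] == sb[0] and mdld(sa, sb, options.mdld_block_limit) == 1


def reparse_authority_check(
    parsed: ParsedName,
    survivors: list[MatchCandidate],
    thesaurus: Thesaurus,
    options: MatchOptions | None = None,
) -> ParsedName:
    """Post-match verification of a name flagged for an ambiguous rank token.

    Triggered when the best surviving candidate has an infraspecific epithet
    MDLD >= 2 at the flagged level (or no candidate matches at that level at
    all).  If (a) the flagged token occurs inside the authority of at least
    one candidate that passed the species-epithet match, and (b) the word
    following it in the input agrees with the word following it in that
    authority, the token is re-read as authority and the tail re-parsed.
    Otherwise the parse is returned unchanged.
    """
    options = options or MatchOptions()
    if parsed.parse_flag != "ambiguous_rank_token" or not survivors:
        return parsed
    flagged_idx = next(
        (i for i, p in enumerate(parsed.infra) if p.rank_token == parsed.ambiguous_token), None
    )
    if flagged_idx is None:
        return parsed
    in_part = parsed.infra[flagged_idx]

    best = survivors[0]
    best_entry = thesaurus.entries[best.entry_id]
    if flagged_idx < len(best_entry.parsed.infra):
        ed = mdld(
            in_part.epithet.lower(),
            best_entry.parsed.infra[flagged_idx].epithet.lower(),
            options.mdld_block_limit,
        )
        if ed < 2:
            return parsed

    token = _strip_token(parsed.ambiguous_token)
    input_next = in_part.epithet
    for cand in survivors:
        auth_tokens = thesaurus.entries[cand.entry_id].parsed.all_authorities().split()
        for j, tok in enumerate(auth_tokens):
            if _strip_token(tok) != token:
                continue
            if j + 1 < len(auth_tokens) and _words_agree(input_next, auth_tokens[j + 1], options):
                return reparse_as_authority(parsed, options)
    return parsed


def _exact_breakdown(full_name: str) -> ScoreBreakdown:
    rec = ComponentRecord("full_name", 0, max(len(full_name), 1), 1.0)
    return ScoreBreakdown((rec,), 1.0, 1.0, 100.0)


def classify_result(
    candidates: list[MatchCandidate],
    normalized: str,
    thesaurus: Thesaurus,
    options: MatchOptions | None = None,
    *,
    raw_input: str = "",
    note: str = "",
) -> MatchResult:
    """Turn a candidate list into an exact / unambiguous / ambiguous / none result.

    Exact means the normalized input equals a reference full name (compared
    case-insensitively when the input carries no case information).  A
    unique candidate, or one leading the runner-up by at least the ambiguity
    margin, is unambiguous; several close candidates are ambiguous and all
    are retained for the user.  Hits on synonym entries resolve to their
    accepted name.
    """
    options = options or MatchOptions()
    ci = options.force_case_insensitive or is_uniform_case(normalized)
    exact_ids = thesaurus.lookup_exact(normalized, case_insensitive=ci) if normalized else []
    if exact_ids:
        chosen = sorted(exact_ids)[0]
        entry = thesaurus.entries[chosen]
        cand = MatchCandidate(chosen, _exact_breakdown(entry.full_name), {"full_name": "orthographic"})
        return _finalize(raw_input, normalized, STATUS_EXACT, (cand,), chosen, thesaurus, note)

    if not candidates:
        return MatchResult(raw_input, normalized, STATUS_NONE, (), note=note)
    top = candidates[0]
    if len(candidates) == 1 or top.score - candidates[1].score >= options.ambiguity_margin:
        status = STATUS_UNAMBIGUOUS
    else:
        status = STATUS_AMBIGUOUS
    return _finalize(raw_input, normalized, status, tuple(candidates), top.entry_id, thesaurus, note)


def _finalize(
    raw_input: str,
    normalized: str,
    status: str,
    candidates: tuple[MatchCandidate, ...],
    chosen: str,
    thesaurus: Thesaurus,
    note: str,
) -> MatchResult:
    entry = thesaurus.entries[chosen]
    accepted = thesaurus.accepted_entry(chosen)
    synonym_name = entry.full_name if entry.status == "synonym" else ""
    return MatchResult(
        raw_input=raw_input,
        normalized=normalized,
        status=status,
        candidates=candidates,
        chosen=chosen,
        accepted_name=accepted.full_name,
        synonym_name=synonym_name,
        note=note,
    )


def match_name(raw: str, thesaurus: Thesaurus, options: MatchOptions | None = None) -> MatchResult:
    """Full pipeline for one name: normalize, exact pre-process, parse,
    match (with the flagged-name re-parse when needed), classify."""
    options = options or MatchOptions()
    normalized = normalize_string(raw, treat_cfr_as_uncertain=options.treat_cfr_as_uncertain)
    if not normalized:
        return MatchResult(raw, normalized, STATUS_NONE, note="empty after normalization")

    ci = options.force_case_insensitive or is_uniform_case(normalized)
    if thesaurus.lookup_exact(normalized, case_insensitive=ci):
        return classify_result([], normalized, thesaurus, options, raw_input=raw)

    try:
        parsed = parse_name(normalized, options)
    except ParseError as exc:
        return MatchResult(raw, normalized, STATUS_NONE, note=str(exc))

    candidates = match_parsed_name(parsed, thesaurus, options)
    if parsed.parse_flag == "ambiguous_rank_token":
        survivors = species_level_candidates(parsed, thesaurus, options)
        reparsed = reparse_authority_check(parsed, survivors, thesaurus, options)
        if reparsed is not parsed:
            candidates = match_parsed_name(reparsed, thesaurus, options)
    return classify_result(candidates, normalized, thesaurus, options, raw_input=raw)
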