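"""Decompose a normalized scientific name into classified components.

A botanical name string interleaves Latin components (genus, species
epithet, up to two infraspecific epithets introduced by rank indicators
such as "subsp." or "var.") with author citations ("L.", "(Opiz) Oborny",
"Bernh. ex Schrank & Mart.").  Parsing is case-sensitive by default —
capitalization separates epithets from authors — but falls back to a
case-insensitive mode when the input is entirely upper- or lowercase, or
when the user forces it.

The notorious single-letter tokens "v.", "f.", "s." and "c." can be either
part of an authority (e.g. "L. f." — Linnaeus filius) or a rank indicator
(variety, form, subspecies, cultivar).  Pattern rules resolve most cases;
when they cannot, the token is provisionally treated as a rank indicator
and the parse is flagged so the matcher can re-examine it against the
authorities of its candidate matches ("s." and "c." participate only when
the user has registered them as rank indicators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

from .options import MatchOptions
from .strmetrics import levenshtein, phonetic_key

__all__ = [
    "Rank",
    "is_uniform_case",
    "InfraPart",
    "ParsedName",
    "ParseError",
    "canonical_rank",
    "parse_name",
    "recapitalize",
]


class ParseError(ValueError):
    """Raised when a string cannot be decomposed into name components."""


class Rank(str, Enum):
    SUBSPECIES = "subspecies"
    VARIETY = "variety"
    FORM = "form"
    CULTIVAR = "cultivar"
    UNKNOWN = "unknown"


#: Built-in rank indicator aliases (dot-stripped, lowercase).  "s" and "c"
#: are deliberately absent: they become indicators only via user options.
DEFAULT_RANK_ALIASES: dict[Rank, frozenset[str]] = {
    Rank.SUBSPECIES: frozenset({"subsp", "ssp", "subspecies"}),
    Rank.VARIETY: frozenset({"var", "varietas", "v"}),
    Rank.FORM: frozenset({"f", "fo", "forma"}),
    Rank.CULTIVAR: frozenset({"cv"}),
}

_AMBIGUOUS_LETTERS = {"v": Rank.VARIETY, "f": Rank.FORM, "s": Rank.SUBSPECIES, "c": Rank.CULTIVAR}

#: Tokens kept lowercase when title-casing an authority string.
_AUTHORITY_SMALL_WORDS = {"ex", "in", "et", "&", "and"}


@dataclass(frozen=True)
class InfraPart:
    """One infraspecific level: rank indicator, epithet, optional authority."""

    rank: Rank
    rank_token: str
    epithet: str
    epithet_phonetic: str
    authority: str = ""


@dataclass(frozen=True)
class ParsedName:
    genus: str
    genus_phonetic: str
    species_epithet: str = ""
    species_phonetic: str = ""
    species_authority: str = ""
    infra: tuple[InfraPart, ...] = ()
    parse_flag: str = "clean"  # or "ambiguous_rank_token"
    ambiguous_token: str = ""
    # bookkeeping for the post-match re-parse and reassembly
    tail_tokens: tuple[str, ...] = ()
    flagged_tail_index: int | None = None
    case_insensitive: bool = False

    def reassemble(self) -> str:
        """Join the components back into a single name string."""
        parts = [self.genus]
        if self.species_epithet:
            parts.append(self.species_epithet)
        if self.species_authority:
            parts.append(self.species_authority)
        for p in self.infra:
            parts.append(p.rank_token)
            parts.append(p.epithet)
            if p.authority:
                parts.append(p.authority)
        return " ".join(parts)

    def all_authorities(self) -> str:
        """Every authority string in the name, joined with single blanks."""
        bits = [self.species_authority] + [p.authority for p in self.infra]
        return " ".join(b for b in bits if b)


def _alpha_core(token: str) -> str:
    return "".join(c for c in token if c.isalpha() or c == "-")


def _safe_phonetic(token: str) -> str:
    core = _alpha_core(token).replace("-", "")
    return phonetic_key(core) if core else ""


def _rank_tables(options: MatchOptions) -> dict[Rank, set[str]]:
    tables = {rank: set(aliases) for rank, aliases in DEFAULT_RANK_ALIASES.items()}
    for rank_name, extra in options.rank_aliases.items():
        tables[Rank(rank_name)].update(a.rstrip(".").casefold() for a in extra)
    return tables


def canonical_rank(token: str, options: MatchOptions | None = None) -> Rank | None:
    """Map a rank-indicator token to its rank, tolerating one typo.

    The dot-stripped, case-folded token is looked up in the user's custom
    aliases first, then the built-in tables; tokens of three or more letters
    also match any alias at Levenshtein distance 1 (so "susp" reads as
    subspecies).  A token equidistant from two different ranks yields
    ``None`` with a warning rather than a guess.
    """
    options = options or MatchOptions()
    t = token.rstrip(".").casefold()
    if not t:
        return None
    for rank_name, extra in options.rank_aliases.items():
        if t in {a.rstrip(".").casefold() for a in extra}:
            return Rank(rank_name)
    tables = _rank_tables(options)
    for rank, aliases in tables.items():
        if t in aliases:
            return rank
    if len(t) < 3:
        return None
    hits: dict[Rank, int] = {}
    for rank, aliases in tables.items():
        d = min((levenshtein(t, a) for a in aliases), default=99)
        if d <= 1:
            hits[rank] = d
    if not hits:
        return None
    best = min(hits.values())
    winners = [rank for rank, d in hits.items() if d == best]
    if len(winners) > 1:
        warnings.warn(
            f"rank indicator {token!r} matches several ranks ({[w.value for w in winners]}); "
            "leaving it unresolved",
            stacklevel=2,
        )
        return None
    return winners[0]


def _is_pure_alpha(token: str) -> bool:
    core = token.replace("-", "")
    return bool(core) and core.isalpha()


def _is_capitalized_word(token: str) -> bool:
    for c in token:
        if c.isalpha():
            return c.isupper()
    return False


def _is_lower_epithet(token: str) -> bool:
    return _is_pure_alpha(token) and token.islower()


def _ambiguous_letter(token: str) -> str | None:
    core = token.rstrip(".")
    if len(core) == 1 and core.casefold() in _AMBIGUOUS_LETTERS:
        return core.casefold()
    return None


def _letter_enabled(letter: str, options: MatchOptions) -> bool:
    if letter in {"v", "f"}:
        return True
    # "s." and "c." count as rank indicators only when the user registered them
    for extra in options.rank_aliases.values():
        if letter in {a.rstrip(".").casefold() for a in extra}:
            return True
    return False


def _parse_tail(
    tail: tuple[str, ...],
    *,
    ci: bool,
    options: MatchOptions,
    prev_token: str,
    authority_override: int | None = None,
) -> tuple[str, list[InfraPart], str, str, int | None]:
    """Classify the tokens following the species epithet.

    Returns (species_authority, infra_parts, parse_flag, ambiguous_token,
    flagged_tail_index).  ``authority_override`` forces the token at that
    tail index to be read as an authority part (used by the post-match
    re-parse of flagged names).
    """
    authority_chunks: list[list[str]] = [[]]  # chunk 0: species authority
    parts: list[InfraPart] = []
    flag, flagged_token = "clean", ""
    flagged_index: int | None = None

    i = 0
    prev = prev_token
    while i < len(tail):
        tok = tail[i]
        nxt = tail[i + 1] if i + 1 < len(tail) else None
        rank: Rank | None = None
        ambiguous_here = False

        letter = _ambiguous_letter(tok)
        if letter is not None:
            if authority_override == i or not _letter_enabled(letter, options):
                rank = None
            elif ci:
                # no capitalization signal: cannot decide, flag and read as rank
                rank = _AMBIGUOUS_LETTERS[letter]
                ambiguous_here = True
            else:
                author_signal = (
                    (prev.endswith(")") or _is_capitalized_word(prev))
                    and nxt is not None
                    and _is_capitalized_word(nxt)
                )
                rank_signal = nxt is not None and _is_lower_epithet(nxt)
                if author_signal and not rank_signal:
                    rank = None
                elif rank_signal and not author_signal:
                    rank = _AMBIGUOUS_LETTERS[letter]
                else:
                    rank = _AMBIGUOUS_LETTERS[letter]
                    ambiguous_here = True
        else:
            rank = canonical_rank(tok, options)

        if rank is not None and nxt is not None and _is_pure_alpha(nxt) and len(parts) < 2:
            if ambiguous_here and flag == "clean":
                flag, flagged_token, flagged_index = "ambiguous_rank_token", tok, i
            epithet = nxt.lower()
            parts.append(
                InfraPart(
                    rank=rank,
                    rank_token=tok,
                    epithet=epithet,
                    epithet_phonetic=_safe_phonetic(epithet),
                )
            )
            authority_chunks.append([])
            prev = nxt
            i += 2
            continue
        if rank is not None and ambiguous_here and nxt is not None and not _is_pure_alpha(nxt) and len(parts) < 2:
            # provisionally a rank indicator, but the "epithet" is author-shaped:
            # keep it as the infra epithet and flag for post-match verification
            if flag == "clean":
                flag, flagged_token, flagged_index = "ambiguous_rank_token", tok, i
            epithet = nxt.lower()
            parts.append(
                InfraPart(rank=rank, rank_token=tok, epithet=epithet, epithet_phonetic=_safe_phonetic(epithet))
            )
            authority_chunks.append([])
            prev = nxt
            i += 2
            continue
        if rank is not None and nxt is None and ambiguous_here:
            # trailing ambiguous token with nothing after it: flag, keep as authority
            if flag == "clean":
                flag, flagged_token, flagged_index = "ambiguous_rank_token", tok, i

        authority_chunks[-1].append(tok)
        prev = tok
        i += 1

    authority = " ".join(authority_chunks[0])
    parts = [replace(p, authority=" ".join(chunk)) for p, chunk in zip(parts, authority_chunks[1:])]
    return authority, parts, flag, flagged_token, flagged_index


def is_uniform_case(text: str) -> bool:
    letters = [c for c in text if c.isalpha()]
    return bool(letters) and (all(c.isupper() for c in letters) or all(c.islower() for c in letters))


def parse_name(normalized: str, options: MatchOptions | None = None) -> ParsedName:
    """Parse a normalized name string into a :class:`ParsedName`.

    The first token is the genus, the next epithet-like token the species
    epithet; tokens up to the first rank indicator form the species
    authority, then up to two (rank indicator, epithet, authority) groups
    follow.  Raises :class:`ParseError` on empty input or when no plausible
    genus token is present.
    """
    options = options or MatchOptions()
    if not normalized or not normalized.strip():
        raise ParseError("cannot parse an empty name")
    tokens = normalized.split()
    ci = options.force_case_insensitive or is_uniform_case(normalized)

    genus_tok = tokens[0]
    if not _alpha_core(genus_tok):
        raise ParseError(f"no plausible genus token at the start of {normalized!r}")

    idx = 1
    species = ""
    if idx < len(tokens):
        tok = tokens[idx]
        is_rank = canonical_rank(tok, options) is not None or _ambiguous_letter(tok) is not None
        if _is_pure_alpha(tok) and len(_alpha_core(tok)) > 1 and not is_rank:
            species = tok
            idx += 1

    tail = tuple(tokens[idx:])
    authority, parts, flag, flagged_token, flagged_index = _parse_tail(
        tail, ci=ci, options=options, prev_token=species or genus_tok
    )

    parsed = ParsedName(
        genus=genus_tok,
        genus_phonetic=_safe_phonetic(genus_tok),
        species_epithet=species,
        species_phonetic=_safe_phonetic(species),
        species_authority=authority,
        infra=tuple(parts),
        parse_flag=flag,
        ambiguous_token=flagged_token,
        tail_tokens=tail,
        flagged_tail_index=flagged_index,
        case_insensitive=ci,
    )
    return recapitalize(parsed)


def reparse_as_authority(parsed: ParsedName, options: MatchOptions | None = None) -> ParsedName:
    """Re-read the flagged rank-indicator token as part of the authority.

    Re-parses the post-epithet remainder with the ambiguous token pinned to
    the authority; used after the matching stage has shown the token to be a
    filius-style author abbreviation rather than a rank indicator.
    """
    options = options or MatchOptions()
    if parsed.flagged_tail_index is None:
        return parsed
    authority, parts, _, _, _ = _parse_tail(
        parsed.tail_tokens,
        ci=parsed.case_insensitive,
        options=options,
        prev_token=parsed.species_epithet or parsed.genus,
        authority_override=parsed.flagged_tail_index,
    )
    return recapitalize(
        replace(
            parsed,
            species_authority=authority,
            infra=tuple(parts),
            parse_flag="clean",
            ambiguous_token="",
            flagged_tail_index=None,
        )
    )


def _initial_cap(word: str) -> str:
    out = []
    seen_alpha = False
    for c in word:
        if c.isalpha():
            out.append(c.upper() if not seen_alpha else c.lower())
            seen_alpha = True
        else:
            out.append(c)
    return "".join(out)


def _titlecase_authority(authority: str) -> str:
    toks = []
    for tok in authority.split():
        if tok.casefold() in _AUTHORITY_SMALL_WORDS:
            toks.append(tok.casefold() if tok != "&" else tok)
        else:
            toks.append(_initial_cap(tok))
    return " ".join(toks)


def recapitalize(parsed: ParsedName) -> ParsedName:
    """Repair capitalization: genus initial-capital, epithets lowercase.

    Authorities are preserved verbatim in case-sensitive mode; in
    case-insensitive mode (where the input carried no usable case) they are
    title-cased token by token, with "ex"/"in"/"et" kept lowercase.
    """
    fix_auth = (lambda a: _titlecase_authority(a)) if parsed.case_insensitive else (lambda a: a)
    return replace(
        parsed,
        genus=_initial_cap(parsed.genus),
        species_epithet=parsed.species_epithet.lower(),
        species_authority=fix_auth(parsed.species_authority),
        infra=tuple(
            replace(p, epithet=p.epithet.lower(), authority=fix_auth(p.authority)) for p in parsed.infra
        ),
    )
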