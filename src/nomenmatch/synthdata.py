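"""Seeded synthetic checklists and corrupted name lists.

No reference checklist ships with the package, so every experiment runs on
generated data: pseudo-Latin binomials/trinomials built from syllable
inventories (epithet lengths centred on the 8–11 characters typical of
vascular-plant epithets), a configurable fraction of synonyms pointing at
accepted entries, authorities drawn from a pool that includes filius-style
"f." citations, and corruption operators (typos, case folding, rank-token
swaps) whose every edit is logged so recovery experiments are closed-loop:
for each corrupted name the manifest records exactly which entry it came
from.

Three canned list profiles mirror common real-world input styles: profile A
(no authorities, "s." as the subspecies indicator), profile B (entirely
uppercase), profile C (clean, code-compliant names).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

__all__ = [
    "SyntheticManifest",
    "generate_checklist",
    "corrupt_name",
    "generate_profile_list",
    "PROFILES",
]

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v",
           "br", "cr", "tr", "pl", "st", "ch", "th"]
_VOWELS = ["a", "e", "i", "o", "u", "ae", "ia"]
_GENUS_ENDINGS = ["a", "us", "um", "is", "ia", "ella", "aria"]
_EPITHET_ENDINGS = ["a", "us", "um", "is", "ensis", "folia", "florus", "oides", "anum"]

AUTHORITIES = [
    "L.", "Mill.", "Lam.", "DC.", "Willd.", "(Opiz) Oborny",
    "Bernh. ex Schrank & Mart.", "(L.) Bernh.", "(Mill.) Swingle",
    "L. f.", "Willd. f.", "(L.) Kern.", "Huds.", "Scop.", "All.",
]

_RANK_TOKENS = {"subspecies": "subsp.", "variety": "var.", "form": "f."}

PROFILES = ("A", "B", "C")


@dataclass
class SyntheticManifest:
    """Ground truth for a generated checklist or corrupted list."""

    seed: int
    #: (full_name, status, accepted_ref)
    entries: list[tuple[str, str, str]] = field(default_factory=list)
    #: per corrupted name: {"corrupted", "source", "edits": [...]}
    corruption_log: list[dict] = field(default_factory=list)


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS)


def _word(rng: random.Random, n_syllables: int, endings: list[str]) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables)) + rng.choice(endings)


def _genus(rng: random.Random) -> str:
    return _word(rng, rng.randint(2, 3), _GENUS_ENDINGS).capitalize()


def _epithet(rng: random.Random) -> str:
    return _word(rng, rng.randint(2, 3), _EPITHET_ENDINGS)


def generate_checklist(
    n_accepted: int,
    synonym_fraction: float = 0.3,
    infra_fraction: float = 0.2,
    seed: int = 0,
    *,
    with_authorities: bool = True,
) -> tuple[SyntheticManifest, list[tuple[str, str, str]]]:
    """Generate checklist rows: ``n_accepted`` accepted names plus
    ``round(n_accepted * synonym_fraction)`` synonyms.

    ``infra_fraction`` of the accepted names carry a subsp./var./f. level
    (always with a distinct epithet, so the filius-ambiguous authorities in
    the pool exercise the parser).  Fully reproducible from ``seed``;
    regenerates on the rare name collision so full names are unique.
    """
    if n_accepted < 1:
        raise ValueError("n_accepted must be >= 1")
    rng = random.Random(seed)
    manifest = SyntheticManifest(seed=seed)
    seen: set[str] = set()
    genera = [_genus(rng) for _ in range(max(3, n_accepted // 4))]

    def fresh_name(make) -> str:
        for _ in range(1000):
            name = make()
            if name not in seen:
                seen.add(name)
                return name
        raise RuntimeError("could not generate a unique name")

    accepted: list[str] = []
    for _ in range(n_accepted):
        def make() -> str:
            bits = [rng.choice(genera), _epithet(rng)]
            if with_authorities:
                bits.append(rng.choice(AUTHORITIES))
            if rng.random() < infra_fraction:
                rank = rng.choice(list(_RANK_TOKENS.values()))
                bits.append(rank)
                bits.append(_epithet(rng))
                if with_authorities and rng.random() < 0.5:
                    bits.append(rng.choice(AUTHORITIES))
            return " ".join(bits)

        name = fresh_name(make)
        accepted.append(name)
        manifest.entries.append((name, "accepted", ""))

    n_syn = round(n_accepted * synonym_fraction)
    for _ in range(n_syn):
        target = rng.choice(accepted)

        def make_syn() -> str:
            bits = [rng.choice(genera), _epithet(rng)]
            if with_authorities:
                bits.append(rng.choice(AUTHORITIES))
            return " ".join(bits)

        name = fresh_name(make_syn)
        manifest.entries.append((name, "synonym", target))

    return manifest, list(manifest.entries)


_EDIT_KINDS = {"substitution", "insertion", "deletion", "transposition", "case_fold", "rank_swap"}
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _epithet_positions(name: str) -> list[int]:
    """Indices of editable characters: letters inside lowercase alphabetic
    tokens that are not rank indicators (blanks and authorities untouched)."""
    positions: list[int] = []
    offset = 0
    for tok in name.split(" "):
        if tok.isalpha() and tok.islower():
            positions.extend(range(offset, offset + len(tok)))
        offset += len(tok) + 1
    return positions


def corrupt_name(
    name: str,
    n_edits: int = 1,
    edit_kinds: set[str] | None = None,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Apply ``n_edits`` seeded corruption operations to ``name``.

    Character edits land inside epithet tokens only and never touch blanks;
    ``case_fold`` uppercases the whole string; ``rank_swap`` replaces the
    rank indicator with a wrong or nonstandard alias.  Returns the corrupted
    string and an edit log.  Raises ``ValueError`` when the name offers too
    few editable positions.
    """
    if n_edits < 1:
        raise ValueError("n_edits must be >= 1")
    kinds = sorted(edit_kinds or {"substitution"})
    unknown = set(kinds) - _EDIT_KINDS
    if unknown:
        raise ValueError(f"unknown edit kinds: {sorted(unknown)}")
    rng = random.Random(seed)
    log: list[dict] = []
    out = name
    for _ in range(n_edits):
        kind = rng.choice(kinds)
        if kind == "case_fold":
            log.append({"kind": "case_fold", "before": out})
            out = out.upper()
            continue
        if kind == "rank_swap":
            out = _swap_rank(out, rng, log)
            continue
        positions = _epithet_positions(out)
        if not positions:
            raise ValueError(f"no editable epithet characters in {out!r}")
        pos = rng.choice(positions)
        if kind == "substitution":
            old = out[pos]
            new = rng.choice([c for c in _LETTERS if c != old.lower()])
            out = out[:pos] + new + out[pos + 1 :]
            log.append({"kind": "substitution", "pos": pos, "old": old, "new": new})
        elif kind == "insertion":
            new = rng.choice(_LETTERS)
            out = out[:pos] + new + out[pos:]
            log.append({"kind": "insertion", "pos": pos, "new": new})
        elif kind == "deletion":
            old = out[pos]
            out = out[:pos] + out[pos + 1 :]
            log.append({"kind": "deletion", "pos": pos, "old": old})
        elif kind == "transposition":
            if pos + 1 not in positions:
                pos = max(p for p in positions if p + 1 in positions) if any(
                    p + 1 in positions for p in positions
                ) else pos
            if pos + 1 < len(out) and out[pos + 1] != " ":
                out = out[:pos] + out[pos + 1] + out[pos] + out[pos + 2 :]
                log.append({"kind": "transposition", "pos": pos})
            else:
                log.append({"kind": "transposition", "pos": pos, "noop": True})
    return out, log


_WRONG_RANKS = ["subsp.", "var.", "f.", "s.", "ssp", "varietas", "forma"]


def _swap_rank(name: str, rng: random.Random, log: list[dict]) -> str:
    tokens = name.split(" ")
    idx = [i for i, t in enumerate(tokens) if t in _RANK_TOKENS.values()]
    if not idx:
        raise ValueError(f"no rank indicator to swap in {name!r}")
    i = rng.choice(idx)
    old = tokens[i]
    new = rng.choice([r for r in _WRONG_RANKS if r != old])
    tokens[i] = new
    log.append({"kind": "rank_swap", "old": old, "new": new})
    return " ".join(tokens)


def generate_profile_list(
    profile: str,
    checklist_names: list[str],
    n: int,
    seed: int = 0,
    *,
    typo_fraction: float = 0.3,
) -> tuple[list[str], SyntheticManifest]:
    """Draw ``n`` names from a checklist and restyle them per profile.

    Profile A strips authorities and writes subspecies as "s."; profile B
    uppercases everything; profile C leaves names code-compliant.  A
    ``typo_fraction`` of the drawn names additionally receives one epithet
    substitution.  The manifest logs every source and edit.
    """
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")
    rng = random.Random(seed)
    manifest = SyntheticManifest(seed=seed)
    out: list[str] = []
    for k in range(n):
        source = rng.choice(checklist_names)
        name = source
        edits: list[dict] = []
        if rng.random() < typo_fraction:
            name, edits = corrupt_name(name, 1, {"substitution"}, seed=rng.randrange(2**31))
        if profile == "A":
            name = _strip_authorities(name).replace("subsp.", "s.")
        elif profile == "B":
            name = name.upper()
            edits = edits + [{"kind": "case_fold"}]
        out.append(name)
        manifest.corruption_log.append({"corrupted": name, "source": source, "edits": edits})
    return out, manifest


def _strip_authorities(name: str) -> str:
    """Keep genus, epithets and rank indicators; drop author tokens."""
    kept: list[str] = []
    tokens = name.split(" ")
    for i, tok in enumerate(tokens):
        if i == 0 or tok in _RANK_TOKENS.values():
            kept.append(tok)
        elif tok.isalpha() and tok.islower() and (i == 1 or tokens[i - 1] in _RANK_TOKENS.values()):
            kept.append(tok)
    return " ".join(kept)
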