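"""Input-string normalization applied before any parsing or matching.

Scientific names arriving from OCR'd literature, herbarium labels or hand
typing carry quote marks, stray digits (years, collector numbers), diacritics
and uncertainty qualifiers ("cf.", "aff.") that the reference checklist never
contains.  ``normalize_string`` strips all of that down to the character
inventory a botanical name can legally use, so the parser and the edit
distances downstream only ever see comparable text.
"""

from __future__ import annotations

import unicodedata

__all__ = ["normalize_string"]

# Characters deleted outright (uncertainty/formatting marks).
_DELETED = set("?!#\"'“”‘’«»‹›`")

# Underscores separate tokens in many database exports; deleting them would
# glue genus and epithet together, so they become blanks instead.
_BLANKED = set("_")

# The character classes a parsed name may legally contain after normalization.
_ALLOWED = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ .()&,-")

_UNCERTAINTY_TOKENS = {"cf", "aff"}


def _fold_diacritics(text: str) -> str:
    """Map letters with diacritical marks onto their ASCII base letters."""
    for src, dst in (("ß", "ss"), ("Ø", "O"), ("ø", "o"),
                     ("Œ", "Oe"), ("œ", "oe"), ("Æ", "Ae"), ("æ", "ae"),
                     ("Đ", "D"), ("đ", "d"), ("Ł", "L"), ("ł", "l")):
        text = text.replace(src, dst)
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def normalize_string(raw: str, *, treat_cfr_as_uncertain: bool = False) -> str:
    """Normalize a raw name string.

    Applies, in order: removal of special characters, removal of digits,
    diacritic folding, insertion of a blank after every dot, removal of the
    uncertainty tokens ``cf.`` / ``aff.`` (and optionally ``cfr.``), and
    blank collapsing.  Total function: any text in, normalized text out.
    """
    uncertain = set(_UNCERTAINTY_TOKENS)
    if treat_cfr_as_uncertain:
        uncertain.add("cfr")

    chars: list[str] = []
    for c in raw:
        if c in _DELETED:
            continue
        if c in _BLANKED:
            chars.append(" ")
            continue
        if c.isdigit():
            continue
        chars.append(c)
    text = _fold_diacritics("".join(chars))

    # Anything still outside the legal inventory becomes a blank (safer than
    # deletion: "Genus×species" must stay two tokens).
    text = "".join(c if c in _ALLOWED else " " for c in text)

    # One blank after every dot ("R.canina" -> "R. canina"); closing
    # punctuation stays glued so "(L.)" survives intact.
    out: list[str] = []
    for i, c in enumerate(text):
        out.append(c)
        if c == "." and i + 1 < len(text) and text[i + 1] not in " ),":
            out.append(" ")
    text = "".join(out)

    # Uncertainty qualifiers are standalone tokens, with or without the dot.
    tokens = [t for t in text.split() if t.rstrip(".").lower() not in uncertain]
    return " ".join(tokens)
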